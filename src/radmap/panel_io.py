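"""Genotype-panel data types and tabular readers/writers.

The central object of the pipeline is a :class:`GenotypePanel`: a
markers x individuals grid of codominant F2 genotype calls.  Genotypes are
stored internally as integer *dosages* of the paternal-strain allele
(2 = paternal-strain homozygote, 1 = heterozygote, 0 = maternal-strain
homozygote, -1 = missing), which makes downstream counting and
crossover arithmetic direct.  The typed surface is :class:`GenotypeCall`.

File formats are deliberately plain: tab-separated panels (first row
individual ids, first column marker ids, cells from a configurable code
*dialect*, default ``a``/``h``/``b``/``-``), a map table TSV, an optional
R/qtl-style CSV export, and FASTA for marker tag sequences.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "GenotypeCall",
    "MarkerRecord",
    "GenotypePanel",
    "MapRow",
    "MapTable",
    "DEFAULT_DIALECT",
    "read_panel",
    "write_panel",
    "read_fasta_sequences",
    "write_map",
    "read_map",
    "write_rqtl_csv",
]

MISSING = -1

#: default cell-string -> dosage mapping ("a" = paternal homozygote)
DEFAULT_DIALECT: Mapping[str, int | None] = {"a": 2, "h": 1, "b": 0, "-": None}

_IUPAC = set("ACGTURYSWKMBDHVN")


class GenotypeCall(enum.Enum):
    """One codominant F2 genotype call.

    ``P1HOM`` is the paternal-strain homozygote (dosage 2), ``HET`` the
    heterozygote (dosage 1), ``P2HOM`` the maternal-strain homozygote
    (dosage 0).  ``MISSING`` has no dosage.
    """

    P1HOM = "P1hom"
    HET = "Het"
    P2HOM = "P2hom"
    MISSING = "Missing"

    @property
    def dosage(self) -> int | None:
        return _DOSAGE[self]

    @classmethod
    def from_dosage(cls, dosage: int | None) -> "GenotypeCall":
        if dosage is None or dosage == MISSING:
            return cls.MISSING
        try:
            return _FROM_DOSAGE[int(dosage)]
        except KeyError:
            raise ValueError(f"invalid dosage {dosage!r}; expected 0, 1, 2 or missing")


_DOSAGE = {
    GenotypeCall.P1HOM: 2,
    GenotypeCall.HET: 1,
    GenotypeCall.P2HOM: 0,
    GenotypeCall.MISSING: None,
}
_FROM_DOSAGE = {2: GenotypeCall.P1HOM, 1: GenotypeCall.HET, 0: GenotypeCall.P2HOM}


@dataclass(frozen=True)
class MarkerRecord:
    """One marker: its id, optional RAD-tag sequence, and genotype vector."""

    id: str
    genotypes: np.ndarray  # int8 dosages, -1 missing
    sequence: str | None = None

    def __post_init__(self):
        if self.sequence is not None:
            bad = set(self.sequence.upper()) - _IUPAC
            if bad:
                raise ValueError(
                    f"marker {self.id!r}: non-IUPAC characters in sequence: {sorted(bad)}"
                )

    @property
    def calls(self) -> list[GenotypeCall]:
        return [GenotypeCall.from_dosage(int(d)) for d in self.genotypes]


class PanelError(ValueError):
    """Raised for malformed panel files or inconsistent panel construction."""


@dataclass
class GenotypePanel:
    """A markers x individuals grid of genotype calls.

    Parameters
    ----------
    marker_ids, individual_ids
        Unique row / column labels, in file order.
    dosages
        ``(n_markers, n_individuals)`` int8 array, values in {-1, 0, 1, 2}.
    sequences
        Optional marker id -> nucleotide string mapping (RAD-tag sequences).
    """

    marker_ids: list[str]
    individual_ids: list[str]
    dosages: np.ndarray
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.marker_ids = list(self.marker_ids)
        self.individual_ids = list(self.individual_ids)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.marker_ids), len(self.individual_ids)):
            raise PanelError(
                f"dosage grid shape {self.dosages.shape} does not match "
                f"{len(self.marker_ids)} markers x {len(self.individual_ids)} individuals"
            )
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise PanelError("duplicate marker ids")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise PanelError("duplicate individual ids")
        bad = ~np.isin(self.dosages, (-1, 0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise PanelError(
                f"invalid dosage {self.dosages[i, j]} at marker "
                f"{self.marker_ids[i]!r}, individual {self.individual_ids[j]!r}"
            )
        if self.n_individuals and self.n_markers:
            all_missing = (self.dosages == MISSING).all(axis=0)
            if all_missing.any():
                j = int(np.flatnonzero(all_missing)[0])
                raise PanelError(
                    f"individual {self.individual_ids[j]!r} has no genotype calls"
                )

    # -- basic accessors ---------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def marker(self, marker_id: str) -> MarkerRecord:
        i = self.marker_index(marker_id)
        return MarkerRecord(
            id=marker_id,
            genotypes=self.dosages[i].copy(),
            sequence=self.sequences.get(marker_id),
        )

    def marker_index(self, marker_id: str) -> int:
        try:
            return self._marker_index[marker_id]
        except AttributeError:
            self._marker_index = {m: i for i, m in enumerate(self.marker_ids)}
            return self._marker_index[marker_id]

    # -- summaries used by QC ---------------------------------------------
    def missing_per_individual(self) -> np.ndarray:
        return (self.dosages == MISSING).sum(axis=0)

    def missing_per_marker(self) -> np.ndarray:
        return (self.dosages == MISSING).sum(axis=1)

    def het_fraction_per_individual(self) -> np.ndarray:
        """Heterozygous fraction among non-missing calls, per individual."""
        obs = (self.dosages != MISSING).sum(axis=0)
        het = (self.dosages == 1).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(obs > 0, het / np.maximum(obs, 1), np.nan)

    def genotype_counts(self) -> np.ndarray:
        """Per-marker (nP1hom, nHet, nP2hom) counts, shape (n_markers, 3)."""
        return np.stack(
            [(self.dosages == d).sum(axis=1) for d in (2, 1, 0)], axis=1
        )

    # -- subsetting --------------------------------------------------------
    def subset(
        self,
        markers: Sequence[str] | None = None,
        individuals: Sequence[str] | None = None,
    ) -> "GenotypePanel":
        """Return a new panel restricted to the given ids (original order kept)."""
        mset = set(markers) if markers is not None else None
        iset = set(individuals) if individuals is not None else None
        mi = [i for i, m in enumerate(self.marker_ids) if mset is None or m in mset]
        ii = [j for j, s in enumerate(self.individual_ids) if iset is None or s in iset]
        mids = [self.marker_ids[i] for i in mi]
        return GenotypePanel(
            marker_ids=mids,
            individual_ids=[self.individual_ids[j] for j in ii],
            dosages=self.dosages[np.ix_(mi, ii)].copy(),
            sequences={m: self.sequences[m] for m in mids if m in self.sequences},
        )


# ---------------------------------------------------------------------------
# panel TSV
# ---------------------------------------------------------------------------

def read_panel(path: str | Path, dialect: Mapping[str, int | None] | None = None) -> GenotypePanel:
    """Read a tab-separated genotype panel.

    First row: individual ids (first cell ignored/blank); first column:
    marker ids.  ``dialect`` maps cell strings to dosages (``None`` =
    missing); unknown codes are an error naming the offending cell.
    Marker and individual order is preserved exactly.
    """
    codes = dict(DEFAULT_DIALECT if dialect is None else dialect)
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise PanelError(f"{path}: empty file")
    header = rows[0]
    individual_ids = [c.strip() for c in header[1:]]
    n_ind = len(individual_ids)
    marker_ids: list[str] = []
    grid = np.empty((len(rows) - 1, n_ind), dtype=np.int8)
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != n_ind + 1:
            raise PanelError(
                f"{path}: line {r}: expected {n_ind + 1} columns, found {len(row)}"
            )
        marker_id = row[0].strip()
        marker_ids.append(marker_id)
        for j, cell in enumerate(row[1:]):
            cell = cell.strip()
            if cell not in codes:
                raise PanelError(
                    f"{path}: unknown genotype code {cell!r} at marker "
                    f"{marker_id!r}, individual {individual_ids[j]!r}"
                )
            d = codes[cell]
            grid[r - 2, j] = MISSING if d is None else d
    return GenotypePanel(marker_ids=marker_ids, individual_ids=individual_ids, dosages=grid)


def write_panel(
    panel: GenotypePanel,
    path: str | Path,
    dialect: Mapping[str, int | None] | None = None,
) -> None:
    """Write a panel as TSV, inverse of :func:`read_panel`."""
    codes = dict(DEFAULT_DIALECT if dialect is None else dialect)
    inverse = {(MISSING if d is None else d): s for s, d in codes.items()}
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["marker", *panel.individual_ids])
        for i, m in enumerate(panel.marker_ids):
            w.writerow([m, *(inverse[int(d)] for d in panel.dosages[i])])


def read_fasta_sequences(path: str | Path, panel: GenotypePanel | None = None) -> dict[str, str]:
    """Read marker tag sequences from FASTA; ids must match panel marker ids
    when a panel is given.  Returns id -> sequence and attaches them to the
    panel in place."""
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if panel is not None:
        unknown = set(seqs) - set(panel.marker_ids)
        if unknown:
            raise PanelError(
                f"FASTA ids not present in panel: {sorted(unknown)[:5]}..."
                if len(unknown) > 5
                else f"FASTA ids not present in panel: {sorted(unknown)}"
            )
        panel.sequences.update(seqs)
    return seqs


# ---------------------------------------------------------------------------
# map table TSV
# ---------------------------------------------------------------------------

_FLAGS = ("none", "p05", "p01")


@dataclass(frozen=True)
class MapRow:
    lg: str
    position_cM: float
    bin_id: str
    n_markers: int
    marker_ids: tuple[str, ...]
    distortion_flag: str = "none"

    def __post_init__(self):
        if self.distortion_flag not in _FLAGS:
            raise ValueError(f"invalid distortion flag {self.distortion_flag!r}")
        if self.position_cM < 0:
            raise ValueError("positions must be non-negative")
        if self.n_markers < 1:
            raise ValueError("bins hold at least one marker")


@dataclass
class MapTable:
    """Serialized form of a genetic map: one row per bin."""

    rows: list[MapRow]

    def __post_init__(self):
        seen: set[str] = set()
        by_lg: dict[str, list[MapRow]] = {}
        for row in self.rows:
            for m in row.marker_ids:
                if m in seen:
                    raise ValueError(f"marker {m!r} appears in more than one bin")
                seen.add(m)
            by_lg.setdefault(row.lg, []).append(row)
        for lg, rows in by_lg.items():
            pos = [r.position_cM for r in rows]
            if pos[0] != 0:
                raise ValueError(f"{lg}: first position must be 0")
            if any(b < a - 1e-9 for a, b in zip(pos, pos[1:])):
                raise ValueError(f"{lg}: positions must be non-decreasing")


_MAP_HEADER = ["lg", "position_cM", "bin_id", "n_markers", "marker_ids", "distortion_flag"]


def _lg_sort_key(name: str):
    # numeric-aware ordering so LG2 < LG10
    digits = "".join(ch for ch in name if ch.isdigit())
    return (int(digits) if digits else float("inf"), name)


def write_map(gmap, path: str | Path) -> None:
    """Write a finalized genetic map as a TSV map table.

    ``gmap`` is a :class:`radmap.map_build.GeneticMap` (duck-typed: any object
    with ``lgs`` carrying name/bin ids/marker ids/positions/flags).  Positions
    are serialized to 4 decimals; linkage groups are emitted in name order.
    """
    lgs = sorted(gmap.lgs, key=lambda lg: _lg_sort_key(lg.name))
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_MAP_HEADER)
        for lg in lgs:
            for k, bin_id in enumerate(lg.bin_ids):
                w.writerow(
                    [
                        lg.name,
                        f"{lg.positions_cM[k]:.4f}",
                        bin_id,
                        len(lg.marker_ids[k]),
                        ",".join(lg.marker_ids[k]),
                        lg.distortion_flags[k],
                    ]
                )


def read_map(path: str | Path) -> MapTable:
    """Read a map table TSV written by :func:`write_map`."""
    with Path(path).open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _MAP_HEADER:
            raise ValueError(f"{path}: unexpected map header {header}")
        rows = [
            MapRow(
                lg=r[0],
                position_cM=float(r[1]),
                bin_id=r[2],
                n_markers=int(r[3]),
                marker_ids=tuple(r[4].split(",")) if r[4] else (),
                distortion_flag=r[5],
            )
            for r in reader
        ]
    return MapTable(rows=rows)


# ---------------------------------------------------------------------------
# interoperability export
# ---------------------------------------------------------------------------

def write_rqtl_csv(panel: GenotypePanel, path: str | Path, chromosomes: Mapping[str, str] | None = None) -> None:
    """Export an R/qtl-style rotated CSV (individuals as rows, genotypes A/H/B).

    ``chromosomes`` optionally maps marker id -> chromosome label (written in
    the second header row; blank when unknown)."""
    code = {2: "A", 1: "H", 0: "B", MISSING: "-"}
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["id", *panel.marker_ids])
        w.writerow(["", *((chromosomes or {}).get(m, "") for m in panel.marker_ids)])
        for j, ind in enumerate(panel.individual_ids):
            w.writerow([ind, *(code[int(d)] for d in panel.dosages[:, j])])
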