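"""Cosegregation binning: group markers with identical segregation patterns.

With 49 F2 individuals, many markers show exactly the same genotype vector
and therefore cannot be separated by recombination in the cross; such
markers share one map location, a *bin*.  Missing genotypes are treated as
wildcards: a marker joins a bin if its observed genotypes agree with the
bin's consensus everywhere both are non-missing.

Markers are processed in order of decreasing non-missing count (ties by
input order), so well-observed patterns seed bins before wildcard-heavy
markers.  A marker compatible with several bins joins the bin with the
most members (ties to the earliest-created bin) and is recorded as
ambiguous; joining fills previously-missing consensus positions from the
marker.  The assignment of ambiguous markers is thereby deterministic,
which affects membership lists but not the bin count or map structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel_io import GenotypePanel, MISSING

__all__ = ["Bin", "BinSet", "assign_bins", "bin_count"]


@dataclass
class Bin:
    """A set of cosegregating markers and their consensus genotype vector."""

    id: str
    member_marker_ids: tuple[str, ...]
    consensus: np.ndarray  # int8 dosages, -1 where all members missing
    ambiguous_members: tuple[tuple[str, tuple[str, ...]], ...] = ()

    @property
    def n_members(self) -> int:
        return len(self.member_marker_ids)


@dataclass
class BinSet:
    bins: list[Bin]
    marker_to_bin: dict[str, str] = field(default_factory=dict)

    @property
    def bin_ids(self) -> list[str]:
        return [b.id for b in self.bins]

    def get(self, bin_id: str) -> Bin:
        try:
            return self._by_id[bin_id]
        except AttributeError:
            self._by_id = {b.id: b for b in self.bins}
            return self._by_id[bin_id]

    def consensus_matrix(self, bin_ids: list[str] | None = None) -> np.ndarray:
        """(n_bins, n_individuals) consensus dosage matrix, -1 missing."""
        ids = self.bin_ids if bin_ids is None else bin_ids
        return np.stack([self.get(b).consensus for b in ids]) if ids else np.empty((0, 0), np.int8)

    def markers_per_bin(self, bin_ids: list[str] | None = None) -> np.ndarray:
        ids = self.bin_ids if bin_ids is None else bin_ids
        return np.array([self.get(b).n_members for b in ids], dtype=int)

    def validate_compatibility(self, panel: GenotypePanel) -> None:
        """Check every member against its bin's *final* consensus (guards
        against consensus drift during incremental filling)."""
        for b in self.bins:
            for m in b.member_marker_ids:
                g = panel.dosages[panel.marker_index(m)]
                clash = (g != b.consensus) & (g != MISSING) & (b.consensus != MISSING)
                if clash.any():
                    raise AssertionError(
                        f"marker {m!r} incompatible with final consensus of bin {b.id!r}"
                    )


def assign_bins(panel: GenotypePanel) -> BinSet:
    """Partition the panel's markers into bins of cosegregating markers."""
    n_m, n_i = panel.n_markers, panel.n_individuals
    obs = (panel.dosages != MISSING).sum(axis=1)
    if n_m and obs.min() < 1:
        i = int(np.argmin(obs))
        raise ValueError(f"marker {panel.marker_ids[i]!r} has no observed genotypes")
    order = np.argsort(-obs, kind="stable")

    consensus = np.empty((n_m, n_i), dtype=np.int8)  # grows by rows used
    members: list[list[str]] = []
    ambiguous: list[tuple[str, int, tuple[int, ...]]] = []  # marker, chosen, candidates
    n_bins = 0
    sizes = np.zeros(n_m, dtype=int)

    for idx in order:
        g = panel.dosages[idx]
        m_id = panel.marker_ids[idx]
        if n_bins:
            C = consensus[:n_bins]
            clash = ((C != g) & (C != MISSING) & (g != MISSING)).any(axis=1)
            cands = np.flatnonzero(~clash)
        else:
            cands = np.empty(0, dtype=int)
        if cands.size == 0:
            consensus[n_bins] = g
            members.append([m_id])
            sizes[n_bins] = 1
            n_bins += 1
        else:
            # largest bin wins; argmax takes the earliest-created on ties
            chosen = int(cands[int(np.argmax(sizes[cands]))])
            if cands.size > 1:
                ambiguous.append((m_id, chosen, tuple(int(c) for c in cands)))
            fill = (consensus[chosen] == MISSING) & (g != MISSING)
            consensus[chosen, fill] = g[fill]
            members[chosen].append(m_id)
            sizes[chosen] += 1

    width = max(4, len(str(n_bins)))
    ids = [f"bin{k + 1:0{width}d}" for k in range(n_bins)]
    amb_by_bin: dict[int, list[tuple[str, tuple[str, ...]]]] = {}
    for m_id, chosen, cands in ambiguous:
        amb_by_bin.setdefault(chosen, []).append((m_id, tuple(ids[c] for c in cands)))

    bins = [
        Bin(
            id=ids[k],
            member_marker_ids=tuple(members[k]),
            consensus=consensus[k].copy(),
            ambiguous_members=tuple(amb_by_bin.get(k, ())),
        )
        for k in range(n_bins)
    ]
    marker_to_bin = {m: b.id for b in bins for m in b.member_marker_ids}
    return BinSet(bins=bins, marker_to_bin=marker_to_bin)


def bin_count(binset: BinSet) -> int:
    return len(binset.bins)


def write_bins_tsv(binset: BinSet, path) -> None:
    """Bin membership TSV: bin_id, n_members, marker_ids, ambiguous_flag."""
    import csv
    from pathlib import Path

    ambiguous_markers = {
        m for b in binset.bins for (m, _cands) in b.ambiguous_members
    }
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["bin_id", "n_members", "marker_ids", "ambiguous_flag"])
        for b in binset.bins:
            flag = int(any(m in ambiguous_markers for m in b.member_marker_ids))
            w.writerow([b.id, b.n_members, ",".join(b.member_marker_ids), flag])
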