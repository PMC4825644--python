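"""Assemble ordered linkage groups into a genetic map with Kosambi distances.

The Kosambi map function, ``d = 25 ln((1 + 2r) / (1 - 2r))`` cM, converts
recombination fractions into additive distances while allowing moderate
crossover interference; its inverse is ``r = tanh(d / 50) / 2``.

Map assembly re-estimates the recombination fraction between consecutive
bins on the final order (so distances reflect pairwise-complete data at
the final adjacency), accumulates Kosambi increments into positions,
orients each linkage group so that the terminal bin holding more markers
sits at 0 cM (a deterministic convention echoing the marker pile-up at
acrocentric chromosome tips), names the groups LG1, LG2, ... in decreasing
order of total marker count, and flags bins containing segregation-
distorted markers (P < 0.05 / P < 0.01).

:func:`map_stats` reports the summary statistics used to sanity-check the
map: per-group length, adjacent-bin spacing, tip-density flags, the
per-individual recombination-event histogram with its 1:2:1 chi-square,
and global double-recombination counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .binning import BinSet
from .grouping_ordering import LinkageGroupDraft, flag_double_recombinants
from .panel_io import MISSING, GenotypePanel
from .qc import distortion_pvalues
from .recomb import em_rf, pair_counts

__all__ = [
    "kosambi",
    "inverse_kosambi",
    "LinkageGroup",
    "GeneticMap",
    "LGStats",
    "MapStats",
    "build_map",
    "map_stats",
    "bin_density",
]

# adjacent fractions estimated at exactly 0.5 (no linkage information at the
# final adjacency) would map to infinite distance; they are capped just below
_R_CAP = 0.5 - 1e-9


def kosambi(r: float) -> float:
    """Kosambi map distance in cM for a recombination fraction in [0, 0.5)."""
    if not 0.0 <= r < 0.5:
        raise ValueError(f"recombination fraction {r!r} outside [0, 0.5)")
    return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def inverse_kosambi(cM: float) -> float:
    """Recombination fraction for a Kosambi distance in cM (inverse map)."""
    if cM < 0:
        raise ValueError("map distance must be non-negative")
    return 0.5 * math.tanh(cM / 50.0)


@dataclass
class LinkageGroup:
    name: str
    bin_ids: list[str]
    marker_ids: list[tuple[str, ...]]  # per bin
    positions_cM: np.ndarray
    adjacent_r: list[float]
    distortion_flags: list[str]

    @property
    def n_markers(self) -> int:
        return sum(len(m) for m in self.marker_ids)

    @property
    def n_bins(self) -> int:
        return len(self.bin_ids)

    @property
    def length_cM(self) -> float:
        return float(self.positions_cM[-1]) if self.n_bins else 0.0


@dataclass
class GeneticMap:
    lgs: list[LinkageGroup]
    unplaced: list[str] = field(default_factory=list)

    @property
    def total_length_cM(self) -> float:
        return float(sum(lg.length_cM for lg in self.lgs))

    @property
    def n_mapped_markers(self) -> int:
        return sum(lg.n_markers for lg in self.lgs)


def _flag(pvals: Sequence[float]) -> str:
    p = [v for v in pvals if np.isfinite(v)]
    if p and min(p) < 0.01:
        return "p01"
    if p and min(p) < 0.05:
        return "p05"
    return "none"


def build_map(
    groups: Sequence[LinkageGroupDraft | Sequence[str]],
    panel: GenotypePanel,
    binset: BinSet,
    marker_pvalues: Mapping[str, float] | None = None,
    lg_prefix: str = "LG",
) -> GeneticMap:
    """Build a finalized genetic map from ordered groups.

    ``marker_pvalues`` maps marker id -> segregation-distortion p-value; if
    omitted, p-values are computed from the panel.
    """
    if marker_pvalues is None:
        pv = distortion_pvalues(panel)
        marker_pvalues = dict(zip(panel.marker_ids, pv))

    seen: set[str] = set()
    built = []
    for g in groups:
        order = list(g.bin_ids) if isinstance(g, LinkageGroupDraft) else list(g)
        dup = seen.intersection(order)
        if dup:
            raise ValueError(f"bin(s) {sorted(dup)} assigned to more than one group")
        seen.update(order)

        members = [binset.get(b).member_marker_ids for b in order]
        # orientation: heavier terminal bin at 0 cM; ties by first bin id
        if len(order) > 1:
            first_n, last_n = len(members[0]), len(members[-1])
            reverse = last_n > first_n or (last_n == first_n and order[-1] < order[0])
            if reverse:
                order = order[::-1]
                members = members[::-1]

        D = binset.consensus_matrix(order)
        adj_r = []
        for k in range(len(order) - 1):
            adj_r.append(min(em_rf(pair_counts(D[k], D[k + 1])).r_hat, _R_CAP))
        positions = np.concatenate([[0.0], np.cumsum([kosambi(r) for r in adj_r])])
        flags = [_flag([marker_pvalues.get(m, np.nan) for m in mm]) for mm in members]
        built.append((order, members, positions, adj_r, flags))

    built.sort(key=lambda t: (-sum(len(m) for m in t[1]), t[0][0]))
    lgs = [
        LinkageGroup(
            name=f"{lg_prefix}{i + 1}",
            bin_ids=order,
            marker_ids=list(members),
            positions_cM=positions,
            adjacent_r=adj_r,
            distortion_flags=flags,
        )
        for i, (order, members, positions, adj_r, flags) in enumerate(built)
    ]
    placed = {m for lg in lgs for mm in lg.marker_ids for m in mm}
    unplaced = [m for m in binset.marker_to_bin if m not in placed]
    return GeneticMap(lgs=lgs, unplaced=unplaced)


@dataclass
class LGStats:
    name: str
    n_markers: int
    n_bins: int
    length_cM: float
    mean_adjacent_cM: float
    largest_gap_cM: float
    tip_density_flags: list[str]  # bins holding >= 8.0% of the LG's markers
    event_histogram: dict[str, int]  # individuals with 0 / 1 / 2 / 3+ events
    event_chi2_p: float


@dataclass
class MapStats:
    per_lg: list[LGStats]
    total_length_cM: float
    mean_markers_per_bin: float  # total markers / total bins
    mean_of_lg_mean_markers_per_bin: float
    double_recombination_count: int
    double_recombination_fraction: float  # per individual-chromosome


def _events_per_individual(D: np.ndarray) -> np.ndarray:
    """Minimum crossover count along an ordered dosage matrix, per column."""
    n_ind = D.shape[1]
    out = np.zeros(n_ind, dtype=int)
    for j in range(n_ind):
        v = D[:, j]
        v = v[v != MISSING].astype(np.int64)
        if v.size > 1:
            out[j] = int(np.abs(np.diff(v)).sum())
    return out


def map_stats(gmap: GeneticMap, panel: GenotypePanel, binset: BinSet, density_threshold: float = 0.08) -> MapStats:
    """Summary statistics of a finalized map."""
    per_lg = []
    double_count = 0
    for lg in gmap.lgs:
        gaps = np.diff(lg.positions_cM)
        D = binset.consensus_matrix(lg.bin_ids)
        events = _events_per_individual(D)
        hist = {
            "0": int((events == 0).sum()),
            "1": int((events == 1).sum()),
            "2": int((events == 2).sum()),
            "3+": int((events >= 3).sum()),
        }
        # observed (2-or-more, 1, 0) against the 1:2:1 obligate-chiasma ratio
        obs = np.array([hist["2"] + hist["3+"], hist["1"], hist["0"]], dtype=float)
        n = obs.sum()
        if n > 0:
            chi2 = float((((obs - n * np.array([0.25, 0.5, 0.25])) ** 2) / (n * np.array([0.25, 0.5, 0.25]))).sum())
            p = float(stats.chi2.sf(chi2, df=2))
        else:
            p = float("nan")
        n_markers = lg.n_markers
        tip_flags = [
            b
            for b, mm in zip(lg.bin_ids, lg.marker_ids)
            if n_markers and len(mm) / n_markers >= density_threshold
        ]
        per_lg.append(
            LGStats(
                name=lg.name,
                n_markers=n_markers,
                n_bins=lg.n_bins,
                length_cM=lg.length_cM,
                mean_adjacent_cM=float(gaps.mean()) if gaps.size else 0.0,
                largest_gap_cM=float(gaps.max()) if gaps.size else 0.0,
                tip_density_flags=tip_flags,
                event_histogram=hist,
                event_chi2_p=p,
            )
        )
        double_count += len(flag_double_recombinants(lg.bin_ids, panel, binset))

    total_bins = sum(s.n_bins for s in per_lg)
    total_markers = sum(s.n_markers for s in per_lg)
    lg_means = [s.n_markers / s.n_bins for s in per_lg if s.n_bins]
    denom = panel.n_individuals * len(gmap.lgs)
    return MapStats(
        per_lg=per_lg,
        total_length_cM=gmap.total_length_cM,
        mean_markers_per_bin=(total_markers / total_bins) if total_bins else float("nan"),
        mean_of_lg_mean_markers_per_bin=float(np.mean(lg_means)) if lg_means else float("nan"),
        double_recombination_count=double_count,
        double_recombination_fraction=(double_count / denom) if denom else float("nan"),
    )


def bin_density(gmap: GeneticMap, binset: BinSet) -> list[tuple[str, str, float, int, float]]:
    """Per-bin marker density (markers per local cM): rows of
    (bin_id, lg, position_cM, n_markers, density).

    The local span of a bin is half the distance to each neighboring bin
    (single-sided at the ends); a zero span yields infinite density.
    """
    rows = []
    for lg in gmap.lgs:
        pos = lg.positions_cM
        for k, (b, mm) in enumerate(zip(lg.bin_ids, lg.marker_ids)):
            lo = pos[k] - (pos[k] - pos[k - 1]) / 2 if k > 0 else pos[0]
            hi = pos[k] + (pos[k + 1] - pos[k]) / 2 if k < len(pos) - 1 else pos[-1]
            span = hi - lo
            dens = len(mm) / span if span > 0 else float("inf")
            rows.append((b, lg.name, float(pos[k]), len(mm), float(dens)))
    return rows
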