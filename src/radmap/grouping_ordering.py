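"""Linkage grouping and within-group bin ordering.

Grouping is single linkage: bins are nodes, and any pair with an estimated
recombination fraction at or below ``max_rf`` is an edge; connected
components are linkage groups.  This is the unique threshold-graph
semantics under which a whole band of thresholds (here roughly 0.11-0.18
for the study design) yields the same major groups.  Components with at
least ``min_major_bins`` bins are *major*; singletons are reported as
unlinked.

Ordering is nearest-neighbor chain extension: start from the pair of bins
with minimal recombination fraction and repeatedly append the unplaced bin
closest to either chain end.  The greedy order is then refined by a local
search (all permutations inside a sliding window plus 2-opt segment
reversals) that minimizes the total number of recombination events implied
by the order — the sum over individuals of the minimum crossover count
along the ordered consensus genotypes.  The objective is integer-valued,
so ties are exact and the search is deterministic.  An exhaustive-search
oracle over all permutations is provided for small groups.

Apparent double recombination events at a single interior bin (an x-y-x
dosage pattern across three adjacent bins) usually indicate genotyping
errors; they are flagged, never auto-corrected.  User-vetted corrections
can be applied from a TSV via :func:`apply_corrections`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import permutations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .binning import BinSet
from .panel_io import MISSING, GenotypePanel
from .recomb import RfMatrix

__all__ = [
    "LinkageGroupDraft",
    "link_groups",
    "order_bins_greedy",
    "order_objective",
    "refine_order",
    "brute_force_order",
    "flag_double_recombinants",
    "apply_corrections",
]


@dataclass
class LinkageGroupDraft:
    """An ordered (or to-be-ordered) group of bins."""

    bin_ids: list[str]
    adjacent_r: list[float]
    objective: int
    major: bool


def link_groups(
    rf: RfMatrix, max_rf: float = 0.15, min_major_bins: int = 21
) -> tuple[list[list[str]], list[str]]:
    """Single-linkage grouping at threshold ``max_rf``.

    Returns (groups, unlinked): groups are the connected components with at
    least two bins, sorted by decreasing size (ties by first bin id);
    singleton components are returned as the unlinked list.  Pairs with
    undefined recombination fraction (no jointly informative individuals)
    contribute no edge.
    """
    if not 0 < max_rf < 0.5:
        raise ValueError("max_rf must be in (0, 0.5)")
    nb = len(rf.bin_ids)
    adj = np.nan_to_num(rf.r, nan=1.0) <= max_rf
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    comps: dict[int, list[str]] = {}
    for b, lab in zip(rf.bin_ids, labels):
        comps.setdefault(int(lab), []).append(b)
    groups = [g for g in comps.values() if len(g) > 1]
    groups.sort(key=lambda g: (-len(g), g[0]))
    unlinked = sorted(b for g in comps.values() if len(g) == 1 for b in g)
    return groups, unlinked


def is_major(group: Sequence[str], min_major_bins: int = 21) -> bool:
    return len(group) >= min_major_bins


def order_bins_greedy(group: Sequence[str], rf: RfMatrix) -> list[str]:
    """Nearest-neighbor chain ordering of one group's bins.

    Seed with the pair at minimal recombination fraction (ties to the
    earliest pair in bin-id order), then repeatedly attach the unplaced bin
    with minimal fraction to either chain end; on ties the left end wins,
    then the earlier bin id.
    """
    group = list(group)
    if len(group) <= 2:
        return group
    idx = [rf.index(b) for b in group]
    sub = rf.r[np.ix_(idx, idx)].copy()
    sub = np.nan_to_num(sub, nan=np.inf)
    np.fill_diagonal(sub, np.inf)
    k = len(group)
    # seed pair: minimal r, ties by (i, j) position (bin creation order)
    best = (np.inf, 0, 1)
    for i in range(k):
        for j in range(i + 1, k):
            if sub[i, j] < best[0]:
                best = (sub[i, j], i, j)
    chain = [best[1], best[2]]
    unplaced = [i for i in range(k) if i not in chain]
    while unplaced:
        cand = (np.inf, 1, 0)  # (r, end_priority 0=left, bin position)
        for b in unplaced:
            for end_pri, end in ((0, chain[0]), (1, chain[-1])):
                key = (sub[b, end], end_pri, b)
                if key < cand:
                    cand = key
        _, end_pri, b = cand
        if end_pri == 0:
            chain.insert(0, b)
        else:
            chain.append(b)
        unplaced.remove(b)
    return [group[i] for i in chain]


def _ordered_matrix(binset: BinSet, order: Sequence[str]) -> np.ndarray:
    return binset.consensus_matrix(list(order))


def order_objective(D: np.ndarray) -> int:
    """Total recombination events implied by an ordered dosage matrix: the
    sum over individuals (columns) of minimum crossover counts.

    Missing entries are skipped per column; implemented by forward-filling
    each column with its last observed dosage, which leaves zero-steps at
    missing rows and the compressed-sequence steps elsewhere.
    """
    D = np.asarray(D)
    if D.size == 0 or D.shape[0] < 2:
        return 0
    if not (D == MISSING).any():
        return int(np.abs(np.diff(D.astype(np.int64), axis=0)).sum())
    n, m = D.shape
    valid = D != MISSING
    idx = np.where(valid, np.arange(n)[:, None], -1)
    idx = np.maximum.accumulate(idx, axis=0)
    first = np.argmax(valid, axis=0)  # first observed row per column
    idx = np.where(idx >= 0, idx, first[None, :])
    filled = D[idx, np.arange(m)[None, :]].astype(np.int64)
    all_missing = ~valid.any(axis=0)
    if all_missing.any():
        filled[:, all_missing] = 0
    return int(np.abs(np.diff(filled, axis=0)).sum())


def _adjacent_r(binset: BinSet, order: Sequence[str]) -> list[float]:
    from .recomb import em_rf, pair_counts

    D = _ordered_matrix(binset, order)
    out = []
    for k in range(len(order) - 1):
        out.append(em_rf(pair_counts(D[k], D[k + 1])).r_hat)
    return out


def refine_order(
    order: Sequence[str],
    panel: GenotypePanel,
    binset: BinSet,
    window: int = 4,
    min_major_bins: int = 21,
) -> LinkageGroupDraft:
    """Local search over an ordered group, minimizing total crossovers.

    Tries every permutation within each sliding window of ``window`` bins
    and every 2-opt segment reversal, accepting strict improvements in a
    deterministic scan, until a full pass yields none.  The result's
    objective never exceeds the input's.
    """
    cur = list(order)
    n = len(cur)
    D = _ordered_matrix(binset, cur)
    best_obj = order_objective(D)
    if n > 2:
        improved = True
        while improved:
            improved = False
            w = min(window, n)
            for start in range(0, n - w + 1):
                base = list(range(n))
                for perm in permutations(range(start, start + w)):
                    if list(perm) == list(range(start, start + w)):
                        continue
                    trial_idx = base[:start] + list(perm) + base[start + w:]
                    obj = order_objective(D[trial_idx])
                    if obj < best_obj:
                        cur = [cur[i] for i in trial_idx]
                        D = D[trial_idx]
                        best_obj = obj
                        improved = True
            for i in range(n - 1):
                for j in range(i + 1, n):
                    trial_idx = list(range(i)) + list(range(j, i - 1 if i else -1, -1)) + list(range(j + 1, n))
                    obj = order_objective(D[trial_idx])
                    if obj < best_obj:
                        cur = [cur[k] for k in trial_idx]
                        D = D[trial_idx]
                        best_obj = obj
                        improved = True
            # segment relocation (length 1-3, both orientations)
            for seg_len in (1, 2, 3):
                for i in range(n - seg_len + 1):
                    seg = list(range(i, i + seg_len))
                    rest = [k for k in range(n) if k not in seg]
                    accepted = False
                    for pos in range(len(rest) + 1):
                        for piece in (seg, seg[::-1]):
                            trial_idx = rest[:pos] + piece + rest[pos:]
                            if trial_idx == list(range(n)):
                                continue
                            obj = order_objective(D[trial_idx])
                            if obj < best_obj:
                                cur = [cur[k] for k in trial_idx]
                                D = D[trial_idx]
                                best_obj = obj
                                improved = True
                                accepted = True
                                break
                        if accepted:
                            break
    return LinkageGroupDraft(
        bin_ids=cur,
        adjacent_r=_adjacent_r(binset, cur),
        objective=best_obj,
        major=is_major(cur, min_major_bins),
    )


def brute_force_order(
    group: Sequence[str], panel: GenotypePanel, binset: BinSet
) -> list[str]:
    """Exhaustive-search ordering oracle for small groups (<= 9 bins).

    Minimizes the same total-crossover objective over all permutations;
    ties resolve to the lexicographically smallest bin-id sequence (which
    also canonicalizes the reversal pair)."""
    group = list(group)
    if len(group) > 9:
        raise ValueError("brute-force ordering is limited to 9 bins")
    if len(group) <= 1:
        return group
    ids = sorted(group)
    D = _ordered_matrix(binset, ids)
    best_perm: tuple[int, ...] | None = None
    best_obj = None
    for perm in permutations(range(len(ids))):
        obj = order_objective(D[list(perm)])
        if best_obj is None or obj < best_obj:
            best_obj = obj
            best_perm = perm
    return [ids[i] for i in best_perm]


def flag_double_recombinants(
    group: LinkageGroupDraft | Sequence[str],
    panel: GenotypePanel,
    binset: BinSet,
) -> list[tuple[str, str]]:
    """Flag (individual_id, bin_id) pairs showing an x-y-x dosage pattern:
    an interior bin whose non-missing dosage differs from equal non-missing
    dosages at both flanking bins — the signature of a double recombination
    event around a single bin, typically a genotyping error."""
    order = group.bin_ids if isinstance(group, LinkageGroupDraft) else list(group)
    if len(order) < 3:
        return []
    D = _ordered_matrix(binset, order)
    left, mid, right = D[:-2], D[1:-1], D[2:]
    hit = (
        (left == right)
        & (left != MISSING)
        & (mid != MISSING)
        & (mid != left)
    )
    flags = [
        (panel.individual_ids[j], order[k + 1])
        for k, j in zip(*np.nonzero(hit))
    ]
    flags.sort(key=lambda t: (order.index(t[1]), t[0]))
    return flags


def apply_corrections(
    panel: GenotypePanel,
    corrections: str | Path | Iterable[tuple[str, str, str]],
    dialect: Mapping[str, int | None] | None = None,
) -> GenotypePanel:
    """Apply user-supplied genotype corrections (marker_id, individual_id,
    new_code) and return a new panel.  Codes use the panel dialect."""
    from .panel_io import DEFAULT_DIALECT

    codes = dict(DEFAULT_DIALECT if dialect is None else dialect)
    if isinstance(corrections, (str, Path)):
        with Path(corrections).open(newline="") as fh:
            rows = [tuple(r[:3]) for r in csv.reader(fh, delimiter="\t") if r]
        if rows and rows[0] == ("marker_id", "individual_id", "new_code"):
            rows = rows[1:]
    else:
        rows = [tuple(r) for r in corrections]
    dosages = panel.dosages.copy()
    ind_index = {s: j for j, s in enumerate(panel.individual_ids)}
    for marker_id, individual_id, code in rows:
        if code not in codes:
            raise ValueError(f"unknown genotype code {code!r} in corrections")
        if individual_id not in ind_index:
            raise ValueError(f"unknown individual {individual_id!r} in corrections")
        d = codes[code]
        dosages[panel.marker_index(marker_id), ind_index[individual_id]] = (
            MISSING if d is None else d
        )
    return GenotypePanel(
        marker_ids=list(panel.marker_ids),
        individual_ids=list(panel.individual_ids),
        dosages=dosages,
        sequences=dict(panel.sequences),
    )
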