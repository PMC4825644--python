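"""Synthetic cross and tag-evolution generators.

The cross simulator emulates the statistical structure of a selfed-F2
mapping population from two fully homozygous strains:

* parents carry opposite alleles at every marker, the F1 is heterozygous
  everywhere, and each F2 is the union of two independent F1 gametes
  (egg and sperm from two independent meioses of the same F1);
* under the default *obligate chiasma* model each bivalent receives
  exactly one chiasma, at a position drawn uniformly (in cM) over the
  chromosome's marker span, and each gamete inherits the crossover with
  probability 1/2 — so crossovers per gamete are 0 or 1, events per
  F2 per chromosome are 2:1:0 in a 1:2:1 ratio, and the expected genetic
  length per chromosome is 50 cM regardless of the nominal span;
* a Poisson model (no interference, count ~ Poisson(span/100)) is
  available for comparison;
* marker positions are uniform or "tip_clustered" (a fraction of markers
  piled into the terminal 1 cM of one end, emulating the marker pile-up at
  the tips of acrocentric chromosomes, where the centromere suppresses
  recombination);
* symmetric genotyping noise is applied last: each call is miscalled to a
  uniformly chosen different state with probability ``error_rate``, then
  set missing with probability ``missing_rate``.  All noise is logged.

Every random draw flows from one :class:`numpy.random.Generator` seeded
from ``SimConfig.seed``, so outputs are bit-reproducible.

Defaults mirror the mapping study's design: 24 chromosomes, 49 F2
individuals, 50 markers per chromosome over a 50 cM span with 30% of
markers tip-clustered, 1% genotyping error and 2% missing calls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .panel_io import MISSING, GenotypePanel
from .phylo import Node, PhyloTree, TagMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_cross",
    "simulate_tag_evolution",
    "simulate_snp_alignment",
]


@dataclass
class SimConfig:
    n_chromosomes: int = 24
    markers_per_chromosome: int | Sequence[int] = 50
    chromosome_length_cM: float = 50.0
    marker_placement: str = "tip_clustered"  # or "uniform"
    tip_cluster_fraction: float = 0.3
    tip_cluster_span_cM: float = 1.0
    marker_positions: Sequence[Sequence[float]] | None = None
    n_f2: int = 49
    chiasma_model: str = "obligate"  # or "poisson"
    error_rate: float = 0.01
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for name in ("error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.chiasma_model not in ("obligate", "poisson"):
            raise ValueError(f"unknown chiasma model {self.chiasma_model!r}")
        if self.marker_placement not in ("uniform", "tip_clustered"):
            raise ValueError(f"unknown marker placement {self.marker_placement!r}")
        if self.marker_positions is not None:
            for c, pos in enumerate(self.marker_positions):
                if any(b < a for a, b in zip(pos, list(pos)[1:])):
                    raise ValueError(f"chromosome {c}: positions must be non-decreasing")

    def markers_on(self, c: int) -> int:
        if self.marker_positions is not None:
            return len(self.marker_positions[c])
        if isinstance(self.markers_per_chromosome, int):
            return self.markers_per_chromosome
        return self.markers_per_chromosome[c]


@dataclass
class SimTruth:
    """Hidden state of a simulated cross, for recovery tests.

    ``crossover_counts`` is (n_chromosomes, n_f2, 2) — crossovers per
    gamete; ``crossover_positions`` mirrors it with per-gamete position
    lists.  Error and missing logs record (marker_id, individual_id,
    original_dosage) for every perturbed call.
    """

    marker_chromosome: dict[str, int]
    marker_position_cM: dict[str, float]
    crossover_counts: np.ndarray
    crossover_positions: list[list[tuple[list[float], list[float]]]]
    error_log: list[tuple[str, str, int]] = field(default_factory=list)
    missing_log: list[tuple[str, str, int]] = field(default_factory=list)

    def events_per_individual(self) -> np.ndarray:
        """(n_chromosomes, n_f2) total crossovers per homolog pair."""
        return self.crossover_counts.sum(axis=2)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "marker_chromosome": self.marker_chromosome,
            "marker_position_cM": self.marker_position_cM,
            "crossover_counts": self.crossover_counts.tolist(),
            "crossover_positions": self.crossover_positions,
            "error_log": self.error_log,
            "missing_log": self.missing_log,
        }
        Path(path).write_text(json.dumps(payload))


def _positions(config: SimConfig, c: int, rng: np.random.Generator) -> np.ndarray:
    if config.marker_positions is not None:
        return np.asarray(config.marker_positions[c], dtype=float)
    m = config.markers_on(c)
    L = config.chromosome_length_cM
    if config.marker_placement == "uniform":
        pos = rng.uniform(0.0, L, size=m)
    else:
        n_tip = int(round(config.tip_cluster_fraction * m))
        tip = rng.uniform(0.0, min(config.tip_cluster_span_cM, L), size=n_tip)
        body = rng.uniform(0.0, L, size=m - n_tip)
        pos = np.concatenate([tip, body])
    return np.sort(pos)


def simulate_cross(config: SimConfig) -> tuple[GenotypePanel, SimTruth]:
    """Simulate a selfed-F2 genotype panel plus its hidden truth."""
    rng = np.random.default_rng(config.seed)
    n_f2 = config.n_f2
    n_chrom = config.n_chromosomes

    marker_ids: list[str] = []
    marker_chrom: dict[str, int] = {}
    marker_pos: dict[str, float] = {}
    blocks: list[np.ndarray] = []
    xo_counts = np.zeros((n_chrom, n_f2, 2), dtype=int)
    xo_positions: list[list[tuple[list[float], list[float]]]] = []

    for c in range(n_chrom):
        pos = _positions(config, c, rng)
        m = len(pos)
        ids = [f"c{c + 1:02d}m{k + 1:04d}" for k in range(m)]
        marker_ids.extend(ids)
        for mid, p in zip(ids, pos):
            marker_chrom[mid] = c
            marker_pos[mid] = float(p)

        lo, hi = (float(pos.min()), float(pos.max())) if m else (0.0, 0.0)
        span = hi - lo
        # gamete haplotypes: (m, n_f2, 2) boolean, True = paternal allele
        start = rng.random((n_f2, 2)) < 0.5
        chrom_positions: list[tuple[list[float], list[float]]] = []
        if config.chiasma_model == "obligate":
            chiasma = rng.uniform(lo, hi, size=(n_f2, 2)) if span > 0 else np.full((n_f2, 2), lo)
            inherit = rng.random((n_f2, 2)) < 0.5
            hap = start[None, :, :] ^ (inherit[None, :, :] & (pos[:, None, None] > chiasma[None, :, :]))
            xo_counts[c] = inherit.astype(int)
            for i in range(n_f2):
                chrom_positions.append(
                    tuple(
                        [float(chiasma[i, g])] if inherit[i, g] else []
                        for g in (0, 1)
                    )
                )
        else:  # poisson
            hap = np.empty((m, n_f2, 2), dtype=bool)
            for i in range(n_f2):
                per_gamete: list[list[float]] = []
                for g in (0, 1):
                    k = rng.poisson(span / 100.0)
                    breaks = np.sort(rng.uniform(lo, hi, size=k))
                    per_gamete.append([float(b) for b in breaks])
                    n_before = np.searchsorted(breaks, pos, side="left")
                    hap[:, i, g] = start[i, g] ^ (n_before % 2 == 1)
                    xo_counts[c, i, g] = k
                chrom_positions.append((per_gamete[0], per_gamete[1]))
        xo_positions.append(chrom_positions)
        blocks.append(hap.sum(axis=2).astype(np.int8))  # paternal-allele dosage

    dosages = np.concatenate(blocks, axis=0) if blocks else np.empty((0, n_f2), np.int8)
    individual_ids = [f"F2_{i + 1:03d}" for i in range(n_f2)]

    error_log: list[tuple[str, str, int]] = []
    missing_log: list[tuple[str, str, int]] = []
    if config.error_rate > 0:
        mask = rng.random(dosages.shape) < config.error_rate
        shifts = rng.integers(1, 3, size=dosages.shape)
        for i, j in np.argwhere(mask):
            error_log.append((marker_ids[i], individual_ids[j], int(dosages[i, j])))
            dosages[i, j] = (dosages[i, j] + shifts[i, j]) % 3
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        for i, j in np.argwhere(mask):
            missing_log.append((marker_ids[i], individual_ids[j], int(dosages[i, j])))
            dosages[i, j] = MISSING

    panel = GenotypePanel(
        marker_ids=marker_ids, individual_ids=individual_ids, dosages=dosages
    )
    truth = SimTruth(
        marker_chromosome=marker_chrom,
        marker_position_cM=marker_pos,
        crossover_counts=xo_counts,
        crossover_positions=xo_positions,
        error_log=error_log,
        missing_log=missing_log,
    )
    return panel, truth


# ---------------------------------------------------------------------------
# tag / SNP evolution on a small tree
# ---------------------------------------------------------------------------

def _as_tree(topology: PhyloTree | str) -> PhyloTree:
    return topology if isinstance(topology, PhyloTree) else PhyloTree.from_newick(topology)


def simulate_tag_evolution(
    topology: PhyloTree | str,
    n_root_tags: int,
    loss_rate_per_unit: float,
    seed: int | None = None,
) -> TagMatrix:
    """Evolve tag presence along a tree: the root carries ``n_root_tags``
    tags and each surviving tag is lost independently along a branch of
    length t with probability 1 - exp(-loss_rate * t).  Returns the leaf
    presence matrix (tags absent everywhere dropped)."""
    if loss_rate_per_unit < 0:
        raise ValueError("loss rate must be non-negative")
    tree = _as_tree(topology)
    rng = np.random.default_rng(seed)
    leaves: dict[str, np.ndarray] = {}

    def walk(node: Node, present: np.ndarray):
        p_loss = 1.0 - np.exp(-loss_rate_per_unit * max(node.length, 0.0))
        present = present & (rng.random(n_root_tags) >= p_loss)
        if node.is_leaf:
            leaves[node.name] = present
        for child in node.children:
            walk(child, present)

    root_present = np.ones(n_root_tags, dtype=bool)
    for child in tree.root.children:
        walk(child, root_present)
    taxa = sorted(leaves)
    tm = TagMatrix(
        taxa=taxa,
        tags=[f"tag{k + 1:06d}" for k in range(n_root_tags)],
        present=np.stack([leaves[t] for t in taxa]),
    )
    return tm.drop_all_absent()


_BASES = np.frombuffer(b"AGCT", dtype="S1")  # 0=A 1=G 2=C 3=T
_TS_PARTNER = np.array([1, 0, 3, 2])  # A<->G, C<->T
_TV_PARTNERS = np.array([[2, 3], [2, 3], [0, 1], [0, 1]])


def _k2p_site_probs(t: float, alpha: float, beta: float) -> tuple[float, float, float]:
    """(p_same, p_transition, p_each_transversion) after time t under K2P
    with transition rate alpha and per-transversion rate beta."""
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # each of the two transversion targets
    return 1.0 - p_ts - 2.0 * p_tv, p_ts, p_tv


def simulate_snp_alignment(
    topology: PhyloTree | str,
    n_sites: int,
    transition_rate: float,
    transversion_rate: float,
    seed: int | None = None,
) -> dict[str, str]:
    """Simulate site-independent K2P evolution along a tree from a uniform
    random root sequence; returns taxon -> sequence."""
    if transition_rate < 0 or transversion_rate < 0:
        raise ValueError("substitution rates must be non-negative")
    tree = _as_tree(topology)
    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, size=n_sites)
    leaves: dict[str, np.ndarray] = {}

    def evolve(seq: np.ndarray, t: float) -> np.ndarray:
        p_same, p_ts, p_tv = _k2p_site_probs(t, transition_rate, transversion_rate)
        u = rng.random(n_sites)
        out = seq.copy()
        ts = u < p_ts
        tv1 = (u >= p_ts) & (u < p_ts + p_tv)
        tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
        out[ts] = _TS_PARTNER[seq[ts]]
        out[tv1] = _TV_PARTNERS[seq[tv1], 0]
        out[tv2] = _TV_PARTNERS[seq[tv2], 1]
        return out

    def walk(node: Node, seq: np.ndarray):
        seq = evolve(seq, max(node.length, 0.0))
        if node.is_leaf:
            leaves[node.name] = seq
        for child in node.children:
            walk(child, seq)

    for child in tree.root.children:
        walk(child, root)
    return {
        t: _BASES[leaves[t]].tobytes().decode() for t in sorted(leaves)
    }
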