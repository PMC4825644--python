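"""RAD-tag phylogenetics: presence/absence and concatenated-SNP distances,
neighbor-joining, and bootstrap support.

Restriction-site mutations make whole RAD-tags disappear from a lineage,
so the count of tags present in exactly one of two strains (the symmetric
difference of their tag sets) serves as a genetic distance.  Tags shared
by all strains additionally provide SNP columns; concatenated SNPs are
compared with the Kimura 2-parameter distance, which separates transition
and transversion proportions:

    d = -1/2 ln( (1 - 2P - Q) * sqrt(1 - 2Q) )

Trees are built by neighbor-joining (Q-criterion agglomeration with the
standard branch-length formulas); negative branch lengths are clamped to
zero with the subtraction shifted onto the sibling edge.  Support values
come from resampling characters (tags or sites) with replacement and
counting how often each internal split of the full-data tree reappears.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "TagMatrix",
    "DistanceMatrix",
    "Node",
    "PhyloTree",
    "strain_consensus_tags",
    "presence_distance",
    "k2p_distance",
    "concatenate_snps",
    "nj_tree",
    "bootstrap_support",
]

# per-individual tag states: 0 = absent, -1 = present but heterozygous,
# k >= 1 = homozygous for allele k
ABSENT = 0
HET = -1


@dataclass
class TagMatrix:
    """Taxa x tags boolean presence grid."""

    taxa: list[str]
    tags: list[str]
    present: np.ndarray  # (n_taxa, n_tags) bool

    def __post_init__(self):
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != (len(self.taxa), len(self.tags)):
            raise ValueError("presence grid shape does not match taxa x tags")

    def drop_all_absent(self) -> "TagMatrix":
        keep = self.present.any(axis=0)
        return TagMatrix(
            taxa=list(self.taxa),
            tags=[t for t, k in zip(self.tags, keep) if k],
            present=self.present[:, keep],
        )


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance grid shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")

    def to_phylip(self) -> str:
        lines = [f" {len(self.taxa)}"]
        for name, row in zip(self.taxa, self.d):
            lines.append(name.ljust(12) + " ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# tree structure
# ---------------------------------------------------------------------------

@dataclass
class Node:
    name: str | None = None
    length: float = 0.0
    children: list["Node"] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]


@dataclass
class PhyloTree:
    """Unrooted tree (rooted representation at a trifurcating root node)."""

    root: Node

    @property
    def taxa(self) -> list[str]:
        return sorted(lf.name for lf in self.root.leaves())

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each encoded as the side *not*
        containing the alphabetically first taxon."""
        all_taxa = frozenset(self.taxa)
        ref = min(all_taxa)
        out: set[frozenset[str]] = set()

        def walk(node: Node):
            names = frozenset(lf.name for lf in node.leaves())
            if 2 <= len(names) <= len(all_taxa) - 2:
                side = names if ref not in names else all_taxa - names
                out.add(side)
            for c in node.children:
                walk(c)

        for c in self.root.children:
            walk(c)
        return out

    def normalize_split(self, names) -> frozenset[str]:
        """Canonical encoding of a bipartition side: the side not containing
        the alphabetically first taxon."""
        all_taxa = frozenset(self.taxa)
        side = frozenset(names)
        return side if min(all_taxa) not in side else all_taxa - side

    def has_split(self, names) -> bool:
        return self.normalize_split(names) in self.splits()

    def attach_supports(self, support: Mapping[frozenset[str], float]) -> None:
        all_taxa = frozenset(self.taxa)
        ref = min(all_taxa)

        def walk(node: Node):
            if not node.is_leaf:
                names = frozenset(lf.name for lf in node.leaves())
                if 2 <= len(names) <= len(all_taxa) - 2:
                    side = names if ref not in names else all_taxa - names
                    if side in support:
                        node.support = support[side]
            for c in node.children:
                walk(c)

        for c in self.root.children:
            walk(c)

    def to_newick(self, include_support: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if include_support and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}:{node.length:.6f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def path_lengths(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length matrix (patristic distances)."""
        taxa = self.taxa
        idx = {t: i for i, t in enumerate(taxa)}
        n = len(taxa)
        d = np.zeros((n, n))

        def walk(node: Node) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            sub = [
                {t: v + c.length for t, v in walk(c).items()} for c in node.children
            ]
            for a in range(len(sub)):
                for b in range(a + 1, len(sub)):
                    for ta, va in sub[a].items():
                        for tb, vb in sub[b].items():
                            d[idx[ta], idx[tb]] = d[idx[tb], idx[ta]] = va + vb
            merged: dict[str, float] = {}
            for s in sub:
                merged.update(s)
            return merged

        walk(self.root)
        return DistanceMatrix(taxa=taxa, d=d)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")

        def convert(dnode) -> Node:
            return Node(
                name=dnode.taxon.label if dnode.taxon else None,
                length=float(dnode.edge.length or 0.0),
                children=[convert(c) for c in dnode.child_nodes()],
            )

        root = convert(tree.seed_node)
        root.length = 0.0
        return cls(root=root)


# ---------------------------------------------------------------------------
# strain consensus filtering
# ---------------------------------------------------------------------------

def strain_consensus_tags(
    tag_table: np.ndarray,
    individual_strains: Sequence[str],
    tag_ids: Sequence[str],
    max_missing_per_strain: Mapping[str, int],
) -> TagMatrix:
    """Collapse a per-individual tag table into per-strain presence calls.

    ``tag_table`` is (n_individuals, n_tags) with states 0 = absent,
    -1 = present-heterozygous, k >= 1 = homozygous allele k.  Per strain a
    tag is discarded when it is missing in at least the strain's threshold
    of individuals, when its homozygous alleles differ among the strain's
    individuals (polymorphic within strain), or when any individual is
    heterozygous for it.  Surviving tags with at least one present
    individual are called present for the strain; a tag is retained
    globally if retained in at least one strain.
    """
    tag_table = np.asarray(tag_table)
    strains = sorted(set(individual_strains))
    unknown = set(max_missing_per_strain) - set(strains)
    missing_thr = set(strains) - set(max_missing_per_strain)
    if missing_thr:
        raise ValueError(f"no missing-tag threshold for strain(s) {sorted(missing_thr)}")
    rows = []
    for strain in strains:
        members = [i for i, s in enumerate(individual_strains) if s == strain]
        sub = tag_table[members]  # (n_members, n_tags)
        n_missing = (sub == ABSENT).sum(axis=0)
        any_het = (sub == HET).any(axis=0)
        # polymorphic within strain: >1 distinct homozygous allele
        alleles = np.where(sub >= 1, sub, 0)
        amax = alleles.max(axis=0)
        poly = ((alleles != amax[None, :]) & (alleles > 0)).any(axis=0)
        discard = (n_missing >= max_missing_per_strain[strain]) | any_het | poly
        present = ~discard & (sub >= 1).any(axis=0)
        rows.append(present)
    present = np.stack(rows)
    tm = TagMatrix(taxa=strains, tags=list(tag_ids), present=present)
    return tm.drop_all_absent()


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def presence_distance(tags: TagMatrix, asymmetric_reference: str | None = None) -> DistanceMatrix:
    """Number of tags present in exactly one of each taxon pair (symmetric
    difference).  With ``asymmetric_reference`` set, d[i][j] instead counts
    tags present in taxon i but absent in taxon j only when i is the
    reference row (sensitivity-analysis variant, symmetrized by max)."""
    if len(tags.taxa) < 2:
        raise ValueError("need at least two taxa")
    P = tags.present.astype(np.int64)
    if asymmetric_reference is None:
        d = np.abs(P[:, None, :] - P[None, :, :]).sum(axis=2).astype(float)
    else:
        one_way = (P[:, None, :] & ~tags.present[None, :, :]).sum(axis=2)
        d = np.maximum(one_way, one_way.T).astype(float)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(taxa=list(tags.taxa), d=d)


_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


def k2p_distance(alignment: Mapping[str, str]) -> DistanceMatrix:
    """Kimura 2-parameter distance on a taxa x sites alignment.

    Sites with a non-ACGT character in either sequence of a pair are
    excluded pairwise.  Saturated pairs (log/sqrt argument <= 0) raise an
    error naming the pair.
    """
    taxa = list(alignment)
    seqs = {t: alignment[t].upper() for t in taxa}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise ValueError("alignment sequences differ in length")
    n = len(taxa)
    d = np.zeros((n, n))
    enc = {t: np.frombuffer(seqs[t].encode(), dtype="S1") for t in taxa}
    valid = {t: np.isin(enc[t], [b"A", b"C", b"G", b"T"]) for t in taxa}
    purine = {t: np.isin(enc[t], [b"A", b"G"]) for t in taxa}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = taxa[i], taxa[j]
            ok = valid[a] & valid[b]
            m = int(ok.sum())
            if m == 0:
                raise ValueError(f"no comparable sites between {a!r} and {b!r}")
            diff = (enc[a] != enc[b]) & ok
            ts = diff & (purine[a] == purine[b])  # within purines or pyrimidines
            P = float(ts.sum()) / m
            Q = float((diff & ~ts).sum()) / m
            arg1 = 1.0 - 2.0 * P - Q
            arg2 = 1.0 - 2.0 * Q
            if arg1 <= 0 or arg2 <= 0:
                raise ValueError(
                    f"K2P distance undefined for pair ({a!r}, {b!r}): "
                    f"P={P:.4f}, Q={Q:.4f} (saturation)"
                )
            d[i, j] = d[j, i] = -0.5 * math.log(arg1 * math.sqrt(arg2))
    return DistanceMatrix(taxa=taxa, d=d)


def concatenate_snps(tag_sequences: Mapping[str, Mapping[str, str]]) -> dict[str, str]:
    """Concatenate polymorphic columns from tags shared by all taxa.

    ``tag_sequences`` maps taxon -> (tag id -> sequence).  Tags are taken
    in sorted id order; within each shared tag, columns with two or more
    distinct unambiguous bases across taxa are kept.  Returns taxon ->
    concatenated SNP string (with a warning if empty).
    """
    taxa = list(tag_sequences)
    shared = sorted(set.intersection(*(set(tag_sequences[t]) for t in taxa)))
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    for tag in shared:
        seqs = [tag_sequences[t][tag].upper() for t in taxa]
        if len({len(s) for s in seqs}) > 1:
            raise ValueError(f"tag {tag!r}: sequence lengths differ among taxa")
        for col in range(len(seqs[0])):
            states = {s[col] for s in seqs if s[col] in _VALID}
            if len(states) >= 2:
                for t, s in zip(taxa, seqs):
                    parts[t].append(s[col])
    out = {t: "".join(parts[t]) for t in taxa}
    if shared and not out[taxa[0]]:
        warnings.warn("no polymorphic columns among shared tags; alignment is empty")
    return out


# ---------------------------------------------------------------------------
# neighbor-joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Standard neighbor-joining (Saitou-Nei with the usual Q criterion).

    Branch lengths for a joined pair are ``l_i = d_ij/2 + (R_i - R_j)/(2(n-2))``;
    a negative length is clamped to zero and the deficit moved to the
    sibling edge.  The final three nodes are resolved exactly.  Ties in the
    Q matrix resolve to the smallest (i, j) index pair, with nodes kept in
    input taxon order, so the output is deterministic.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor-joining needs at least three taxa")
    nodes: list[Node] = [Node(name=t) for t in dm.taxa]
    # tie-break key: smallest leaf label in each working cluster, so the
    # result does not depend on taxon input order
    keys: list[str] = list(dm.taxa)
    D = dm.d.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        R = D.sum(axis=1)
        Q = (m - 2) * D - R[:, None] - R[None, :]
        iu, ju = np.triu_indices(m, k=1)
        vals = Q[iu, ju]
        tied = vals <= vals.min()
        i, j = min(
            ((int(a), int(b)) for a, b in zip(iu[tied], ju[tied])),
            key=lambda ij: tuple(sorted((keys[ij[0]], keys[ij[1]]))),
        )
        li = D[i, j] / 2.0 + (R[i] - R[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        a, b = nodes[i], nodes[j]
        a.length, b.length = li, lj
        parent = Node(children=[a, b])
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        D2[-1, : m - 2] = D2[: m - 2, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    # exact three-node resolution
    a, b, c = nodes
    la = (D[0, 1] + D[0, 2] - D[1, 2]) / 2.0
    lb = (D[0, 1] + D[1, 2] - D[0, 2]) / 2.0
    lc = (D[0, 2] + D[1, 2] - D[0, 1]) / 2.0
    a.length, b.length, c.length = max(la, 0.0), max(lb, 0.0), max(lc, 0.0)
    return PhyloTree(root=Node(children=[a, b, c]))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _resample(data, cols: np.ndarray):
    if isinstance(data, TagMatrix):
        return TagMatrix(
            taxa=list(data.taxa),
            tags=[data.tags[c] for c in cols],
            present=data.present[:, cols],
        )
    # alignment: Mapping[str, str]
    return {t: "".join(s[c] for c in cols) for t, s in data.items()}


def bootstrap_support(
    data: TagMatrix | Mapping[str, str],
    builder: Callable[[object], PhyloTree],
    B: int = 10000,
    seed: int | None = None,
) -> PhyloTree:
    """Column bootstrap: resample tags or alignment sites with replacement
    ``B`` times, rebuild the tree, and report for each internal split of
    the full-data tree the percentage of replicates containing it."""
    if B < 1:
        raise ValueError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    tree = builder(data)
    ref_splits = tree.splits()
    counts = {s: 0 for s in ref_splits}
    n_cols = len(data.tags) if isinstance(data, TagMatrix) else len(next(iter(data.values())))
    for _ in range(B):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep = builder(_resample(data, cols))
        for s in rep.splits():
            if s in counts:
                counts[s] += 1
    support = {s: 100.0 * c / B for s, c in counts.items()}
    tree.attach_supports(support)
    return tree
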