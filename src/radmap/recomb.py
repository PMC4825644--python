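"""Recombination-fraction estimation for coupling-phase codominant F2 pairs.

Both parental strains are fully homozygous for opposite alleles, so the F1
carries all paternal alleles on one homolog (coupling phase).  For a pair
of loci with recombination fraction ``r``, F1 gametes are parental with
probability ``(1-r)/2`` each and recombinant with probability ``r/2`` each,
and an F2 individual is the union of two independent gametes.  Writing the
genotype at each locus as the paternal-allele dosage (0/1/2), the nine
two-locus classes have probabilities::

    (2,2), (0,0)                     : ((1-r)/2)^2
    (2,0), (0,2)                     : (r/2)^2
    (2,1), (1,2), (1,0), (0,1)       : r(1-r)/2
    (1,1)                            : ((1-r)^2 + r^2) / 2

Every class except the double heterozygote carries a known recombinant-
gamete count (|d1 - d2|); the double heterozygote is a mixture of
parental/parental and recombinant/recombinant gamete pairs contributing
``2 r^2 / ((1-r)^2 + r^2)`` expected recombinant gametes.  The EM iteration

    r  <-  [ S_fixed + n11 * 2 r^2 / ((1-r)^2 + r^2) ] / (2 N)

from r0 = 0.25 converges to the maximum-likelihood estimate on [0, 0.5].
A naive count estimator (double heterozygotes counted as non-recombinant)
is available via ``method="count"`` for sensitivity analysis.

LOD is reported in base 10 against the r = 0.5 (free recombination) null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .binning import BinSet
from .panel_io import MISSING

__all__ = [
    "PairCounts",
    "RfEstimate",
    "RfMatrix",
    "pair_counts",
    "em_rf",
    "count_rf",
    "estimate_rf",
    "rf_matrix",
    "class_probabilities",
    "min_crossovers",
]

# fixed recombinant-gamete count per (d1, d2) class; (1,1) handled by EM
_FIXED = np.abs(np.subtract.outer(np.arange(3), np.arange(3))).astype(float)


@dataclass(frozen=True)
class PairCounts:
    """3x3 grid of jointly non-missing individuals, indexed by dosage."""

    n: np.ndarray  # (3, 3) non-negative ints; n[d1, d2]

    def __post_init__(self):
        object.__setattr__(self, "n", np.asarray(self.n, dtype=np.int64))
        if self.n.shape != (3, 3) or (self.n < 0).any():
            raise ValueError("pair counts must be a 3x3 grid of non-negative integers")

    @property
    def total(self) -> int:
        return int(self.n.sum())


@dataclass(frozen=True)
class RfEstimate:
    r_hat: float
    lod: float
    n_informative: int
    converged: bool


@dataclass
class RfMatrix:
    """All-pairs recombination fractions between bins.

    ``r`` and ``lod`` are symmetric with NaN diagonal; entries are NaN for
    pairs with no jointly informative individual.
    """

    bin_ids: list[str]
    r: np.ndarray
    lod: np.ndarray
    n: np.ndarray

    def index(self, bin_id: str) -> int:
        try:
            return self._idx[bin_id]
        except AttributeError:
            self._idx = {b: i for i, b in enumerate(self.bin_ids)}
            return self._idx[bin_id]


def pair_counts(g1: np.ndarray, g2: np.ndarray) -> PairCounts:
    """Tally individuals non-missing at both loci into the 3x3 dosage grid."""
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.shape != g2.shape:
        raise ValueError(f"genotype vectors differ in length: {g1.shape} vs {g2.shape}")
    ok = (g1 != MISSING) & (g2 != MISSING)
    n = np.zeros((3, 3), dtype=np.int64)
    np.add.at(n, (g1[ok], g2[ok]), 1)
    return PairCounts(n=n)


def class_probabilities(r: float | np.ndarray) -> np.ndarray:
    """Probabilities of the nine (d1, d2) classes at recombination fraction r;
    shape (..., 3, 3), summing to 1."""
    r = np.asarray(r, dtype=float)
    c = (1.0 - r) / 2.0
    q = r / 2.0
    p = np.empty(r.shape + (3, 3), dtype=float)
    p[..., 2, 2] = p[..., 0, 0] = c * c
    p[..., 2, 0] = p[..., 0, 2] = q * q
    p[..., 2, 1] = p[..., 1, 2] = p[..., 1, 0] = p[..., 0, 1] = 2 * c * q
    p[..., 1, 1] = 2 * c * c + 2 * q * q
    return p


def _loglik(n: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Multinomial log-likelihood (natural log) of counts ``n`` (..., 3, 3)
    at fractions ``r`` (...)."""
    p = class_probabilities(r)
    with np.errstate(divide="ignore", invalid="ignore"):
        return xlogy(n, p).sum(axis=(-2, -1))


def _em_many(
    S: np.ndarray, n11: np.ndarray, N: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized EM; returns (r_hat, converged) for each element.

    S: fixed recombinant-gamete counts; n11: double-heterozygote counts;
    N: informative totals.  Elements with N == 0 come back NaN.
    """
    S = np.asarray(S, dtype=float)
    n11 = np.asarray(n11, dtype=float)
    N = np.asarray(N, dtype=float)
    r = np.full(N.shape, 0.25)
    converged = np.zeros(N.shape, dtype=bool)
    valid = N > 0
    denom = np.where(valid, 2.0 * N, 1.0)
    for _ in range(max_iter):
        w = 2.0 * r * r / ((1.0 - r) ** 2 + r * r)
        r_new = np.clip((S + n11 * w) / denom, 0.0, 0.5)
        newly = np.abs(r_new - r) < tol
        r = r_new
        converged = newly
        if bool(converged[valid].all()):
            break
    r = np.where(valid, r, np.nan)
    converged = converged & valid
    return r, converged


def _lod(n: np.ndarray, r_hat: np.ndarray) -> np.ndarray:
    ll_hat = _loglik(n, np.asarray(r_hat))
    ll_null = _loglik(n, np.full(np.shape(r_hat), 0.5))
    lod = (ll_hat - ll_null) / np.log(10.0)
    return np.maximum(lod, 0.0)  # exact 0 at r_hat = 0.5 up to rounding


def em_rf(counts: PairCounts, tol: float = 1e-8, max_iter: int = 1000) -> RfEstimate:
    """Maximum-likelihood recombination fraction by EM for one pair."""
    if counts.total == 0:
        raise ValueError("no jointly informative individuals")
    n = counts.n.astype(float)
    S = float((n * _FIXED).sum())
    r, conv = _em_many(np.array([S]), np.array([n[1, 1]]), np.array([counts.total]), tol, max_iter)
    r_hat = float(r[0])
    lod = float(_lod(n[None], np.array([r_hat]))[0])
    return RfEstimate(r_hat=r_hat, lod=lod, n_informative=counts.total, converged=bool(conv[0]))


def count_rf(counts: PairCounts) -> RfEstimate:
    """Naive count estimator: fixed recombinant gametes over 2N, double
    heterozygotes counted as non-recombinant."""
    if counts.total == 0:
        raise ValueError("no jointly informative individuals")
    n = counts.n.astype(float)
    r_hat = float(min((n * _FIXED).sum() / (2.0 * counts.total), 0.5))
    lod = float(_lod(n[None], np.array([r_hat]))[0])
    return RfEstimate(r_hat=r_hat, lod=lod, n_informative=counts.total, converged=True)


def estimate_rf(counts: PairCounts, method: str = "em", **kwargs) -> RfEstimate:
    if method == "em":
        return em_rf(counts, **kwargs)
    if method == "count":
        return count_rf(counts)
    raise ValueError(f"unknown rf method {method!r}")


def rf_matrix(
    binset_or_matrix: BinSet | np.ndarray,
    bin_ids: list[str] | None = None,
    method: str = "em",
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> RfMatrix:
    """All-pairs recombination fractions between bin consensus genotypes.

    Accepts a :class:`BinSet` or a raw (n_bins, n_individuals) dosage matrix
    with -1 for missing.  Pair counts are accumulated with one-hot matrix
    products so the whole matrix is a handful of BLAS calls; the EM runs
    vectorized over the upper triangle.
    """
    if isinstance(binset_or_matrix, BinSet):
        D = binset_or_matrix.consensus_matrix()
        ids = binset_or_matrix.bin_ids
    else:
        D = np.asarray(binset_or_matrix)
        ids = bin_ids if bin_ids is not None else [f"bin{i}" for i in range(D.shape[0])]
    nb = D.shape[0]
    ind = [(D == d).astype(np.float32) for d in (0, 1, 2)]

    counts = np.empty((3, 3, nb, nb), dtype=np.float64)
    for a in range(3):
        for b in range(3):
            counts[a, b] = ind[a] @ ind[b].T
    N = counts.sum(axis=(0, 1))
    S = (counts * _FIXED[:, :, None, None]).sum(axis=(0, 1))
    n11 = counts[1, 1]

    iu, ju = np.triu_indices(nb, k=1)
    if method == "em":
        r_u, conv_u = _em_many(S[iu, ju], n11[iu, ju], N[iu, ju], tol, max_iter)
    elif method == "count":
        with np.errstate(invalid="ignore", divide="ignore"):
            r_u = np.minimum(S[iu, ju] / (2.0 * N[iu, ju]), 0.5)
        r_u = np.where(N[iu, ju] > 0, r_u, np.nan)
        conv_u = N[iu, ju] > 0
    else:
        raise ValueError(f"unknown rf method {method!r}")

    n_pair = np.moveaxis(counts, (0, 1), (-2, -1))[iu, ju]  # (npairs, 3, 3)
    lod_u = np.where(np.isfinite(r_u), _lod(n_pair, np.nan_to_num(r_u, nan=0.5)), np.nan)

    r = np.full((nb, nb), np.nan)
    lod = np.full((nb, nb), np.nan)
    r[iu, ju] = r[ju, iu] = r_u
    lod[iu, ju] = lod[ju, iu] = lod_u
    return RfMatrix(bin_ids=list(ids), r=r, lod=lod, n=N.astype(np.int64))


def min_crossovers(dosages) -> int:
    """Minimum total crossover count (over the two gametes) consistent with
    an ordered dosage sequence: the sum of |step| between consecutive
    non-missing entries.  Missing entries are skipped; all-missing gives 0."""
    d = np.asarray(
        [MISSING if v is None else int(v) for v in dosages], dtype=np.int64
    )
    v = d[d != MISSING]
    if v.size < 2:
        return 0
    return int(np.abs(np.diff(v)).sum())
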