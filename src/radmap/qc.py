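"""Panel-construction QC: individual and marker filters, segregation distortion.

The mapping panel is built from a selfed F2, where every marker is expected
to segregate 1:2:1 (paternal homozygote : heterozygote : maternal
homozygote).  Filtering removes, in this order:

* individuals with too many missing genotypes or anomalously low
  heterozygosity (a selfed-F2 individual should be heterozygous at about
  half its markers; a near-homozygous "F2" is most likely a later selfing
  generation),
* markers with heavy segregation distortion (raw chi-square P below a
  cutoff, no multiple-testing adjustment) and markers missing in too many
  individuals.

Thresholds default to: more than 800 missing markers per individual,
heterozygous fraction below 0.2, distortion P < 1e-4, and more than 7
missing individuals per marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .panel_io import GenotypePanel, MISSING

__all__ = [
    "QCReport",
    "TagAccounts",
    "distortion_test",
    "distortion_pvalues",
    "filter_individuals",
    "filter_markers",
    "tag_accounting",
]


@dataclass
class QCReport:
    """Record of removals along one filtering step."""

    removed_individuals: list[tuple[str, str, float]] = field(default_factory=list)
    removed_markers: list[tuple[str, str, float]] = field(default_factory=list)
    individuals_before: int = 0
    individuals_after: int = 0
    markers_before: int = 0
    markers_after: int = 0

    def __post_init__(self):
        pass

    def validate(self) -> None:
        assert self.individuals_after == self.individuals_before - len(self.removed_individuals)
        assert self.markers_after == self.markers_before - len(self.removed_markers)


@dataclass(frozen=True)
class TagAccounts:
    """Parental RAD-tag bookkeeping: shared - het-within-strain - monomorphic
    = polymorphic markers available for mapping."""

    shared: int
    het_within_strain: int
    monomorphic: int
    polymorphic: int


def tag_accounting(shared: int, het_within: int, monomorphic: int) -> TagAccounts:
    """Account for parental tags: the polymorphic remainder becomes the
    candidate marker set."""
    if min(shared, het_within, monomorphic) < 0:
        raise ValueError("tag counts must be non-negative")
    polymorphic = shared - het_within - monomorphic
    if polymorphic < 0:
        raise ValueError(
            f"negative remainder: shared={shared} < het_within={het_within} "
            f"+ monomorphic={monomorphic}"
        )
    return TagAccounts(shared, het_within, monomorphic, polymorphic)


def distortion_test(counts: tuple[int, int, int]) -> tuple[float, float]:
    """Chi-square goodness-of-fit of (nP1hom, nHet, nP2hom) against the
    Mendelian 1:2:1 expectation; returns (chi2, p) with 2 df.

    No continuity correction, no multiple-testing adjustment.
    """
    n2, n1, n0 = counts
    n = n2 + n1 + n0
    if min(n2, n1, n0) < 0:
        raise ValueError("genotype counts must be non-negative")
    if n == 0:
        raise ValueError("no observed genotypes")
    expected = np.array([n / 4, n / 2, n / 4])
    chi2 = float((((np.array([n2, n1, n0]) - expected) ** 2) / expected).sum())
    p = float(stats.chi2.sf(chi2, df=2))
    return chi2, p


def distortion_pvalues(panel: GenotypePanel) -> np.ndarray:
    """Vector of 1:2:1 chi-square p-values, one per marker (NaN where a
    marker has no observed genotypes)."""
    counts = panel.genotype_counts().astype(float)
    n = counts.sum(axis=1)
    expected = np.stack([n / 4, n / 2, n / 4], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = ((counts - expected) ** 2 / expected).sum(axis=1)
    p = stats.chi2.sf(chi2, df=2)
    return np.where(n > 0, p, np.nan)


def filter_individuals(
    panel: GenotypePanel,
    max_missing: int = 800,
    het_low: float = 0.2,
) -> tuple[GenotypePanel, QCReport]:
    """Drop individuals missing more than ``max_missing`` genotypes and
    individuals whose heterozygous fraction (among non-missing calls) is
    below ``het_low``.

    Both rules are evaluated on the input panel; an individual violating
    both is reported under the missingness rule.
    """
    if panel.n_individuals == 0 or panel.n_markers == 0:
        raise ValueError("empty panel")
    missing = panel.missing_per_individual()
    het = panel.het_fraction_per_individual()
    report = QCReport(
        individuals_before=panel.n_individuals,
        markers_before=panel.n_markers,
        markers_after=panel.n_markers,
    )
    keep = []
    for j, ind in enumerate(panel.individual_ids):
        if missing[j] > max_missing:
            report.removed_individuals.append((ind, "missing_genotypes", float(missing[j])))
        elif het[j] < het_low:
            report.removed_individuals.append((ind, "low_heterozygosity", float(het[j])))
        else:
            keep.append(ind)
    if not keep:
        raise ValueError("all individuals removed by QC filters")
    report.individuals_after = len(keep)
    out = panel.subset(individuals=keep) if len(keep) < panel.n_individuals else panel
    report.validate()
    return out, report


def filter_markers(
    panel: GenotypePanel,
    max_missing_individuals: int = 7,
    distortion_alpha: float = 1e-4,
) -> tuple[GenotypePanel, QCReport]:
    """Drop markers with heavy segregation distortion (P < alpha), then
    markers missing in more than ``max_missing_individuals`` individuals."""
    if panel.n_individuals < 1:
        raise ValueError("panel has no individuals")
    p = distortion_pvalues(panel)
    missing = panel.missing_per_marker()
    report = QCReport(
        individuals_before=panel.n_individuals,
        individuals_after=panel.n_individuals,
        markers_before=panel.n_markers,
    )
    keep = []
    for i, m in enumerate(panel.marker_ids):
        if np.isfinite(p[i]) and p[i] < distortion_alpha:
            report.removed_markers.append((m, "segregation_distortion", float(p[i])))
        elif missing[i] > max_missing_individuals:
            report.removed_markers.append((m, "missing_genotypes", float(missing[i])))
        else:
            keep.append(m)
    report.markers_after = len(keep)
    out = panel.subset(markers=keep) if len(keep) < panel.n_markers else panel
    report.validate()
    return out, report
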