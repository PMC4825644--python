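"""End-to-end map construction: panel -> bins -> rf matrix -> groups ->
ordered groups -> genetic map.  Thin orchestration over the stage modules;
the CLI and the analysis drivers call this."""

from __future__ import annotations

from dataclasses import dataclass, field

from .binning import BinSet, assign_bins
from .grouping_ordering import (
    LinkageGroupDraft,
    is_major,
    link_groups,
    order_bins_greedy,
    refine_order,
)
from .map_build import GeneticMap, build_map
from .panel_io import GenotypePanel
from .recomb import RfMatrix, rf_matrix

__all__ = ["MapResult", "build_linkage_map"]


@dataclass
class MapResult:
    binset: BinSet
    rf: RfMatrix
    drafts: list[LinkageGroupDraft]
    minor_groups: list[list[str]]
    unlinked_bins: list[str]
    genetic_map: GeneticMap = field(default=None)

    @property
    def n_major(self) -> int:
        return sum(1 for d in self.drafts if d.major)


def build_linkage_map(
    panel: GenotypePanel,
    max_rf: float = 0.15,
    min_major_bins: int = 21,
    refine_window: int = 4,
    rf_method: str = "em",
    order: bool = True,
    include_minor: bool = False,
) -> MapResult:
    """Run the full mapping pipeline on a QC-filtered panel.

    Only major groups (>= ``min_major_bins`` bins) enter the final map by
    default; minor groups and unlinked singleton bins are reported
    separately and their markers listed as unplaced.  With ``order=False``
    the (expensive) within-group ordering and map assembly are skipped and
    only grouping is performed.
    """
    binset = assign_bins(panel)
    rf = rf_matrix(binset, method=rf_method)
    groups, unlinked = link_groups(rf, max_rf=max_rf, min_major_bins=min_major_bins)
    major = [g for g in groups if is_major(g, min_major_bins)]
    minor = [g for g in groups if not is_major(g, min_major_bins)]
    drafts: list[LinkageGroupDraft] = []
    gmap = None
    if order:
        to_order = groups if include_minor else major
        for g in to_order:
            greedy = order_bins_greedy(g, rf)
            drafts.append(
                refine_order(
                    greedy, panel, binset, window=refine_window, min_major_bins=min_major_bins
                )
            )
        gmap = build_map(drafts, panel, binset)
    else:
        drafts = [
            LinkageGroupDraft(bin_ids=list(g), adjacent_r=[], objective=0, major=is_major(g, min_major_bins))
            for g in groups
        ]
    return MapResult(
        binset=binset,
        rf=rf,
        drafts=drafts,
        minor_groups=minor,
        unlinked_bins=unlinked,
        genetic_map=gmap,
    )
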