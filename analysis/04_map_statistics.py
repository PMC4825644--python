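"""Summary statistics of the assembled map.

Per linkage group: markers, bins, Kosambi length, adjacent-bin spacing,
largest gap, bins holding >= 8% of the group's markers (tip pile-ups), and
the per-individual recombination-event histogram with its 1:2:1 chi-square.

Reads results/panel_corrected.tsv (the flag-reviewed panel from the map
step); writes results/map_stats.tsv and results/bin_density.tsv.
"""

from pathlib import Path

import numpy as np

from radmap.map_build import bin_density, map_stats
from radmap.panel_io import read_panel
from radmap.pipeline import build_linkage_map

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    panel = read_panel(OUT / "panel_corrected.tsv")
    result = build_linkage_map(panel, max_rf=0.15)
    stats = map_stats(result.genetic_map, panel, result.binset)

    with (OUT / "map_stats.tsv").open("w") as fh:
        fh.write("lg\tn_markers\tn_bins\tlength_cM\tmean_adjacent_cM\tlargest_gap_cM\t"
                 "events_0\tevents_1\tevents_2\tevents_3plus\tevent_chi2_p\ttip_density_bins\n")
        for s in stats.per_lg:
            fh.write(f"{s.name}\t{s.n_markers}\t{s.n_bins}\t{s.length_cM:.4f}\t"
                     f"{s.mean_adjacent_cM:.4f}\t{s.largest_gap_cM:.4f}\t"
                     f"{s.event_histogram['0']}\t{s.event_histogram['1']}\t"
                     f"{s.event_histogram['2']}\t{s.event_histogram['3+']}\t"
                     f"{s.event_chi2_p:.4g}\t{','.join(s.tip_density_flags)}\n")
    with (OUT / "bin_density.tsv").open("w") as fh:
        fh.write("bin_id\tlg\tposition_cM\tn_markers\tdensity_per_cM\n")
        for bin_id, lg, pos, n, dens in bin_density(result.genetic_map, result.binset):
            fh.write(f"{bin_id}\t{lg}\t{pos:.4f}\t{n}\t{dens:.4g}\n")

    lengths = [s.length_cM for s in stats.per_lg]
    hist = np.sum([[s.event_histogram[k] for k in ("0", "1", "2", "3+")] for s in stats.per_lg], axis=0)
    print(f"total length: {stats.total_length_cM:.1f} cM; "
          f"per-LG mean {np.mean(lengths):.1f} cM (range {min(lengths):.1f}-{max(lengths):.1f})")
    print(f"markers per bin: {stats.mean_markers_per_bin:.2f} overall; "
          f"{stats.mean_of_lg_mean_markers_per_bin:.2f} as mean of per-LG means")
    print(f"recombination events per individual-chromosome 0/1/2/3+: {hist.tolist()}")
    print(f"apparent double recombination events: {stats.double_recombination_count} "
          f"({100.0 * stats.double_recombination_fraction:.1f}% of individual-chromosomes)")


if __name__ == "__main__":
    main()
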