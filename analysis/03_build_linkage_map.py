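"""Build the genetic map from the filtered panel.

Markers with identical segregation patterns are collapsed into bins,
pairwise recombination fractions between bins are estimated by EM, bins
are grouped by single linkage at a maximum recombination fraction of 0.15,
ordered by nearest-neighbor chaining, refined to minimize total crossover
events, and placed on a Kosambi cM scale.

A genotyping miscall flanked by two equal genotypes shows up as a double
recombination event at a single interior bin and inflates the map, so
after the first pass every flagged (individual, bin) call is written to a
reviewable correction file (set to missing) and the map is rebuilt — the
same review-and-correct cycle used to finalize such maps by hand.

Reads results/panel_filtered.tsv; writes results/map.tsv, results/bins.tsv,
results/double_recombinant_flags.tsv, results/corrections.tsv and
results/panel_corrected.tsv.
"""

from pathlib import Path

from radmap.binning import write_bins_tsv
from radmap.grouping_ordering import apply_corrections, flag_double_recombinants
from radmap.panel_io import read_panel, write_map, write_panel
from radmap.pipeline import build_linkage_map

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    panel = read_panel(OUT / "panel_filtered.tsv")
    result = build_linkage_map(panel, max_rf=0.15)
    gmap = result.genetic_map
    print(f"{panel.n_markers} markers occupy {len(result.binset.bins)} bins")
    print(f"major linkage groups (>20 bins): {result.n_major}; "
          f"minor groups: {len(result.minor_groups)}; "
          f"unlinked bins: {len(result.unlinked_bins)}")
    print(f"initial map: {gmap.total_length_cM:.1f} cM "
          "(inflated by miscall-induced double recombination events)")

    all_flags = []
    panel2, result2, gmap2 = panel, result, gmap
    for round_no in range(1, 5):
        flags = []
        for lg in gmap2.lgs:
            for individual, bin_id in flag_double_recombinants(lg.bin_ids, panel2, result2.binset):
                for marker in result2.binset.get(bin_id).member_marker_ids:
                    flags.append((marker, individual, bin_id))
        if not flags:
            break
        all_flags.extend(flags)
        panel2 = apply_corrections(panel2, [(m, i, "-") for m, i, _ in flags])
        result2 = build_linkage_map(panel2, max_rf=0.15)
        gmap2 = result2.genetic_map
        print(f"review round {round_no}: {len(flags)} flagged calls set to missing "
              f"-> {gmap2.total_length_cM:.1f} cM")

    with (OUT / "double_recombinant_flags.tsv").open("w") as fh:
        fh.write("marker_id\tindividual_id\tbin_id\n")
        for marker, individual, bin_id in all_flags:
            fh.write(f"{marker}\t{individual}\t{bin_id}\n")
    with (OUT / "corrections.tsv").open("w") as fh:
        fh.write("marker_id\tindividual_id\tnew_code\n")
        for marker, individual, _ in all_flags:
            fh.write(f"{marker}\t{individual}\t-\n")

    print(f"corrected map: {gmap2.total_length_cM:.1f} cM over {len(gmap2.lgs)} LGs "
          f"({gmap2.total_length_cM / len(gmap2.lgs):.1f} cM per linkage group)")
    print(f"mapped markers: {gmap2.n_mapped_markers} "
          f"({100.0 * gmap2.n_mapped_markers / panel.n_markers:.1f}% of the panel; "
          "chromosomes collapsing below 21 bins after correction leave the major set)")
    write_panel(panel2, OUT / "panel_corrected.tsv")
    write_map(gmap2, OUT / "map.tsv")
    write_bins_tsv(result2.binset, OUT / "bins.tsv")


if __name__ == "__main__":
    main()
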