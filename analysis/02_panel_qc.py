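"""QC-filter the simulated panel the way the mapping panel was built.

Individuals missing more than 800 genotypes or with heterozygosity below
20% are dropped; then markers with segregation distortion at P < 1e-4 and
markers missing in more than 7 individuals are dropped.

Reads results/panel.tsv; writes results/panel_filtered.tsv and
results/qc_report.tsv.
"""

from pathlib import Path

from radmap.panel_io import read_panel, write_panel
from radmap.qc import filter_individuals, filter_markers

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    panel = read_panel(OUT / "panel.tsv")
    print(f"input: {panel.n_markers} markers x {panel.n_individuals} individuals")
    panel, rep_ind = filter_individuals(panel)
    print(f"individuals removed: {len(rep_ind.removed_individuals)} "
          f"-> {panel.n_individuals} retained")
    panel, rep_mark = filter_markers(panel)
    n_dist = sum(1 for _, r, _ in rep_mark.removed_markers if r == "segregation_distortion")
    n_miss = len(rep_mark.removed_markers) - n_dist
    print(f"markers removed: {n_dist} distorted (P < 1e-4), {n_miss} with >7 missing "
          f"-> {panel.n_markers} retained")
    write_panel(panel, OUT / "panel_filtered.tsv")
    with (OUT / "qc_report.tsv").open("w") as fh:
        fh.write("id\taxis\treason\tstatistic\n")
        for i, reason, stat in rep_ind.removed_individuals:
            fh.write(f"{i}\tindividual\t{reason}\t{stat:g}\n")
        for m, reason, stat in rep_mark.removed_markers:
            fh.write(f"{m}\tmarker\t{reason}\t{stat:g}\n")


if __name__ == "__main__":
    main()
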