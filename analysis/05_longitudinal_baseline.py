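"""Deviation-from-baseline trajectories in the longitudinal cohort.

Each post-treatment sample's Bray-Curtis distance to its group's baseline
centroid (mean proportion vector over timepoints < 0) quantifies how far a
community has moved; the faster-drifting mutant-like group deviates more.
"""

from pathlib import Path

from microkit import distance_to_baseline
from microkit.io import read_metadata, read_otu_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    table = read_otu_table(ROOT / "data" / "longitudinal_table.tsv")
    meta = read_metadata(ROOT / "data" / "longitudinal_metadata.tsv")

    d = distance_to_baseline(table, meta, reference="group_baseline_centroid")
    d.to_csv(ROOT / "distance_to_baseline.tsv", sep="\t", index=False)
    traj = d.groupby(["group", "timepoint"])["distance"].mean().unstack()
    print("mean Bray-Curtis distance to group baseline centroid:")
    print(traj.round(3).to_string())
    day3 = traj[3]
    print(f"day 3: MUT deviates {day3['MUT'] / day3['WT']:.1f}x further "
          "from baseline than WT")


if __name__ == "__main__":
    main()
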