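"""Component sRNA profiles and overrepresented features.

Relative profiles per blood component (features below 2% pooled as
'others'), RNA-class-aggregated profiles, and a one-vs-rest Wilcoxon scan
(BH-adjusted p < 0.05, increased fold change, expressed in every sample of
the component). Writes tables under results/profiles/.
"""

import argparse
from pathlib import Path

import pandas as pd

from bloodsrna import io, preprocess, stats


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--expression-dir", type=Path, default=Path("results/expression"))
    parser.add_argument("--qc-dir", type=Path, default=Path("results/qc"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/profiles"))
    args = parser.parse_args()

    rpm = io.read_count_matrix(args.expression_dir / "rpm")
    excluded = set(
        pd.read_csv(args.qc_dir / "qc_exclusions.tsv", sep="\t")["sample_id"]
    )
    rpm = rpm.subset_samples([s for s in rpm.samples if s not in excluded])

    args.out_dir.mkdir(parents=True, exist_ok=True)
    profiles = stats.component_profile(rpm)
    io.write_table(profiles, args.out_dir / "component_profiles.tsv")
    class_profiles = stats.class_profile(rpm)
    class_profiles.to_csv(args.out_dir / "class_profiles.tsv", sep="\t")
    markers = stats.overrepresented_srnas(preprocess.log_transform(rpm), rpm_matrix=rpm)
    io.write_table(markers, args.out_dir / "markers.tsv")

    n_named = (profiles["feature"] != "others").groupby(profiles["component"]).sum()
    print(f"profiles: {n_named.min()}-{n_named.max()} features above 2% per component")
    print("dominant RNA class per component:")
    for comp, row in class_profiles.iterrows():
        print(f"  {comp:15s} {row.idxmax():8s} {row.max():.2f}")
    passing = markers[markers["passes"]]
    per_comp = passing.groupby("component").size()
    print(f"overrepresented features: {len(passing)} passing calls "
          f"({per_comp.min()}-{per_comp.max()} per component)")


if __name__ == "__main__":
    main()
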