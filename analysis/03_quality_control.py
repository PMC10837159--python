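"""Two-stage sample QC: purity gate, then t-SNE outlier detection.

Cellular fractions need flow-cytometry purity > 70%; survivors are embedded
into two t-SNE dimensions on log2(RPM+1) expression and samples that do not
sit among their own component (kNN majority rule) are excluded. Writes the
embedding and the exclusion table under results/qc/.
"""

import argparse
from pathlib import Path

import pandas as pd

from bloodsrna import io, preprocess, qc


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
    parser.add_argument("--expression-dir", type=Path, default=Path("results/expression"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/qc"))
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    samples = io.read_sort_samples(args.cohort_dir / "sort_samples.tsv")
    counts = io.read_count_matrix(args.expression_dir / "counts")

    passed, failed = qc.purity_filter(samples)
    log = preprocess.log_transform(preprocess.rpm_normalize(counts.subset_samples(passed)))
    coords = qc.embed(log, seed=args.seed)
    flagged = qc.flag_outliers(coords, log.components)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    coords.to_csv(args.out_dir / "embedding.tsv", sep="\t")
    rows = [{"sample_id": s, "reason": "purity"} for s in sorted(failed)]
    rows += [{"sample_id": s, "reason": "embedding"} for s in sorted(flagged)]
    io.write_table(pd.DataFrame(rows, columns=["sample_id", "reason"]),
                   args.out_dir / "qc_exclusions.tsv")

    n = len(samples)
    print(f"{n} fractions in; {len(failed)} excluded for purity <= 70% "
          f"({100 * len(failed) / n:.1f}%), {n - len(failed)} remain")
    print(f"{len(flagged)} excluded as embedding outliers "
          f"({100 * len(flagged) / (n - len(failed)):.1f}%), "
          f"{n - len(failed) - len(flagged)} samples pass QC")
    print(f"exclusions and embedding written to {args.out_dir}")


if __name__ == "__main__":
    main()
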