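#!/usr/bin/env python
"""Per-probe one-way ANOVA across ages, BH correction, and the
p <= 0.05 / |fold change| >= 2 differential filter."""

import argparse
import warnings
from pathlib import Path

from impnet.data_model import StudyDesign, read_expression_matrix
from impnet.differential_filter import filter_differential, run_differential


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--fc", type=float, default=2.0)
    args = ap.parse_args()

    matrix = read_expression_matrix(
        args.results / "expression_normalized.tsv", StudyDesign()
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # n=2 replicates per age is by design
        diff = run_differential(matrix, alpha=args.alpha, fc_threshold=args.fc)
    diff.to_csv(args.results / "differential.tsv", sep="\t")
    survivors = filter_differential(diff, args.alpha, args.fc)
    (args.results / "differential_probes.txt").write_text(
        "\n".join(survivors) + "\n"
    )
    print(f"{len(survivors)} of {len(diff)} probes pass the differential filter")


if __name__ == "__main__":
    main()
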