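#!/usr/bin/env python
"""Quantile-normalize the expression matrix across all chips."""

import argparse
from pathlib import Path

from impnet.data_model import (
    StudyDesign,
    quantile_normalize,
    read_expression_matrix,
    write_expression_matrix,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    matrix = read_expression_matrix(args.results / "expression.tsv", StudyDesign())
    normed = quantile_normalize(matrix)
    write_expression_matrix(normed, args.results / "expression_normalized.tsv")
    print(f"normalized {normed.n_probes} probes")


if __name__ == "__main__":
    main()
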