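#!/usr/bin/env python
"""IMP-content statistics: male/female cross-correlation and n-weighted
pooled totals from the packaged series, plus per-age summary and compact
letter display for the simulated individual measurements."""

import argparse
from pathlib import Path

import pandas as pd

from impnet.datasets import imp_phenotype_series
from impnet.phenotype_stats import (
    cross_group_correlation,
    group_summary,
    pooled_mean,
    significance_letters,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    pheno = imp_phenotype_series()
    male = pheno[pheno["group"] == "male"].sort_values("time_point")
    female = pheno[pheno["group"] == "female"].sort_values("time_point")
    r = cross_group_correlation(male["mean"].tolist(), female["mean"].tolist())
    print(f"cross-sex IMP profile correlation: r = {r:.3f} (n = {len(male)})")

    print("n-weighted pooled totals by age (wk):")
    for t in sorted(pheno["time_point"].unique()):
        rows = pheno[(pheno["time_point"] == t) & (pheno["group"] != "total")]
        pooled = pooled_mean(
            [(float(m), int(n)) for m, n in rows[["mean", "n"]].itertuples(index=False)]
        )
        print(f"  {t:>2} wk: {pooled:.4f} (n = {rows['n'].sum()})")

    raw_path = args.results / "phenotype_raw.tsv"
    if raw_path.exists():
        raw = pd.read_csv(raw_path, sep="\t")
        summary = group_summary(raw)
        letters = significance_letters(
            {
                str(t): raw[raw["time_point"] == t]["value"].tolist()
                for t in sorted(raw["time_point"].unique())
            }
        )
        summary["letters"] = [letters[str(t)] for t in summary["time_point"]]
        summary.to_csv(args.results / "phenotype_summary.tsv", sep="\t", index=False)
        print(f"simulated phenotype summary written to {args.results}/phenotype_summary.tsv")


if __name__ == "__main__":
    main()
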