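"""Relative quantification by 2^-ddCt and qPCR-microarray concordance.

The Livak estimator: dCt = mean Ct(target) - mean Ct(reference) per time
point; ddCt references the calibrator time point (2 wk); the expression
ratio is 2^-ddCt. Ratios are printed as signed fold changes (r when r >= 1,
-1/r otherwise). Concordance between a qPCR profile and the matching
microarray profile is the Pearson correlation of the signed vectors with an
exact-t two-tailed p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression_network import ConstantProfileError, pearson_correlation

__all__ = [
    "CtTable",
    "FoldChangeProfile",
    "ConcordanceResult",
    "delta_delta_ct",
    "signed_fold_change",
    "signed_to_ratio",
    "concordance",
    "correlation_pvalue",
    "read_ct_table",
]


@dataclass
class CtTable:
    """Raw cycle-threshold records for one target gene.

    ``records``: DataFrame with columns time_point, replicate, ct_target,
    ct_reference. ``calibrator`` is the baseline time point (ddCt = 0).
    """

    gene: str
    reference_gene: str
    records: pd.DataFrame
    calibrator: int = 2

    def __post_init__(self) -> None:
        required = {"time_point", "replicate", "ct_target", "ct_reference"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        ct = self.records[["ct_target", "ct_reference"]].to_numpy(dtype=float)
        if not (np.isfinite(ct).all() and (ct > 0).all()):
            raise ValueError("Ct values must be positive and finite")
        if self.calibrator not in set(self.records["time_point"]):
            raise ValueError(
                f"calibrator time point {self.calibrator} has no records"
            )


@dataclass(frozen=True)
class FoldChangeProfile:
    """Signed fold changes per time point, baseline entry = 1.0."""

    gene: str
    source: str  # 'qPCR' or 'microarray'
    time_points: tuple[int, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.time_points) != len(self.values):
            raise ValueError("time points and values differ in length")
        for v in self.values:
            if not (abs(v) >= 1.0):
                raise ValueError(
                    f"signed fold change {v} has magnitude below 1"
                )


@dataclass(frozen=True)
class ConcordanceResult:
    gene: str
    r: float
    p: float
    n: int


def delta_delta_ct(table: CtTable) -> pd.Series:
    """Expression ratio 2^-ddCt per time point; calibrator ratio exactly 1."""
    grouped = table.records.groupby("time_point")
    d_ct = grouped["ct_target"].mean() - grouped["ct_reference"].mean()
    dd_ct = d_ct - d_ct[table.calibrator]
    ratio = np.power(2.0, -dd_ct)
    ratio[table.calibrator] = 1.0
    return ratio.sort_index()


def signed_fold_change(ratio: float) -> float:
    """Map a positive expression ratio to the signed convention."""
    if not ratio > 0:
        raise ValueError("expression ratio must be positive")
    return float(ratio) if ratio >= 1.0 else float(-1.0 / ratio)


def signed_to_ratio(signed: float) -> float:
    """Inverse of :func:`signed_fold_change` on {|s| >= 1}."""
    if abs(signed) < 1.0:
        raise ValueError("signed fold change must have magnitude >= 1")
    return float(signed) if signed >= 1.0 else float(-1.0 / signed)


def correlation_pvalue(r: float, n: int) -> float:
    """Two-tailed p for a Pearson r via the exact t transform.

    t = r * sqrt(n - 2) / sqrt(1 - r^2) against Student's t with n - 2
    degrees of freedom; symmetric in the sign of r. |r| = 1 returns the
    limit p = 0.
    """
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = abs(r) * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(t, df=n - 2))


def concordance(q: FoldChangeProfile, a: FoldChangeProfile) -> ConcordanceResult:
    """Pearson concordance between two signed fold-change profiles.

    Profiles must describe the same gene over the same ordered time points
    (baseline entries included, exactly as printed).
    """
    if q.gene != a.gene:
        raise ValueError(f"gene mismatch: {q.gene!r} vs {a.gene!r}")
    if q.time_points != a.time_points:
        raise ValueError("profiles must share the same ordered time points")
    n = len(q.values)
    if n < 3:
        raise ValueError("need at least 3 time points")
    r = pearson_correlation(q.values, a.values)
    if abs(r) == 1.0:
        p = 0.0
    else:
        p = correlation_pvalue(r, n)
    return ConcordanceResult(gene=q.gene, r=r, p=p, n=n)


def read_ct_table(path: str | Path, calibrator: int = 2) -> list[CtTable]:
    """Read a TSV of Ct records, one :class:`CtTable` per target gene.

    Columns: gene, reference_gene, time_point, replicate, ct_target,
    ct_reference.
    """
    df = pd.read_csv(path, sep="\t")
    tables = []
    for (gene, ref), sub in df.groupby(["gene", "reference_gene"], sort=True):
        tables.append(
            CtTable(
                gene=str(gene),
                reference_gene=str(ref),
                records=sub.reset_index(drop=True),
                calibrator=calibrator,
            )
        )
    return tables
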