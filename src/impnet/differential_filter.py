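"""Differential-expression filtering across the time course.

A probe survives when its one-way ANOVA across time-point groups is
significant after multiple-testing correction (BH by default) AND its
signed fold change versus the 2 wk baseline reaches the cutoff at one or
more time points. Both thresholds are inclusive (p_adj <= alpha,
|signed fc| >= fc_threshold).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import ExpressionMatrix, StudyDesign, mean_by_timepoint

__all__ = [
    "signed_fold_changes",
    "anova_per_probe",
    "adjust_pvalues",
    "run_differential",
    "filter_differential",
]

_ADJUST_METHODS = {"fdr_bh": "fdr_bh", "bh": "fdr_bh", "bonferroni": "bonferroni"}


def signed_fold_changes(profile: pd.Series, baseline) -> pd.Series:
    """Signed fold change per time point from a per-time-point log2 profile.

    ratio = 2^(mean_t - mean_baseline); reported as ratio when >= 1 and
    -1/ratio when < 1, so down-regulation prints as a negative value of
    symmetric magnitude. The baseline's own entry is 1.0.
    """
    if baseline not in profile.index:
        raise ValueError(f"baseline {baseline!r} missing from profile")
    ratio = np.power(2.0, profile - profile[baseline])
    signed = pd.Series(
        np.where(ratio >= 1.0, ratio, -1.0 / ratio), index=profile.index
    )
    signed[baseline] = 1.0
    return signed


def anova_per_probe(m: ExpressionMatrix, design: StudyDesign | None = None) -> pd.Series:
    """Classical one-way fixed-effects ANOVA p-value per probe.

    Groups are the time points; replicates are the observations. Degenerate
    probes are resolved deterministically: all values identical -> p = 1;
    zero within-group variance with unequal group means -> p = 0 (with a
    warning, since F is formally infinite).
    """
    design = design or m.design
    groups = [
        m.data[m.columns_for_timepoint(t)].to_numpy(dtype=float)
        for t in design.time_points
    ]
    if any(g.shape[1] < 1 for g in groups):
        raise ValueError("every time point needs at least one sample")
    total_obs = sum(g.shape[1] for g in groups)
    if total_obs - len(groups) < 1:
        raise ValueError("no within-group degrees of freedom; add replicates")
    if min(g.shape[1] for g in groups) < 3:
        warnings.warn(
            "some time points have fewer than 3 replicates; "
            "per-probe ANOVA will have low power",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_res = stats.f_oneway(*groups, axis=1)
    p = np.asarray(f_res.pvalue, dtype=float)

    stacked = np.hstack(groups)
    within_ss = sum(
        ((g - g.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for g in groups
    )
    all_equal = np.ptp(stacked, axis=1) == 0
    degenerate = (within_ss == 0) & ~all_equal
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} probes have zero within-group variance "
            "with unequal means; reporting p = 0",
            stacklevel=2,
        )
    p[degenerate] = 0.0
    p[all_equal] = 1.0
    return pd.Series(p, index=m.probe_ids, name="p_raw")


def adjust_pvalues(p: Sequence[float] | pd.Series, method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing correction preserving input order; values capped at 1.

    ``method``: 'fdr_bh' (Benjamini-Hochberg step-up, default) or
    'bonferroni'.
    """
    arr = np.asarray(p, dtype=float)
    if arr.size and ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if arr.size == 0:
        return arr
    key = _ADJUST_METHODS.get(method.lower())
    if key is None:
        raise ValueError(f"unknown correction method {method!r}")
    adjusted = multipletests(arr, method=key)[1]
    return np.minimum(adjusted, 1.0)


def run_differential(
    m: ExpressionMatrix,
    *,
    alpha: float = 0.05,
    fc_threshold: float = 2.0,
    method: str = "fdr_bh",
) -> pd.DataFrame:
    """Full per-probe differential table.

    Columns: ``fc_<t>`` signed fold change per time point, ``p_raw``,
    ``p_adj``, ``passes``.
    """
    means = mean_by_timepoint(m)
    baseline = m.design.baseline
    log_diff = means.sub(means[baseline], axis=0)
    ratio = np.power(2.0, log_diff.to_numpy())
    signed = np.where(ratio >= 1.0, ratio, -1.0 / ratio)
    fc = pd.DataFrame(
        signed, index=means.index, columns=[f"fc_{t}" for t in means.columns]
    )
    fc[f"fc_{baseline}"] = 1.0

    p_raw = anova_per_probe(m)
    p_adj = adjust_pvalues(p_raw, method=method)
    non_baseline = [f"fc_{t}" for t in m.design.time_points if t != baseline]
    max_abs_fc = fc[non_baseline].abs().max(axis=1)
    out = fc.copy()
    out["p_raw"] = p_raw
    out["p_adj"] = p_adj
    out["passes"] = (out["p_adj"] <= alpha) & (max_abs_fc >= fc_threshold)
    return out


def filter_differential(
    results: pd.DataFrame, alpha: float = 0.05, fc_threshold: float = 2.0
) -> set[str]:
    """Probe ids passing both gates (inclusive thresholds) at >= 1 time point."""
    fc_cols = [c for c in results.columns if c.startswith("fc_")]
    max_abs = results[fc_cols].abs().max(axis=1)
    mask = (results["p_adj"] <= alpha) & (max_abs >= fc_threshold)
    return set(results.index[mask])
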