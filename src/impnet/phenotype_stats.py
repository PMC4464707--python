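"""Descriptive and comparative statistics for the IMP-content phenotype.

IMP content (mg/g of muscle) is measured per bird at six ages in males and
females. This module produces the per-cell mean +/- SE summary, n-weighted
pooled totals, the cross-sex correlation of the mean series, and a compact
letter display from pairwise Welch t-tests.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .coexpression_network import pearson_correlation

__all__ = [
    "group_summary",
    "pooled_mean",
    "cross_group_correlation",
    "significance_letters",
    "read_phenotype_table",
]


def group_summary(raw: pd.DataFrame) -> pd.DataFrame:
    """Mean, SE = sd/sqrt(n) and n per (time_point, group) cell.

    ``raw`` has columns time_point, group, value; every cell needs n >= 2
    for a defined standard error.
    """
    required = {"time_point", "group", "value"}
    if missing := required - set(raw.columns):
        raise ValueError(f"raw phenotype table missing columns: {sorted(missing)}")
    if raw.empty:
        raise ValueError("empty phenotype table")
    rows = []
    for (t, g), sub in raw.groupby(["time_point", "group"], sort=True):
        vals = sub["value"].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(
                f"cell ({t}, {g}) has n={len(vals)}; SE needs n >= 2"
            )
        rows.append(
            {
                "time_point": t,
                "group": g,
                "mean": vals.mean(),
                "se": vals.std(ddof=1) / np.sqrt(len(vals)),
                "n": len(vals),
            }
        )
    return pd.DataFrame(rows)


def pooled_mean(subgroups: Sequence[tuple[float, int]]) -> float:
    """n-weighted pooled mean of (mean, n) subgroup summaries."""
    if not subgroups:
        raise ValueError("no subgroups to pool")
    means = np.array([m for m, _ in subgroups], dtype=float)
    ns = np.array([n for _, n in subgroups], dtype=float)
    if (ns < 1).any():
        raise ValueError("all subgroup sizes must be >= 1")
    return float((means * ns).sum() / ns.sum())


def cross_group_correlation(a: Sequence[float], b: Sequence[float]) -> float:
    """Pearson r between two per-time-point mean series."""
    return pearson_correlation(a, b)


def significance_letters(
    groups: dict[str, Sequence[float]], alpha: float = 0.05
) -> dict[str, str]:
    """Compact letter display from pairwise two-sided Welch t-tests.

    Two groups share a letter iff their pairwise test is non-significant at
    ``alpha``. Letters come from the maximal cliques of the
    "not-significantly-different" graph, ordered by the smallest group mean
    in the clique (then time/label order) for reproducibility.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = {}
    for name in names:
        vals = np.asarray(groups[name], dtype=float)
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has n < 2")
        arrays[name] = vals

    nonsig = nx.Graph()
    nonsig.add_nodes_from(names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if np.array_equal(arrays[a], arrays[b]):
                p = 1.0
            else:
                p = stats.ttest_ind(arrays[a], arrays[b], equal_var=False).pvalue
                if np.isnan(p):  # both groups constant but different
                    p = 0.0
            if p > alpha:
                nonsig.add_edge(a, b)

    order = {name: i for i, name in enumerate(names)}
    cliques = [sorted(c, key=lambda n: (arrays[n].mean(), order[n])) for c in nx.find_cliques(nonsig)]
    cliques.sort(key=lambda c: (min(arrays[n].mean() for n in c), min(order[n] for n in c)))
    letters = {name: "" for name in names}
    for i, clique in enumerate(cliques):
        letter = _letter(i)
        for name in clique:
            letters[name] += letter
    return {name: "".join(sorted(letters[name])) for name in names}


def _letter(i: int) -> str:
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = ""
    i += 1
    while i:
        i, rem = divmod(i - 1, 26)
        out = alphabet[rem] + out
    return out


def read_phenotype_table(path) -> pd.DataFrame:
    """Read either raw (time_point, group, value) or summary-level
    (time_point, group, mean, se, n) phenotype TSVs."""
    df = pd.read_csv(path, sep="\t")
    if {"time_point", "group", "value"} <= set(df.columns):
        return df
    if {"time_point", "group", "mean", "se", "n"} <= set(df.columns):
        return df
    raise ValueError(
        "phenotype table must be raw (time_point, group, value) or "
        "summary (time_point, group, mean, se, n)"
    )
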