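"""Published measurement tables used as pipeline inputs.

Two small datasets from the chicken muscle IMP study travel with the
package: the IMP-content phenotype series (mean +/- SE mg/g and sample
sizes per age and sex) and the qPCR / microarray signed fold-change
profiles of the four validation genes (Bmpr2, Prps2, Gja1, Pecam1). These
are inputs to the statistics modules, not pre-computed results: every
correlation or pooled value derived from them is recomputed at run time.
"""

from __future__ import annotations

import pandas as pd

from .qpcr_concordance import FoldChangeProfile

__all__ = [
    "TIME_POINTS_WK",
    "imp_phenotype_series",
    "qpcr_validation_profiles",
    "CANDIDATE_GENES",
]

TIME_POINTS_WK: tuple[int, ...] = (2, 4, 6, 8, 10, 12)

#: The 15 candidate regulator genes (CGs) surviving the three-network
#: intersection and co-expression membership filter.
CANDIDATE_GENES: tuple[str, ...] = (
    "Hspa2", "Pten", "Gabpa", "Bpi", "Mkl1", "Srf", "Cd34", "Hspa4",
    "Etv6", "Bmpr2", "Gde1", "Igfbp5", "Cd28", "Pecam1", "Gja1",
)

_PHENOTYPE_ROWS = [
    # (time_point, group, mean mg/g, SE mg/g, n birds)
    (2, "male", 2.9073, 0.1360, 14),
    (4, "male", 3.8823, 0.1242, 16),
    (6, "male", 3.4162, 0.1740, 11),
    (8, "male", 3.7006, 0.3120, 6),
    (10, "male", 3.0038, 0.2348, 9),
    (12, "male", 3.8039, 0.2969, 9),
    (2, "female", 2.9822, 0.1709, 14),
    (4, "female", 3.8094, 0.3132, 15),
    (6, "female", 3.9376, 0.3354, 12),
    (8, "female", 3.6698, 0.3157, 8),
    (10, "female", 3.3249, 0.2548, 9),
    (12, "female", 4.3400, 0.3523, 10),
    (2, "total", 2.9448, 0.1074, 28),
    (4, "total", 3.8470, 0.1618, 31),
    (6, "total", 3.6882, 0.1975, 23),
    (8, "total", 3.6830, 0.2162, 14),
    (10, "total", 3.1643, 0.1725, 18),
    (12, "total", 4.0861, 0.2349, 19),
]


def imp_phenotype_series() -> pd.DataFrame:
    """IMP content summary per (time point, group).

    Columns: time_point (wk), group in {male, female, total}, mean (mg/g),
    se (mg/g), n (birds).
    """
    return pd.DataFrame(
        _PHENOTYPE_ROWS, columns=["time_point", "group", "mean", "se", "n"]
    )


_QPCR_ROWS: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    # gene: (qPCR signed fold changes, microarray signed fold changes),
    # ordered 2, 4, 6, 8, 10, 12 wk; baseline 2 wk = 1.00
    "Bmpr2": (
        (1.00, -1.71, -2.00, -1.53, -1.98, -2.91),
        (1.00, -2.41, -1.40, -2.19, -1.63, -2.90),
    ),
    "Prps2": (
        (1.00, 1.39, -1.97, 2.28, 1.13, -1.21),
        (1.00, 1.64, -1.35, 2.47, 1.33, 1.05),
    ),
    "Gja1": (
        (1.00, 1.29, -1.75, 3.31, 1.42, -1.09),
        (1.00, 1.01, -1.48, 2.72, 1.66, -1.37),
    ),
    "Pecam1": (
        (1.00, 2.04, -1.08, 3.16, 1.33, -1.05),
        (1.00, 1.96, 1.12, 2.87, 2.47, 1.22),
    ),
}


def qpcr_validation_profiles() -> dict[str, tuple[FoldChangeProfile, FoldChangeProfile]]:
    """Signed fold-change profiles of the four qPCR validation genes.

    Returns gene -> (qPCR profile, microarray profile), each over the six
    ages with the 2 wk baseline printed as 1.00.
    """
    out = {}
    for gene, (q, a) in _QPCR_ROWS.items():
        out[gene] = (
            FoldChangeProfile(gene, "qPCR", TIME_POINTS_WK, q),
            FoldChangeProfile(gene, "microarray", TIME_POINTS_WK, a),
        )
    return out
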