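"""Core data containers and normalization for the expression pipeline.

The study design is a time-course microarray: chickens sampled every two
weeks from 2 wk to 12 wk of age, one male and one female chip per time
point, single-color log2 intensities. Everything downstream (differential
filtering, co-expression, phenotype correlation) consumes the
:class:`ExpressionMatrix` built here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StudyDesign",
    "ExpressionMatrix",
    "ProbeAnnotation",
    "SeedGeneSet",
    "DEFAULT_SEED_GENES",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotation",
    "write_annotation",
    "read_seed_list",
    "quantile_normalize",
    "mean_by_timepoint",
]

#: The 19 genes directly catalyzing IMP synthesis, decomposition and
#: utilization; the anchors of the co-expression search.
DEFAULT_SEED_GENES: tuple[str, ...] = (
    "Gart", "Atic", "Paics", "Adsl", "Prps2", "Entpd4", "Nt5c1a",
    "Nt5c1b", "Nme1", "Prps1", "Nudt9", "Ppat", "Ampd3", "Entpd5",
    "Itpa", "Nme6", "Ampd1", "Adssl1", "Entpd8",
)


@dataclass(frozen=True)
class StudyDesign:
    """Time points (weeks of age), replicate labels, and the baseline.

    The default mirrors the study layout: ages 2-12 wk sampled every two
    weeks, one male ("M") and one female ("F") chip at each age, with the
    2 wk samples serving as the fold-change baseline.
    """

    time_points: tuple[int, ...] = (2, 4, 6, 8, 10, 12)
    replicates: tuple[str, ...] = ("M", "F")
    baseline: int = 2

    def __post_init__(self) -> None:
        if len(self.time_points) < 2:
            raise ValueError("a study design needs at least two time points")
        if any(b <= a for a, b in zip(self.time_points, self.time_points[1:])):
            raise ValueError("time points must be strictly increasing")
        if not self.replicates:
            raise ValueError("at least one replicate label is required")
        if self.baseline not in self.time_points:
            raise ValueError(
                f"baseline {self.baseline!r} is not one of the time points"
            )

    @property
    def samples(self) -> list[tuple[int, str]]:
        """(time_point, replicate) pairs in design order."""
        return [(t, r) for t in self.time_points for r in self.replicates]

    def sample_name(self, time_point: int, replicate: str) -> str:
        return f"{time_point}wk_{replicate}"

    @property
    def sample_names(self) -> list[str]:
        return [self.sample_name(t, r) for t, r in self.samples]

    def parse_sample_name(self, name: str) -> tuple[int, str]:
        """Resolve a column header of the form ``<weeks>wk_<replicate>``."""
        try:
            weeks, rep = name.split("wk_", 1)
            tp = int(weeks)
        except ValueError as exc:
            raise ValueError(f"unparseable sample name {name!r}") from exc
        if tp not in self.time_points or rep not in self.replicates:
            raise ValueError(f"sample {name!r} is not part of the design")
        return tp, rep


@dataclass
class ExpressionMatrix:
    """Probe x sample log2 intensities tied to a :class:`StudyDesign`.

    ``data`` is a DataFrame with probe ids as index and design sample names
    (``"<weeks>wk_<rep>"``) as columns, ordered by the design.
    """

    data: pd.DataFrame
    design: StudyDesign
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe ids: {dupes}")
        expected = self.design.sample_names
        missing = [c for c in expected if c not in self.data.columns]
        if missing:
            raise ValueError(f"design samples missing from matrix: {missing}")
        extra = [c for c in self.data.columns if c not in expected]
        if extra:
            raise ValueError(f"columns not in the design: {extra}")
        self.data = self.data.loc[:, expected]
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]

    def columns_for_timepoint(self, time_point: int) -> list[str]:
        return [
            self.design.sample_name(time_point, r) for r in self.design.replicates
        ]


@dataclass
class ProbeAnnotation:
    """probe_id -> (gene_symbol, gene_id) mapping with an optional seed flag."""

    table: pd.DataFrame  # columns: gene_symbol, gene_id, (is_seed); index probe_id

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("annotation maps a probe_id to more than one record")
        for col in ("gene_symbol", "gene_id"):
            if col not in self.table.columns:
                raise ValueError(f"annotation is missing column {col!r}")

    def gene_symbol(self, probe_id: str) -> str:
        return str(self.table.at[probe_id, "gene_symbol"])

    def probes_for_symbol(self, symbol: str) -> list[str]:
        mask = self.table["gene_symbol"] == symbol
        return self.table.index[mask].tolist()

    def __contains__(self, probe_id: object) -> bool:
        return probe_id in self.table.index


@dataclass(frozen=True)
class SeedGeneSet:
    """Ordered, unique gene symbols anchoring the co-expression search."""

    genes: tuple[str, ...] = DEFAULT_SEED_GENES

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("seed gene set must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("seed gene symbols must be unique")

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: object) -> bool:
        return symbol in self.genes


# ---------------------------------------------------------------------------
# File I/O (TSV dialects)
# ---------------------------------------------------------------------------

def read_expression_matrix(
    path: str | Path,
    design: StudyDesign,
    *,
    sample_map: Mapping[str, str] | None = None,
    log2_transform: bool = False,
    impute_missing: bool = False,
) -> ExpressionMatrix:
    """Read a tab-separated probe x sample matrix.

    First column must be ``probe_id``; remaining headers must resolve to
    design samples, directly or through ``sample_map`` (file header ->
    canonical ``<weeks>wk_<rep>`` name). ``log2_transform`` applies
    log2(x + 1) for raw linear intensities; ``impute_missing`` replaces NaN
    with the per-probe row mean instead of rejecting the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate probe ids in {path.name}: {dupes}")
    if sample_map:
        df = df.rename(columns=dict(sample_map))
    expected = set(design.sample_names)
    unresolved = [c for c in df.columns if c not in expected]
    if unresolved:
        raise ValueError(
            f"columns not resolvable to design samples: {unresolved}"
        )
    if df.isna().any().any():
        if not impute_missing:
            raise ValueError(
                f"{path.name} contains missing values; "
                "pass impute_missing=True to row-mean impute"
            )
        row_means = df.mean(axis=1)
        df = df.apply(lambda col: col.fillna(row_means))
    values = df.astype(float)
    if log2_transform:
        values = np.log2(values + 1.0)
    return ExpressionMatrix(data=values, design=design)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    out = m.data.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_annotation(path: str | Path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", index_col="probe_id", dtype=str)
    return ProbeAnnotation(table=df)


def write_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    out = annotation.table.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def read_seed_list(path: str | Path) -> SeedGeneSet:
    """One gene symbol per line; '#' starts a comment."""
    genes: list[str] = []
    for line in Path(path).read_text().splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            genes.append(entry)
    return SeedGeneSet(genes=tuple(genes))


# ---------------------------------------------------------------------------
# Normalization and summarization
# ---------------------------------------------------------------------------

def _quantile_normalize_values(values: np.ndarray) -> np.ndarray:
    """Force all columns to share the rank-mean reference distribution.

    Reference = mean of the column-sorted values at each rank. Tied values
    within a column receive the mean of the reference over the tied rank
    range, so ties stay ties and the column multiset is preserved exactly.
    """
    n, _ = values.shape
    order = np.argsort(values, axis=0, kind="stable")
    ref = np.take_along_axis(values, order, axis=0).mean(axis=1)
    out = np.empty_like(values, dtype=float)
    for j in range(values.shape[1]):
        col_order = order[:, j]
        sorted_col = values[col_order, j]
        new_group = np.r_[True, sorted_col[1:] != sorted_col[:-1]]
        group_id = np.cumsum(new_group) - 1
        sums = np.bincount(group_id, weights=ref)
        counts = np.bincount(group_id)
        out[col_order, j] = (sums / counts)[group_id]
    return out


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize the matrix across sample columns.

    After normalization every column's sorted value multiset is identical.
    Idempotent; raises if the matrix is already flagged as normalized.
    """
    if m.normalized:
        raise ValueError("matrix is already normalized")
    values = m.data.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("cannot normalize non-finite values")
    normed = _quantile_normalize_values(values)
    data = pd.DataFrame(normed, index=m.data.index, columns=m.data.columns)
    return ExpressionMatrix(data=data, design=m.design, normalized=True)


def mean_by_timepoint(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-probe per-time-point mean over replicates (probes x time points).

    Needed wherever a 6-point expression profile must be commensurate with
    the 6-point phenotype series.
    """
    cols = {}
    for t in m.design.time_points:
        names = m.columns_for_timepoint(t)
        if not names:
            raise ValueError(f"time point {t} has no samples")
        cols[t] = m.data[names].mean(axis=1)
    return pd.DataFrame(cols, index=m.data.index)
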