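"""Seed-anchored Pearson co-expression graph construction and analysis.

The 19 IMP-pathway seed genes are correlated against every differential
probe across all sample columns; pairs at or above the correlation cutoff
(0.85 by default, signed) become edges of an undirected weighted graph.
Connected components are the sub-networks; probes sharing a gene symbol are
collapsed into non-redundant gene nodes.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .data_model import ExpressionMatrix, ProbeAnnotation, SeedGeneSet

__all__ = [
    "ConstantProfileError",
    "pearson_correlation",
    "seed_correlation_table",
    "build_coexpression_graph",
    "connected_components",
    "collapse_redundant_probes",
    "coexpressed_counts",
    "write_sif",
    "write_graphml",
]


class ConstantProfileError(ValueError):
    """Pearson correlation is undefined for a constant vector."""


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation of two equal-length vectors (n >= 3)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("vectors must be 1-d and of equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 observations")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        raise ConstantProfileError("correlation undefined for a constant vector")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _seed_probe_map(
    seeds: SeedGeneSet, annotation: ProbeAnnotation, matrix: ExpressionMatrix
) -> tuple[dict[str, list[str]], list[str]]:
    """Seed symbol -> probes present on the matrix; plus missing seeds."""
    mapping: dict[str, list[str]] = {}
    missing: list[str] = []
    probe_set = set(matrix.probe_ids)
    for gene in seeds:
        probes = [p for p in annotation.probes_for_symbol(gene) if p in probe_set]
        if probes:
            mapping[gene] = probes
        else:
            missing.append(gene)
    if missing:
        warnings.warn(
            f"seed genes without probes on the matrix (skipped): {missing}",
            stacklevel=3,
        )
    return mapping, missing


def seed_correlation_table(
    m: ExpressionMatrix,
    seeds: SeedGeneSet,
    candidates: Iterable[str],
    annotation: ProbeAnnotation,
) -> pd.DataFrame:
    """Pearson r for every (seed probe, candidate probe) pair.

    Correlations are computed across all sample columns. Seed-seed pairs
    are included once (unordered). Returns columns: seed_probe, seed_gene,
    candidate_probe, r.
    """
    seed_map, _ = _seed_probe_map(seeds, annotation, m)
    seed_probes = [p for probes in seed_map.values() for p in probes]
    seed_genes = {p: g for g, probes in seed_map.items() for p in probes}
    candidate_probes = sorted(set(candidates) - set(seed_probes))
    absent = [p for p in candidate_probes if p not in m.probe_ids]
    if absent:
        raise KeyError(f"candidate probes not on the matrix: {absent[:5]}")

    values = m.data
    seed_arr = values.loc[seed_probes].to_numpy(dtype=float)
    rows: list[tuple[str, str, str, float]] = []

    if candidate_probes:
        cand_arr = values.loc[candidate_probes].to_numpy(dtype=float)
        r_block = _rowwise_pearson(seed_arr, cand_arr)
        for i, sp in enumerate(seed_probes):
            for j, cp in enumerate(candidate_probes):
                rows.append((sp, seed_genes[sp], cp, r_block[i, j]))
    if len(seed_probes) > 1:
        r_ss = _rowwise_pearson(seed_arr, seed_arr)
        for i in range(len(seed_probes)):
            for j in range(i + 1, len(seed_probes)):
                rows.append(
                    (
                        seed_probes[i],
                        seed_genes[seed_probes[i]],
                        seed_probes[j],
                        r_ss[i, j],
                    )
                )
    return pd.DataFrame(rows, columns=["seed_probe", "seed_gene", "candidate_probe", "r"])


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Correlation matrix between the rows of ``a`` and the rows of ``b``."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    an = np.sqrt((ac**2).sum(axis=1))
    bn = np.sqrt((bc**2).sum(axis=1))
    if (an == 0).any() or (bn == 0).any():
        raise ConstantProfileError("constant profile in correlation block")
    return np.clip((ac @ bc.T) / np.outer(an, bn), -1.0, 1.0)


def build_coexpression_graph(
    table: pd.DataFrame,
    threshold: float = 0.85,
    *,
    absolute: bool = False,
    annotation: ProbeAnnotation | None = None,
) -> nx.Graph:
    """Threshold the correlation table into an undirected weighted graph.

    An edge is added for every record with r >= threshold (or |r| when
    ``absolute``). All seed probes remain as nodes even when isolated;
    candidate probes appear only when incident to an edge. Node attributes:
    ``role`` in {seed, coexpressed}, ``gene_symbol`` when an annotation is
    given.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    g = nx.Graph(threshold=threshold, absolute=absolute)
    for sp, sg in zip(table["seed_probe"], table["seed_gene"]):
        if sp not in g:
            g.add_node(sp, role="seed", gene_symbol=sg)
    seed_probes = set(table["seed_probe"])
    for row in table.itertuples(index=False):
        r = row.r
        if (abs(r) if absolute else r) >= threshold:
            for node in (row.seed_probe, row.candidate_probe):
                if node not in g:
                    role = "seed" if node in seed_probes else "coexpressed"
                    symbol = (
                        annotation.gene_symbol(node)
                        if annotation is not None and node in annotation
                        else node
                    )
                    g.add_node(node, role=role, gene_symbol=symbol)
            if row.seed_probe != row.candidate_probe:
                g.add_edge(row.seed_probe, row.candidate_probe, r=float(r))
    if annotation is not None:
        for node, data in g.nodes(data=True):
            if "gene_symbol" not in data or data["gene_symbol"] == node:
                if node in annotation:
                    data["gene_symbol"] = annotation.gene_symbol(node)
                else:
                    data.setdefault("gene_symbol", node)
    return g


def connected_components(g: nx.Graph) -> list[set[str]]:
    """Maximal connected node sets, largest first, ties by smallest member."""
    comps = [set(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), min(map(str, c))))


def collapse_redundant_probes(g: nx.Graph, annotation: ProbeAnnotation) -> nx.Graph:
    """Merge probes sharing a gene symbol into single gene-level nodes.

    The merged node takes the gene symbol as its id, inherits the union of
    incident edges, and keeps the max-|r| weight where parallel edges
    collapse. Probes without annotation are kept as-is (warned).
    """
    uncovered = [n for n in g.nodes if n not in annotation]
    if uncovered:
        warnings.warn(
            f"{len(uncovered)} nodes lack annotation and are kept unmerged",
            stacklevel=2,
        )
    node_map = {
        n: (annotation.gene_symbol(n) if n in annotation else n) for n in g.nodes
    }
    out = nx.Graph(**g.graph)
    for n, data in g.nodes(data=True):
        target = node_map[n]
        if target in out:
            # a merged node is a seed if any member probe was a seed
            if data.get("role") == "seed":
                out.nodes[target]["role"] = "seed"
        else:
            out.add_node(
                target,
                role=data.get("role", "coexpressed"),
                gene_symbol=target if n in annotation else data.get("gene_symbol", n),
            )
    for u, v, data in g.edges(data=True):
        cu, cv = node_map[u], node_map[v]
        if cu == cv:
            continue  # intra-gene edge disappears with the merge
        r = float(data.get("r", 0.0))
        if out.has_edge(cu, cv):
            if abs(r) > abs(out[cu][cv]["r"]):
                out[cu][cv]["r"] = r
        else:
            out.add_edge(cu, cv, r=r)
    return out


def coexpressed_counts(g: nx.Graph, seeds: SeedGeneSet) -> dict[str, int | None]:
    """Per-seed count of non-seed neighbors; None when the seed is absent.

    Works on both probe-level and collapsed gene-level graphs: a seed's
    nodes are those whose gene_symbol matches and whose role is 'seed'.
    """
    by_symbol: dict[str, list[str]] = {}
    for n, data in g.nodes(data=True):
        if data.get("role") == "seed":
            by_symbol.setdefault(str(data.get("gene_symbol", n)), []).append(n)
    counts: dict[str, int | None] = {}
    for gene in seeds:
        nodes = by_symbol.get(gene)
        if not nodes:
            counts[gene] = None
            continue
        neighbors: set[str] = set()
        for n in nodes:
            for nb in g.neighbors(n):
                if g.nodes[nb].get("role") != "seed":
                    neighbors.add(nb)
        counts[gene] = len(neighbors)
    return counts


def write_sif(g: nx.Graph, path: str | Path, relation: str = "coexp") -> None:
    with open(path, "w") as fh:
        isolated = [n for n in g.nodes if g.degree(n) == 0]
        for u, v in sorted(map(lambda e: tuple(sorted(map(str, e))), g.edges)):
            fh.write(f"{u}\t{relation}\t{v}\n")
        for n in sorted(map(str, isolated)):
            fh.write(f"{n}\n")


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, str(path))
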