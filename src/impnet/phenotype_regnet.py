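"""Phenotype-anchored regulatory network construction.

Candidate regulators (CGs) are the genes present in every one of several
independently built regulator networks AND in the co-expression network.
The 19 seed genes, the CGs, and the IMP-content phenotype are then joined
into a correlation network thresholded at |r| >= 0.7, the phenotype's
neighbors are split by correlation sign, and literature regulator edges are
merged in under an explicit group-pair edge policy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .coexpression_network import ConstantProfileError

__all__ = [
    "IMP_GENE",
    "CG",
    "INTERMEDIATE",
    "PHENOTYPE",
    "DEFAULT_KEEP_PAIRS",
    "IntersectionReport",
    "RegulatoryNetwork",
    "PhenotypeRelation",
    "intersect_candidate_networks",
    "phenotype_correlation_matrix",
    "build_threshold_graph",
    "classify_phenotype_relation",
    "merge_regulatory_network",
    "read_edge_table",
    "write_regnet_graphml",
]

IMP_GENE = "IMP_GENE"
CG = "CG"
INTERMEDIATE = "INTERMEDIATE"
PHENOTYPE = "PHENOTYPE"

#: Unordered group pairs whose *correlation* edges survive the merge.
#: Same-group edges and direct CG-IMP_GENE edges are dropped; anything
#: touching the phenotype node is kept.
DEFAULT_KEEP_PAIRS: frozenset[frozenset[str]] = frozenset(
    {
        frozenset({INTERMEDIATE, IMP_GENE}),
        frozenset({INTERMEDIATE, CG}),
        frozenset({PHENOTYPE, IMP_GENE}),
        frozenset({PHENOTYPE, CG}),
        frozenset({PHENOTYPE, INTERMEDIATE}),
    }
)


@dataclass(frozen=True)
class IntersectionReport:
    """Both stages of the candidate-gene filter, reported explicitly."""

    in_all_networks: frozenset[str]
    survivors: frozenset[str]

    @property
    def removed_not_coexpressed(self) -> frozenset[str]:
        return self.in_all_networks - self.survivors


def intersect_candidate_networks(
    networks: Mapping[str, Iterable[str]],
    coexpression_nodes: Iterable[str],
) -> IntersectionReport:
    """Genes present in every candidate network and in the co-expression net.

    Stage 1 intersects the node sets of all candidate networks; stage 2
    drops genes absent from the co-expression network. Both stages are
    returned so the pipeline can report the filtered-out genes.
    """
    if len(networks) < 2:
        raise ValueError("need at least two candidate networks to intersect")
    sets = {name: set(nodes) for name, nodes in networks.items()}
    for name, s in sets.items():
        if not s:
            warnings.warn(f"candidate network {name!r} is empty", stacklevel=2)
    in_all: set[str] = set.intersection(*sets.values())
    survivors = in_all & set(coexpression_nodes)
    return IntersectionReport(frozenset(in_all), frozenset(survivors))


def phenotype_correlation_matrix(
    profiles: pd.DataFrame,
    phenotype: pd.Series,
    phenotype_name: str = "IMP_content",
) -> pd.DataFrame:
    """Symmetric Pearson matrix over gene profiles plus a phenotype row/column.

    ``profiles`` is genes x time points (rows are per-time-point mean
    expression); ``phenotype`` must share the same ordered time points.
    Constant profiles yield NaN rows/columns and a warning listing them.
    """
    if list(profiles.columns) != list(phenotype.index):
        raise ValueError("profiles and phenotype must share ordered time points")
    if profiles.shape[1] < 3:
        raise ValueError("need at least 3 time points")
    combined = pd.concat(
        [profiles, phenotype.to_frame(phenotype_name).T]
    )
    values = combined.to_numpy(dtype=float)
    sd = values.std(axis=1)
    flagged = combined.index[sd == 0].tolist()
    if flagged:
        warnings.warn(
            f"constant profiles with undefined correlations: {flagged}",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=combined.index, columns=combined.index)


def build_threshold_graph(
    corr: pd.DataFrame,
    min_abs_r: float = 0.7,
    groups: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Correlation network keeping off-diagonal pairs with |r| >= min_abs_r.

    Edge weight keeps the sign of r. Node attribute ``group`` is taken from
    ``groups`` when provided.
    """
    if not 0.0 < min_abs_r <= 1.0:
        raise ValueError("min_abs_r must be in (0, 1]")
    g = nx.Graph(threshold=min_abs_r)
    names = list(corr.index)
    for n in names:
        g.add_node(n, group=(groups or {}).get(n, INTERMEDIATE))
    arr = corr.to_numpy(dtype=float)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = arr[i, j]
            if np.isfinite(r) and abs(r) >= min_abs_r:
                g.add_edge(names[i], names[j], weight=float(r))
    return g


@dataclass(frozen=True)
class PhenotypeRelation:
    positive: frozenset[str]
    negative: frozenset[str]
    unrelated: frozenset[str]


def classify_phenotype_relation(
    g: nx.Graph, phenotype_node: str = "IMP_content"
) -> PhenotypeRelation:
    """Partition non-phenotype nodes by the sign of their phenotype edge."""
    if phenotype_node not in g:
        raise KeyError(f"phenotype node {phenotype_node!r} absent from graph")
    positive, negative = set(), set()
    for nb in g.neighbors(phenotype_node):
        if g[phenotype_node][nb]["weight"] >= 0:
            positive.add(nb)
        else:
            negative.add(nb)
    unrelated = set(g.nodes) - positive - negative - {phenotype_node}
    return PhenotypeRelation(
        frozenset(positive), frozenset(negative), frozenset(unrelated)
    )


@dataclass
class RegulatoryNetwork:
    """Mixed network: undirected correlation edges + directed regulator edges.

    ``groups`` assigns every node to IMP_GENE / CG / INTERMEDIATE /
    PHENOTYPE; correlation edges carry the signed r, regulator edges a
    provenance string (empty provenance marks a hypothesized edge, the
    dashed lines of the merged figure).
    """

    groups: dict[str, str] = field(default_factory=dict)
    corr_edges: dict[frozenset[str], float] = field(default_factory=dict)
    reg_edges: list[tuple[str, str, str, bool]] = field(default_factory=list)
    # reg edge: (source, target, provenance, hypothesized)

    def nodes(self) -> set[str]:
        return set(self.groups)


def merge_regulatory_network(
    corr_net: nx.Graph,
    regulator_edges: Sequence[tuple] | pd.DataFrame,
    *,
    keep_pairs: frozenset[frozenset[str]] = DEFAULT_KEEP_PAIRS,
) -> RegulatoryNetwork:
    """Union the correlation network with directed regulator edges, then
    prune correlation edges by the group-pair policy.

    The default policy keeps INTERMEDIATE-IMP_GENE, INTERMEDIATE-CG and all
    phenotype edges, dropping same-group edges and direct CG-IMP_GENE
    links. Regulator edges are always kept, tagged hypothesized when they
    carry no provenance.
    """
    groups: dict[str, str] = {}
    for n, data in corr_net.nodes(data=True):
        grp = data.get("group")
        if grp is None:
            raise ValueError(f"node {n!r} has no group")
        groups[n] = grp

    if isinstance(regulator_edges, pd.DataFrame):
        reg_iter = [
            (
                row.source,
                row.target,
                getattr(row, "group_source", INTERMEDIATE),
                getattr(row, "group_target", INTERMEDIATE),
                str(getattr(row, "provenance", "") or ""),
            )
            for row in regulator_edges.itertuples(index=False)
        ]
    else:
        reg_iter = [
            (e[0], e[1], e[2], e[3], str(e[4]) if len(e) > 4 else "")
            for e in regulator_edges
        ]

    net = RegulatoryNetwork(groups=dict(groups))
    for src, tgt, gsrc, gtgt, prov in reg_iter:
        for node, grp in ((src, gsrc), (tgt, gtgt)):
            if node in net.groups and net.groups[node] != grp:
                raise ValueError(
                    f"node {node!r} is {net.groups[node]} in the correlation "
                    f"network but {grp} in the regulator edges"
                )
            net.groups[node] = grp
        prov = prov if prov.lower() not in {"", "nan", "none"} else ""
        net.reg_edges.append((src, tgt, prov, prov == ""))

    for u, v, data in corr_net.edges(data=True):
        pair = frozenset({net.groups[u], net.groups[v]})
        if pair in keep_pairs:
            net.corr_edges[frozenset({u, v})] = float(data["weight"])
    net.reg_edges.sort()
    return net


def read_edge_table(path: str | Path) -> pd.DataFrame:
    """TSV regulator/candidate edge table.

    Columns: source, target, directed (0/1), group_source, group_target,
    provenance (may be empty -> hypothesized).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"source", "target", "directed", "group_source", "group_target"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"edge table missing columns: {sorted(missing)}")
    if "provenance" not in df.columns:
        df["provenance"] = ""
    return df


def write_regnet_graphml(net: RegulatoryNetwork, path: str | Path) -> None:
    g = nx.MultiDiGraph()
    for n, grp in net.groups.items():
        g.add_node(n, group=grp)
    for pair, w in net.corr_edges.items():
        u, v = sorted(pair)
        g.add_edge(u, v, kind="correlation", weight=w, hypothesized=False)
    for src, tgt, prov, hyp in net.reg_edges:
        g.add_edge(
            src, tgt, kind="regulator", provenance=prov, hypothesized=bool(hyp)
        )
    nx.write_graphml(g, str(path))
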