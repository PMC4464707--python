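"""Typed pathway graphs: merging edge-list files, degrees, hubs, membership.

Pathway files are TSV edge lists with typed endpoints (gene or compound)
and a pathway id per edge. Merging unions nodes and edges while tracking
edge provenance (which pathways contributed each edge); the "total degree"
of a node is its simple degree on the deduplicated merged edge set.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .data_model import SeedGeneSet

__all__ = [
    "read_pathway_edgelist",
    "read_pathway_edgelists",
    "write_pathway_edgelist",
    "merge_networks",
    "node_degrees",
    "select_hubs",
    "pathway_membership",
    "write_pathway_graphml",
]

_VALID_KINDS = {"gene", "compound"}


def _add_typed_node(g: nx.Graph, node_id: str, kind: str, context: str) -> None:
    if kind not in _VALID_KINDS:
        raise ValueError(f"unknown node kind {kind!r} ({context})")
    existing = g.nodes[node_id]["kind"] if node_id in g else None
    if existing is not None and existing != kind:
        raise ValueError(
            f"node {node_id!r} is {existing!r} elsewhere but {kind!r} ({context})"
        )
    g.add_node(node_id, kind=kind)


def read_pathway_edgelist(path: str | Path) -> nx.Graph:
    """Read one TSV file: source_id, source_kind, target_id, target_kind, pathway_id."""
    path = Path(path)
    g = nx.Graph(name=path.stem)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(
                    f"{path.name}:{lineno}: expected 5 tab-separated fields, "
                    f"got {len(parts)}"
                )
            src, src_kind, tgt, tgt_kind, pathway = parts
            ctx = f"{path.name}:{lineno}"
            if src == tgt:
                raise ValueError(f"{ctx}: self-edge on {src!r}")
            _add_typed_node(g, src, src_kind, ctx)
            _add_typed_node(g, tgt, tgt_kind, ctx)
            if g.has_edge(src, tgt):
                g[src][tgt]["pathways"].add(pathway)
            else:
                g.add_edge(src, tgt, pathways={pathway})
    return g


def read_pathway_edgelists(paths: Iterable[str | Path]) -> list[nx.Graph]:
    return [read_pathway_edgelist(p) for p in paths]


def write_pathway_edgelist(g: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v, data in sorted(
            g.edges(data=True), key=lambda e: tuple(sorted((str(e[0]), str(e[1]))))
        ):
            u, v = sorted((str(u), str(v)))
            for pw in sorted(data["pathways"]):
                fh.write(
                    f"{u}\t{g.nodes[u]['kind']}\t{v}\t{g.nodes[v]['kind']}\t{pw}\n"
                )


def merge_networks(graphs: Sequence[nx.Graph]) -> nx.Graph:
    """Union of pathway graphs: nodes, edges, and edge provenance sets.

    Idempotent and order-independent. A node id carrying conflicting kinds
    across files is an error.
    """
    merged = nx.Graph(name="merged")
    for g in graphs:
        for n, data in g.nodes(data=True):
            _add_typed_node(merged, n, data["kind"], f"graph {g.graph.get('name')}")
        for u, v, data in g.edges(data=True):
            if merged.has_edge(u, v):
                merged[u][v]["pathways"] |= set(data["pathways"])
            else:
                merged.add_edge(u, v, pathways=set(data["pathways"]))
    return merged


def node_degrees(g: nx.Graph) -> pd.DataFrame:
    """(node, kind, degree) on the deduplicated edge set, sorted by degree desc."""
    rows = [
        (n, g.nodes[n].get("kind", "gene"), g.degree(n)) for n in g.nodes
    ]
    df = pd.DataFrame(rows, columns=["node", "kind", "degree"])
    return df.sort_values(["degree", "node"], ascending=[False, True]).reset_index(
        drop=True
    )


def select_hubs(
    degrees: pd.DataFrame,
    kind_filter: str = "any",
    min_degree: int = 10,
    strict: bool = True,
) -> set[str]:
    """Nodes of the requested kind with degree > min_degree (strict) or >=.

    The strict default matches the hub definition of "total degree of more
    than 10".
    """
    if min_degree < 0:
        raise ValueError("min_degree must be >= 0")
    df = degrees
    if kind_filter != "any":
        df = df[df["kind"] == kind_filter]
    mask = df["degree"] > min_degree if strict else df["degree"] >= min_degree
    return set(df.loc[mask, "node"])


def pathway_membership(
    g: nx.Graph, genes: SeedGeneSet | Iterable[str]
) -> tuple[dict[str, set[str]], dict[str, int]]:
    """Per-gene pathway sets and per-pathway gene counts.

    A gene's pathway set is the union of the provenance of its incident
    edges; genes absent from the graph map to the empty set. The count
    table drives the pathways-per-gene histogram.
    """
    gene_pathways: dict[str, set[str]] = {}
    for gene in genes:
        if gene not in g:
            gene_pathways[gene] = set()
            continue
        pws: set[str] = set()
        for _, _, data in g.edges(gene, data=True):
            pws |= set(data["pathways"])
        gene_pathways[gene] = pws
    pathway_counts: dict[str, int] = {}
    for pws in gene_pathways.values():
        for pw in pws:
            pathway_counts[pw] = pathway_counts.get(pw, 0) + 1
    return gene_pathways, pathway_counts


def write_pathway_graphml(g: nx.Graph, path: str | Path) -> None:
    # GraphML cannot store sets; serialize provenance as a sorted '|' join
    out = nx.Graph(**{k: v for k, v in g.graph.items()})
    out.add_nodes_from(g.nodes(data=True))
    for u, v, data in g.edges(data=True):
        out.add_edge(u, v, pathways="|".join(sorted(data["pathways"])))
    nx.write_graphml(out, str(path))
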