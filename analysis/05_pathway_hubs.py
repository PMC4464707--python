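#!/usr/bin/env python
"""Merge the per-pathway edge lists into one gene-compound network and
select hub genes and hub compounds (degree strictly greater than 10)."""

import argparse
from pathlib import Path

from impnet.pathway_network import (
    merge_networks,
    node_degrees,
    read_pathway_edgelists,
    select_hubs,
    write_pathway_graphml,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--min-degree", type=int, default=10)
    args = ap.parse_args()

    files = sorted((args.results / "pathways").glob("pathway_*.tsv"))
    merged = merge_networks(read_pathway_edgelists(files))
    degrees = node_degrees(merged)
    hub_genes = select_hubs(degrees, "gene", args.min_degree, strict=True)
    hub_compounds = select_hubs(degrees, "compound", args.min_degree, strict=True)

    degrees.to_csv(args.results / "pathway_degrees.tsv", sep="\t", index=False)
    write_pathway_graphml(merged, args.results / "pathway_merged.graphml")

    print(
        f"merged {len(files)} pathway files: {merged.number_of_nodes()} nodes, "
        f"{merged.number_of_edges()} edges"
    )
    print(f"hub genes ({len(hub_genes)}): {', '.join(sorted(hub_genes))}")
    print(f"hub compounds ({len(hub_compounds)}): {', '.join(sorted(hub_compounds))}")


if __name__ == "__main__":
    main()
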