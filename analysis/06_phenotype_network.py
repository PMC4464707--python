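#!/usr/bin/env python
"""Correlate gene expression profiles with the IMP-content phenotype
series, build the |r| >= 0.7 phenotype graph, and classify genes as
positively or negatively IMP-related."""

import argparse
from pathlib import Path

from impnet.data_model import (
    SeedGeneSet,
    StudyDesign,
    mean_by_timepoint,
    read_annotation,
    read_expression_matrix,
)
from impnet.phenotype_regnet import (
    CG,
    IMP_GENE,
    PHENOTYPE,
    build_threshold_graph,
    classify_phenotype_relation,
    merge_regulatory_network,
    phenotype_correlation_matrix,
    write_regnet_graphml,
)
from impnet.synthetic_data import SimulationSpec, generate_phenotype


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--min-abs-r", type=float, default=0.7)
    args = ap.parse_args()

    matrix = read_expression_matrix(
        args.results / "expression_normalized.tsv", StudyDesign()
    )
    annotation = read_annotation(args.results / "annotation.tsv")
    spec = SimulationSpec(seed=args.seed)
    seeds = SeedGeneSet()

    means = mean_by_timepoint(matrix)
    means.index = [annotation.gene_symbol(p) for p in means.index]
    genes = [g for g in seeds if g in means.index]
    seed_symbols = set(genes)
    genes += [
        g for g, _ in spec.phenotype_couplings
        if g in means.index and g not in seed_symbols
    ]
    profiles = means.loc[genes]

    series, raw = generate_phenotype(spec, profiles)
    corr = phenotype_correlation_matrix(profiles, series)
    groups = {g: (IMP_GENE if g in seed_symbols else CG) for g in profiles.index}
    groups[series.name] = PHENOTYPE
    graph = build_threshold_graph(corr, args.min_abs_r, groups)
    relation = classify_phenotype_relation(graph, series.name)
    regnet = merge_regulatory_network(graph, [])

    write_regnet_graphml(regnet, args.results / "regulatory_network.graphml")
    raw.to_csv(args.results / "phenotype_raw.tsv", sep="\t", index=False)

    print(f"positively IMP-related: {', '.join(sorted(relation.positive)) or '-'}")
    print(f"negatively IMP-related: {', '.join(sorted(relation.negative)) or '-'}")


if __name__ == "__main__":
    main()
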