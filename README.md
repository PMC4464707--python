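# impnet

Seed-gene-anchored co-expression and regulatory network analysis of
inosine monophosphate (IMP) content in developing chicken breast muscle.

IMP is the main flavor nucleotide of meat. Its concentration in breast
muscle changes with age, and the genes of IMP metabolism (synthesis,
degradation, salvage) form a natural anchor set for asking which other
genes — and ultimately which phenotype differences — move with them.
`impnet` implements that analysis end to end:

1. **Normalize** a probes × chips expression matrix (quantile
   normalization with explicit tie handling).
2. **Filter** probes by per-age one-way ANOVA with Benjamini–Hochberg
   correction (adjusted p ≤ 0.05) and signed fold change (|fc| ≥ 2).
3. **Anchor** a Pearson co-expression network on 19 IMP-metabolism seed
   genes (edges at r ≥ 0.85), with component extraction and gene-level
   probe collapsing.
4. **Merge** gene–compound pathway edge lists with provenance tracking
   and select hub genes/compounds (degree > 10).
5. **Correlate** expression profiles against the IMP phenotype series
   (|r| ≥ 0.7) and assemble a typed regulatory network (IMP genes,
   candidate genes, intermediates, phenotype) under group-pair rules.
6. **Validate** with Livak 2^−ΔΔCt qPCR quantification and
   qPCR–microarray concordance (exact t-transform p-values).
7. **Summarize** the phenotype: per-age/sex means ± SE, n-weighted pooled
   totals, cross-sex correlation, and compact letter displays from
   pairwise Welch tests.

A deterministic synthetic-data generator plants known modules, fold
changes, hubs, and phenotype couplings so the whole pipeline is testable
without the original chips. See [docs/methods.md](docs/methods.md) for
models, parameters, and limitations.

## Worked example

The package ships the study's reference tables (per-age IMP content by
sex, and qPCR/microarray fold-change profiles for four validation genes).
The headline numbers are computed, not stored:

```python
from impnet.datasets import imp_phenotype_series, qpcr_validation_profiles
from impnet.phenotype_stats import cross_group_correlation, pooled_mean
from impnet.qpcr_concordance import concordance

pheno = imp_phenotype_series()
male = pheno[pheno["group"] == "male"].sort_values("time_point")
female = pheno[pheno["group"] == "female"].sort_values("time_point")
r = cross_group_correlation(male["mean"].tolist(), female["mean"].tolist())
print(f"male/female IMP correlation: r = {r:.3f}")

rows = pheno[(pheno["time_point"] == 4) & (pheno["group"] != "total")]
pairs = list(zip(rows["mean"], rows["n"]))
print(f"pooled 4 wk total: {pooled_mean(pairs):.4f}")

q, a = qpcr_validation_profiles()["Bmpr2"]
res = concordance(q, a)
print(f"Bmpr2 qPCR vs microarray: r = {res.r:.4f}, p = {res.p:.4f}, n = {res.n}")
```

Output:

```
male/female IMP correlation: r = 0.822
pooled 4 wk total: 3.8470
Bmpr2 qPCR vs microarray: r = 0.9251, p = 0.0082, n = 6
```

## Running the analysis

Numbered scripts under `analysis/` run the study step by step, writing
everything under `results/`:

```sh
python analysis/01_simulate_study.py --seed 0
python analysis/02_normalize_expression.py
python analysis/03_differential_filter.py
python analysis/04_coexpression_network.py
python analysis/05_pathway_hubs.py
python analysis/06_phenotype_network.py --seed 0
python analysis/07_qpcr_concordance.py --seed 0
python analysis/08_phenotype_statistics.py
```

Representative output (seed 0):

```
133 of 2000 probes pass the differential filter
network: 111 nodes, 92 edges, 19 components; 111 genes after collapse
hub genes (7): HUBG00, HUBG01, HUBG02, HUBG03, HUBG04, HUBG05, HUBG06
positively IMP-related: Adsl, Entpd4
negatively IMP-related: Bmpr2, Prps2
cross-sex IMP profile correlation: r = 0.822 (n = 6)
```

The same stages are available as one command:

```sh
impnet run --seed 0 --out-dir results/pipeline
```

Reruns with the same seed and configuration are byte-identical (apart
from timings inside the JSON run report).

## Reproduction

All tests, including the headline-value and planted-recovery checks:

```sh
python -m pytest -q tests/
```

The acceptance script recomputes the main quantities (cross-sex
correlation, pooled totals, qPCR concordance r and p, planted-module
recovery precision/recall) and writes them as JSON; every random stream
derives from `--seed`:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/impnet/` — the library (data model, differential filter,
  co-expression, pathway, phenotype/regulatory network, qPCR, phenotype
  statistics, synthetic data, CLI).
- `analysis/` — thin numbered drivers over the library.
- `scripts/acceptance.py` — deterministic headline-quantity report.
- `tests/` — unit, property-based (hypothesis), and acceptance tests.
- `docs/methods.md` — models, parameters, numerical choices, limitations.
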