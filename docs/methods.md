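# Methods

This note records the statistical models, algorithms, default parameters,
and numerical choices behind `impnet`, and what the bundled synthetic data
generator does and does not attempt to model.

## Study design

The package models a developmental time-course microarray study of chicken
breast muscle: six ages (2, 4, 6, 8, 10, 12 weeks), one male and one female
chip per age (12 chips), with the 2-week samples as the fold-change
baseline. The phenotype of interest is muscle inosine monophosphate (IMP)
content, measured on individual birds grouped by age and sex. Nineteen
IMP-metabolism genes act as *seed genes* for network construction; a
further set of differentially expressed candidate genes (CGs) is screened
against the phenotype.

## Normalization

`quantile_normalize` maps every chip to a common reference distribution:
the reference is the row-wise mean of the column-sorted matrix, and each
column's values are replaced by the reference value at their rank. Ties are
handled by assigning every member of a tied span the mean of the reference
values over that span, so ties stay ties and each column's sum over a tied
span is preserved. Consequences worth knowing:

- For tie-free columns, all normalized columns are exact permutations of
  the reference distribution, and the transform is idempotent.
- With ties, cross-column multiset identity is deliberately relaxed in
  favor of within-column tie preservation.
- A `normalized` flag on the matrix refuses accidental double
  normalization; re-running on the raw values is a no-op by construction.

## Differential filter

Each probe is tested with a one-way fixed-effects ANOVA across the six
ages (`scipy.stats.f_oneway`, vectorized across probes). Degenerate cases
are pinned: a probe with identical values everywhere gets p = 1; zero
within-group variance with unequal group means gets p = 0 (with a warning).
With two chips per age the test is valid but low-powered; the package warns
when any group has fewer than three replicates.

P-values are adjusted with Benjamini–Hochberg (`statsmodels`
`multipletests`, `fdr_bh`; Bonferroni available). Signed fold changes use
the convention s = r if r ≥ 1 else −1/r, where r = 2^(Δlog2) against the
baseline age. The filter is inclusive at its boundaries: a probe passes
with adjusted p ≤ 0.05 **and** max |s| ≥ 2.0.

## Co-expression network

The network is seed-anchored: Pearson correlations are computed only
between seed-gene probes and filter-surviving probes (plus seed–seed
pairs), never all-vs-all. An edge requires signed r ≥ 0.85 by default
(`--absolute` switches to |r| ≥ 0.85). Seed probes are always retained as
nodes even when isolated. Components are ordered by size (ties broken by
smallest member). `collapse_redundant_probes` merges probes of the same
gene symbol, keeping the edge of maximal |r| per gene pair. Correlation is
undefined for constant profiles and raises rather than returning NaN
silently.

## Pathway network

Pathway files are 5-column TSV edge lists (node, kind, node, kind, pathway)
with `kind` in {gene, compound}; parsing errors report file and line
number. `merge_networks` takes the union of nodes and edges, merging
per-edge pathway-provenance sets; conflicting kinds for the same node
raise. Hubs are nodes with degree **strictly greater** than the cutoff
(default 10) within a kind.

## Phenotype and regulatory network

Gene expression profiles are reduced to six per-age means and correlated
with the six-point phenotype series. Genes join the phenotype graph when
|r| ≥ 0.7 (signed weight retained); `classify_phenotype_relation`
partitions the phenotype's neighbors into positively and negatively
IMP-related sets. The regulatory merge keeps correlation edges only for
allowed group pairs — {intermediate, IMP gene}, {intermediate, CG}, and
any pair involving the phenotype — dropping same-group and direct CG–IMP
gene edges, and adds hypothesized directed regulatory edges with
provenance.

## Phenotype statistics

- Per-age, per-sex summaries report mean, standard error (SE = sd/√n,
  ddof 1) and n; cells with n = 1 are rejected.
- Pooled (total) means are n-weighted: Σ nᵢmᵢ / Σ nᵢ. The packaged male
  and female rows reproduce the packaged totals at every age to ≤ 5×10⁻⁴
  (≤ 10⁻³ at 12 wk, where the published total carries more rounding).
- The cross-sex profile correlation is plain Pearson over the six ages
  (r = 0.822 for the packaged series).
- Compact letter displays are built from pairwise Welch t-tests: the
  "not significantly different" relation defines a graph whose maximal
  cliques (networkx `find_cliques`) become letters, so two groups share a
  letter exactly when their pairwise test is non-significant.

## qPCR quantification and concordance

Relative expression uses the Livak 2^−ΔΔCt method with the 2-week age as
calibrator; the calibrator's ratio is exactly 1. Replicate Ct values are
averaged per age before differencing, so any linear drift in the reference
gene cancels. Signed fold changes are the same s = r or −1/r convention.
Concordance between a qPCR and a microarray fold-change profile is Pearson
r over the six ages, with the two-tailed p from the exact t transform
t = r√(n−2)/√(1−r²) (cross-checked against `scipy.stats.pearsonr` and a
Monte-Carlo null in the tests). For the four packaged validation genes this
yields r (p): Bmpr2 0.925 (0.008), Prps2 0.863 (0.027), Gja1 0.986
(0.0003), Pecam1 0.799 (0.056).

## Synthetic data generator

The generator exists so that every pipeline stage can be exercised, and
its planted structure recovered, without the original chips. Defaults
(`SimulationSpec`): 2,000 probes, the 12-chip design above, three planted
co-expression modules (Entpd8 ×60, Gart ×30, Ppat ×10 members) at
generating correlation ρ = 0.95, 10% decoy differentially expressed
probes, log2 effect amplitude 2.5, phenotype couplings Adsl +0.9 and
Bmpr2 −0.9, and eight pathway files planting exactly seven gene hubs and
seven compound hubs of degree > 10.

Noise decomposition (the load-bearing choice): a module's latent profile
is its age pattern plus a per-age biological wobble (sd 0.25) shared by
the two sex chips of that age, plus per-chip technical noise (sd 0.1).
Member probes add independent noise whose total variance is fixed by ρ
(var = latent·(1/ρ² − 1)), split half at the age level and half per chip.
Sharing the age-level components across the sex replicates is what makes
two chips per age sufficient for the ANOVA to detect planted effects —
mirroring the empirical observation that male and female profiles track
each other closely — while decoy/null probes carry large i.i.d. noise
(sd 0.8) that suppresses spurious seed correlations.

Phenotype coupling is exact, not approximate: the six-point phenotype
series is built by Gram–Schmidt so its sample correlation with each anchor
profile equals the target to machine precision (multi-anchor targets solve
a linear system in the anchors' Gram basis; the orthogonal completion uses
the Gram-inverse projector since anchors need not be orthogonal). Jointly
opposite couplings (+0.9/−0.9) are only attainable when the two anchor
profiles anticorrelate, so the generator plants the coupling genes' probes
from one shared "driver" age pattern, sign-flipped for negative targets.
Individual-level phenotype measurements are then drawn around the series.

Ct tables are generated by inverting 2^−ΔΔCt exactly; with `noise_sd` 0
the round trip recovers the input profile to 10⁻⁹, and added Ct noise is
mean-zero in log2-ratio space.

All randomness flows from the single `seed` in `SimulationSpec`;
generation is byte-deterministic, and side streams (phenotype, coupling
genes, pathways, Ct noise) use fixed offsets of that seed so stages stay
independently reproducible.

### Generator scope and limitations

- Scale is deliberately desk-sized (2,000 probes vs ~10⁴–10⁵ on a real
  chip) so the whole pipeline and test suite run in seconds; thresholds
  and recovery behavior were chosen analytically for this scale and then
  verified, not tuned post hoc.
- The generator does not model probe-level effects (GC content, cross
  hybridization), array spatial artifacts, or non-Gaussian intensity
  distributions; quantile normalization is therefore nearly a no-op on
  synthetic data and is validated separately on adversarial inputs.
- Two replicates per age is faithful to the modeled design but makes the
  per-probe ANOVA fragile; real use with this few replicates should lean
  on the fold-change gate, as the default filter does.
- Pearson correlation over six points has wide sampling error; the exact
  t-based p-values are correct under bivariate normality but n = 6
  concordance values should be read as descriptive.
- The compact letter display is based on unadjusted pairwise Welch tests,
  matching common usage in phenotype tables, not on a familywise-corrected
  procedure.
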