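"""Seeded generators for every input the pipeline consumes, with truth tables.

The raw chips of the study are not deposited, so the pipeline is exercised
on synthetic data emulating its statistical structure: a 6-time-point x
2-replicate single-color design, planted co-expression modules anchored at
seed genes, differentially expressed decoy probes, a phenotype series with
exactly constructed gene couplings, Ct tables that invert the 2^-ddCt
estimator, and pathway edge-list files with planted hub degrees.

All randomness flows from one ``numpy.random.Generator`` per call; equal
specs and seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    DEFAULT_SEED_GENES,
    ExpressionMatrix,
    ProbeAnnotation,
    SeedGeneSet,
    StudyDesign,
)
from .qpcr_concordance import CtTable, FoldChangeProfile, signed_to_ratio

__all__ = [
    "ModuleSpec",
    "PathwaySpec",
    "SimulationSpec",
    "generate_study",
    "generate_phenotype",
    "generate_ct_table",
    "generate_pathway_files",
]


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-expression module anchored at a seed gene."""

    seed_gene: str
    n_members: int
    generating_correlation: float

    def __post_init__(self) -> None:
        if not 0.0 < self.generating_correlation < 1.0:
            raise ValueError("generating correlation must lie in (0, 1)")
        if self.n_members < 1:
            raise ValueError("a module needs at least one member")


@dataclass(frozen=True)
class PathwaySpec:
    """Layout of the synthetic pathway edge-list files."""

    n_pathways: int = 8
    nodes_per_pathway: int = 12
    hub_gene_degrees: tuple[int, ...] = (11, 12, 12, 13, 14, 15, 17)
    hub_compound_degrees: tuple[int, ...] = (11, 11, 12, 13, 14, 16, 18)
    background_max_degree: int = 4


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one synthetic study.

    Defaults are the desk-scale study conditions: 2,000 probes (a
    full-chip run uses 13,378), 6 time points x male/female replicates,
    three modules at generating correlation 0.95, 10% differentially
    expressed decoys with a 2.5 log2-unit time-course amplitude.
    """

    seed: int = 0
    n_probes: int = 2000
    design: StudyDesign = field(default_factory=StudyDesign)
    modules: tuple[ModuleSpec, ...] = (
        ModuleSpec("Entpd8", 60, 0.95),
        ModuleSpec("Gart", 30, 0.95),
        ModuleSpec("Ppat", 10, 0.95),
    )
    de_fraction: float = 0.1
    de_log2_effect: float = 2.5
    phenotype_couplings: tuple[tuple[str, float], ...] = (
        ("Adsl", 0.9),
        ("Bmpr2", -0.9),
    )
    ct_noise_sd: float = 0.2
    pathways: PathwaySpec = field(default_factory=PathwaySpec)
    base_mean: float = 8.0
    base_sd: float = 1.5
    sample_noise_sd: float = 0.8
    module_latent_noise_sd: float = 0.25
    technical_noise_sd: float = 0.1
    member_tp_noise_frac: float = 0.5

    def __post_init__(self) -> None:
        total_members = sum(m.n_members for m in self.modules)
        if self.n_probes < len(DEFAULT_SEED_GENES) + total_members + 10:
            raise ValueError("n_probes too small for seeds + module members")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        for gene, target in self.phenotype_couplings:
            if not abs(target) < 1.0:
                raise ValueError(
                    f"impossible phenotype coupling |r| >= 1 for {gene!r}"
                )


def _timepoint_pattern(
    rng: np.random.Generator, design: StudyDesign, amplitude: float
) -> np.ndarray:
    """Random per-time-point log2 effect, 0 at baseline, max |effect| = amplitude."""
    effects = rng.normal(0.0, 1.0, size=len(design.time_points))
    b = design.time_points.index(design.baseline)
    effects -= effects[b]
    peak = np.abs(effects).max()
    if peak == 0:
        effects[(b + 1) % len(effects)] = 1.0
        peak = 1.0
    effects *= amplitude / peak
    return effects


def _expand_to_samples(effects: np.ndarray, design: StudyDesign) -> np.ndarray:
    """Per-time-point vector -> per-sample vector in design column order."""
    return np.repeat(effects, len(design.replicates))


def generate_study(
    spec: SimulationSpec,
) -> tuple[ExpressionMatrix, ProbeAnnotation, dict[str, pd.DataFrame]]:
    """Synthesize the expression matrix, annotation and truth tables.

    Probe layout: the first 19 probes carry the seed genes; module members
    follow, then differentially expressed decoys, then null probes. Module
    members are the module's latent profile (seed-gene pattern + small
    shared-latent noise) mixed with independent per-sample noise so the
    population correlation with the seed equals the module's generating
    correlation. Decoy DE probes carry their own independent time-course
    pattern. Truth tables record module membership and DE status.
    """
    rng = np.random.default_rng(spec.seed)
    design = spec.design
    n_samples = len(design.samples)
    seeds = list(DEFAULT_SEED_GENES)
    module_seeds = {m.seed_gene for m in spec.modules}
    unknown = module_seeds - set(seeds)
    if unknown:
        raise ValueError(f"module seed genes not in the seed set: {sorted(unknown)}")

    probe_ids: list[str] = []
    symbols: list[str] = []
    rows: list[np.ndarray] = []
    module_rows: list[dict] = []
    de_rows: list[dict] = []

    def new_probe(symbol: str) -> str:
        pid = f"P{len(probe_ids):05d}"
        probe_ids.append(pid)
        symbols.append(symbol)
        return pid

    base_means = rng.normal(spec.base_mean, spec.base_sd, size=spec.n_probes)
    latents: dict[str, np.ndarray] = {}

    n_tp = len(design.time_points)
    tech_sd = spec.technical_noise_sd

    # Genes named in the phenotype couplings share one "driver" time-course
    # (sign-flipped for negative targets). Anchors that oppose each other
    # must themselves be anticorrelated, otherwise a phenotype correlating
    # +r with one and -r with the other cannot exist (the squared
    # correlations with near-orthogonal directions would exceed 1).
    coupling_signs = {
        g: (1.0 if r > 0 else -1.0)
        for g, r in spec.phenotype_couplings
        if r != 0.0
    }
    rng_pheno_genes = np.random.default_rng(spec.seed + 101)
    driver_samples = (
        _expand_to_samples(
            _timepoint_pattern(rng_pheno_genes, design, spec.de_log2_effect), design
        )
        if coupling_signs
        else np.zeros(n_samples)
    )

    # 1. seed-gene probes. A module seed's latent is its time-course
    # pattern plus a time-point-level biological wobble (shared by the two
    # sex replicates, which the study reports as highly correlated) plus a
    # small per-chip technical term.
    for gene in seeds:
        pid = new_probe(gene)
        mu = base_means[len(probe_ids) - 1]
        if gene in module_seeds:
            effects = _timepoint_pattern(rng, design, spec.de_log2_effect)
            tp_wobble = rng.normal(0.0, spec.module_latent_noise_sd, size=n_tp)
            latent = _expand_to_samples(effects + tp_wobble, design) + rng.normal(
                0.0, tech_sd, size=n_samples
            )
            latents[gene] = latent
            rows.append(mu + latent)
            de_rows.append({"probe_id": pid, "is_de": True})
        else:
            row = mu + rng.normal(0.0, 0.35, size=n_samples)
            if gene in coupling_signs:
                row = row + coupling_signs[gene] * driver_samples
                de_rows.append({"probe_id": pid, "is_de": True})
            else:
                de_rows.append({"probe_id": pid, "is_de": False})
            rows.append(row)

    # 2. module members: latent + independent noise split between a
    # time-point-level component and a per-sample component so the
    # population correlation with the seed equals the generating value.
    for mod in spec.modules:
        latent = latents[mod.seed_gene]
        rho = mod.generating_correlation
        noise_var = latent.var() * (1.0 / rho**2 - 1.0)
        tp_sd = np.sqrt(spec.member_tp_noise_frac * noise_var)
        samp_sd = np.sqrt((1.0 - spec.member_tp_noise_frac) * noise_var)
        for k in range(mod.n_members):
            pid = new_probe(f"M{mod.seed_gene.upper()}{k:03d}")
            mu = base_means[len(probe_ids) - 1]
            eps = _expand_to_samples(
                rng.normal(0.0, tp_sd, size=n_tp), design
            ) + rng.normal(0.0, samp_sd, size=n_samples)
            rows.append(mu + latent + eps)
            module_rows.append(
                {
                    "probe_id": pid,
                    "seed_gene": mod.seed_gene,
                    "generating_correlation": rho,
                }
            )
            de_rows.append({"probe_id": pid, "is_de": True})

    # 3. decoy DE probes (own independent time-course pattern, noisy chip
    # profile) and exchangeable null probes.
    extra_genes = [g for g in coupling_signs if g not in seeds]
    n_remaining = spec.n_probes - len(probe_ids) - len(extra_genes)
    n_de = int(round(spec.de_fraction * spec.n_probes))
    n_de = min(n_de, n_remaining)
    for k in range(n_remaining):
        is_de = k < n_de
        pid = new_probe(f"G{len(probe_ids):05d}")
        mu = base_means[len(probe_ids) - 1]
        profile = mu + rng.normal(0.0, spec.sample_noise_sd, size=n_samples)
        if is_de:
            effects = _timepoint_pattern(rng, design, spec.de_log2_effect)
            profile = profile + _expand_to_samples(effects, design)
        rows.append(profile)
        de_rows.append({"probe_id": pid, "is_de": is_de})

    # 4. candidate genes named in the phenotype couplings but absent from
    # the seed set get an expressed probe of their own.
    for gene in extra_genes:
        pid = new_probe(gene)
        mu = base_means[len(probe_ids) - 1]
        rows.append(
            mu
            + coupling_signs[gene] * driver_samples
            + rng_pheno_genes.normal(0.0, 0.35, size=n_samples)
        )
        de_rows.append({"probe_id": pid, "is_de": True})

    data = pd.DataFrame(
        np.vstack(rows), index=pd.Index(probe_ids, name="probe_id"),
        columns=design.sample_names,
    )
    matrix = ExpressionMatrix(data=data, design=design)

    ann = pd.DataFrame(
        {
            "gene_symbol": symbols,
            "gene_id": [f"ID{i:06d}" for i in range(len(probe_ids))],
            "is_seed": [s in seeds for s in symbols],
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    annotation = ProbeAnnotation(table=ann.astype({"gene_symbol": str, "gene_id": str}))

    truth = {
        "modules": pd.DataFrame(
            module_rows, columns=["probe_id", "seed_gene", "generating_correlation"]
        ),
        "de": pd.DataFrame(de_rows, columns=["probe_id", "is_de"]),
    }
    return matrix, annotation, truth


def _coupled_series(
    rng: np.random.Generator, anchor: np.ndarray, target_r: float
) -> np.ndarray:
    """Unit-variance series with exact sample correlation to ``anchor``.

    Gram-Schmidt construction: the anchor is centered and normalized to u;
    a random draw is orthogonalized against u and the constant vector and
    normalized to v; the result is target*u + sqrt(1-target^2)*v, which has
    sample correlation exactly ``target_r`` with the anchor.
    """
    n = len(anchor)
    u = anchor - anchor.mean()
    nu = np.linalg.norm(u)
    if nu == 0:
        raise ValueError("anchor profile is constant; coupling undefined")
    u /= nu
    for _ in range(64):
        z = rng.normal(size=n)
        v = z - z.mean()
        v -= (v @ u) * u
        nv = np.linalg.norm(v)
        if nv > 1e-8:
            v /= nv
            break
    else:  # pragma: no cover - essentially impossible
        raise RuntimeError("failed to draw an orthogonal complement")
    return target_r * u + np.sqrt(1.0 - target_r**2) * v


def generate_phenotype(
    spec: SimulationSpec,
    profiles: pd.DataFrame,
    *,
    mean_level: float = 3.5,
    amplitude: float = 0.5,
    se: float = 0.2,
    n_per_cell: int = 12,
) -> tuple[pd.Series, pd.DataFrame]:
    """Phenotype series with exact correlations to the coupled genes.

    ``profiles`` is genes x time points (mean expression). The pooled
    (total) series is constructed so its sample correlation with each
    coupled gene's profile equals the coupling target exactly (to machine
    precision); with several couplings the series solves the linear system
    in the orthonormalized anchor basis. Individual-level male/female
    measurements are then drawn around the series with the given SE and n.

    Returns (total series indexed by time point, raw individuals DataFrame
    with columns time_point, group, value).
    """
    rng = np.random.default_rng(spec.seed + 1)
    tps = list(profiles.columns)
    n = len(tps)
    couplings = spec.phenotype_couplings
    for gene, _ in couplings:
        if gene not in profiles.index:
            raise KeyError(f"coupling gene {gene!r} not in profiles")

    if not couplings:
        w = _coupled_series(rng, rng.normal(size=n), 0.0)
    else:
        anchors = []
        for gene, _ in couplings:
            a = profiles.loc[gene].to_numpy(dtype=float)
            a = a - a.mean()
            norm = np.linalg.norm(a)
            if norm == 0:
                raise ValueError(f"coupling gene {gene!r} has a constant profile")
            anchors.append(a / norm)
        U = np.column_stack(anchors)  # n x k unit anchor vectors
        t = np.array([r for _, r in couplings], dtype=float)
        gram = U.T @ U
        alpha = np.linalg.solve(gram, t)
        w_par = U @ alpha
        par_norm_sq = float(t @ alpha)
        if par_norm_sq > 1.0 + 1e-12:
            raise ValueError("phenotype couplings are jointly impossible")
        # orthogonal completion to unit norm. The anchors are generally
        # not mutually orthogonal, so projecting onto their span needs the
        # Gram inverse (U (U'U)^-1 U'), not U U'. The columns of U are
        # centered, so the projection preserves centering.
        for _ in range(64):
            z = rng.normal(size=n)
            v = z - z.mean()
            v -= U @ np.linalg.solve(gram, U.T @ v)
            nv = np.linalg.norm(v)
            if nv > 1e-8:
                v /= nv
                break
        else:  # pragma: no cover
            raise RuntimeError("failed to complete the coupling basis")
        w = w_par + np.sqrt(max(0.0, 1.0 - par_norm_sq)) * v

    series = pd.Series(
        mean_level + amplitude * w * np.sqrt(n), index=tps, name="IMP_content"
    )

    sd_individual = se * np.sqrt(n_per_cell)
    raw_rows = []
    for t in tps:
        for group in ("male", "female"):
            offset = rng.normal(0.0, se / 2.0)
            vals = rng.normal(series[t] + offset, sd_individual, size=n_per_cell)
            for v in vals:
                raw_rows.append({"time_point": t, "group": group, "value": v})
    raw = pd.DataFrame(raw_rows)
    return series, raw


def generate_ct_table(
    true_fold_changes: FoldChangeProfile,
    reference_drift: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    n_replicates: int = 3,
    reference_gene: str = "Gapdh",
    calibrator_delta_ct: float = 3.0,
    reference_base_ct: float = 16.0,
) -> CtTable:
    """Ct records whose noiseless 2^-ddCt recovers the input profile exactly.

    The calibrator is the profile's first time point. ``reference_drift``
    shifts the reference gene's Ct linearly across time points (the
    estimator is invariant to it); ``noise_sd`` adds independent N(0, sd^2)
    cycles to every recorded Ct value.
    """
    rng = np.random.default_rng(seed)
    calibrator = true_fold_changes.time_points[0]
    rows = []
    for i, (tp, signed) in enumerate(
        zip(true_fold_changes.time_points, true_fold_changes.values)
    ):
        ratio = signed_to_ratio(signed)
        dd_ct = -np.log2(ratio)
        d_ct = calibrator_delta_ct + dd_ct
        ct_ref = reference_base_ct + reference_drift * i
        for rep in range(n_replicates):
            rows.append(
                {
                    "time_point": tp,
                    "replicate": f"r{rep + 1}",
                    "ct_target": ct_ref + d_ct + rng.normal(0.0, noise_sd)
                    if noise_sd
                    else ct_ref + d_ct,
                    "ct_reference": ct_ref + rng.normal(0.0, noise_sd)
                    if noise_sd
                    else ct_ref,
                }
            )
    return CtTable(
        gene=true_fold_changes.gene,
        reference_gene=reference_gene,
        records=pd.DataFrame(rows),
        calibrator=calibrator,
    )


def generate_pathway_files(
    spec: SimulationSpec, out_dir: str | Path
) -> tuple[list[Path], pd.DataFrame]:
    """Write pathway edge-list files whose merged union has planted degrees.

    Hub genes connect to distinct compounds (and vice versa for hub
    compounds), so merged degrees equal the planted values exactly;
    background gene-compound edges give every pathway additional
    low-degree nodes. Each edge is assigned to one pathway file; a hub's
    star is spread across several files so merging is actually exercised.

    Returns (file paths, truth table with columns node, kind, degree).
    """
    rng = np.random.default_rng(spec.seed + 2)
    ps = spec.pathways
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    edges: list[tuple[str, str, str, str]] = []  # (src, src_kind, tgt, tgt_kind)
    leaf_counter = [0]

    def new_leaf(kind: str) -> str:
        leaf_counter[0] += 1
        return f"{'LG' if kind == 'gene' else 'LC'}{leaf_counter[0]:04d}"

    for h, deg in enumerate(ps.hub_gene_degrees):
        hub = f"HUBG{h:02d}"
        for _ in range(deg):
            edges.append((hub, "gene", new_leaf("compound"), "compound"))
    for h, deg in enumerate(ps.hub_compound_degrees):
        hub = f"HUBC{h:02d}"
        for _ in range(deg):
            edges.append((new_leaf("gene"), "gene", hub, "compound"))

    # background chains: alternating gene-compound paths (degree <= 2)
    for p in range(ps.n_pathways):
        prev, prev_kind = f"BGG{p:02d}_0", "gene"
        for k in range(1, ps.nodes_per_pathway):
            kind = "compound" if prev_kind == "gene" else "gene"
            node = f"BG{'C' if kind == 'compound' else 'G'}{p:02d}_{k}"
            if prev_kind == "gene":
                edges.append((prev, prev_kind, node, kind))
            else:
                edges.append((node, kind, prev, prev_kind))
            prev, prev_kind = node, kind

    # assign each edge to a pathway file; duplicate a sample of edges into a
    # second file so provenance merging is exercised
    assignment = rng.integers(0, ps.n_pathways, size=len(edges))
    files: list[list[str]] = [[] for _ in range(ps.n_pathways)]
    for (src, sk, tgt, tk), p in zip(edges, assignment):
        files[p].append(f"{src}\t{sk}\t{tgt}\t{tk}\tpw{p:02d}")
    dup_idx = rng.choice(len(edges), size=max(1, len(edges) // 10), replace=False)
    for i in dup_idx:
        src, sk, tgt, tk = edges[i]
        p2 = (assignment[i] + 1) % ps.n_pathways
        files[p2].append(f"{src}\t{sk}\t{tgt}\t{tk}\tpw{p2:02d}")

    paths = []
    for p, lines in enumerate(files):
        path = out_dir / f"pathway_{p:02d}.tsv"
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        paths.append(path)

    # planted degrees counted straight off the (deduplicated) edge list
    degree: dict[str, int] = {}
    kind_of: dict[str, str] = {}
    for src, sk, tgt, tk in edges:
        degree[src] = degree.get(src, 0) + 1
        degree[tgt] = degree.get(tgt, 0) + 1
        kind_of[src], kind_of[tgt] = sk, tk
    truth = (
        pd.DataFrame(
            [(n, kind_of[n], d) for n, d in degree.items()],
            columns=["node", "kind", "degree"],
        )
        .sort_values(["degree", "node"], ascending=[False, True])
        .reset_index(drop=True)
    )
    truth.to_csv(out_dir / "truth_degrees.tsv", sep="\t", index=False)
    return paths, truth
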