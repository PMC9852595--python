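"""Synthetic multi-omics cohorts with planted, recoverable structure.

The generator emulates the statistical architecture the analysis relies on,
without modelling raw array intensities or sequencing reads:

* per-CpG baseline methylation drawn from a bimodal M-value mixture (a
  methylated and an unmethylated mode), matching the bimodal beta histograms
  of array data;
* a planted set of CpGs differentially methylated between CLL and de novo
  DLBCL, with effects applied on the M scale so beta-values cannot leave
  [0, 1] (additive beta effects would saturate near the boundaries); the
  target group beta-differential defaults to 0.35;
* a disjoint planted set of IGHV CpGs shifted in IGHV-unmutated samples of
  every group, so the score-CpG selection cascade has something to exclude;
* RS samples split into a CLL-like subpopulation (sharing the CLL effect
  pattern) and a DLBCL-like subpopulation (sharing the DLBCL pattern), both
  carrying a global hypomethylation shift;
* negative-binomial expression counts whose signature genes separate the two
  RS subpopulations, and a subset of promoters whose methylation is coupled
  to expression at a configurable Spearman correlation.

Every random draw flows through the single config seed; equal configs give
bit-identical cohorts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    BetaMatrix,
    CountMatrix,
    CpGAnnotation,
    GeneAnnotation,
    SampleSheet,
    ValidationError,
    write_cpg_annotation,
    write_gene_annotation,
    write_matrix,
    write_sample_sheet,
)

logger = logging.getLogger(__name__)

_LN2 = math.log(2.0)


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults mirror the emulated study design."""

    seed: int
    # cohort sizes
    n_cll_u: int = 40
    n_cll_m: int = 40
    n_dlbcl: int = 60
    n_rs_cll_like: int = 30
    n_rs_dlbcl_like: int = 10
    # methylation
    n_cpgs: int = 20_000
    frac_cll_dlbcl_differential: float = 0.05
    delta_beta_effect: float = 0.35
    frac_ighv_differential: float = 0.03
    ighv_effect_m: float = 2.0
    rs_global_hypomethylation_shift: float = -0.5
    noise_sd_m: float = 0.5
    frac_rs_cll_like_unmutated: float = 0.8
    # expression
    n_genes: int = 5_000
    frac_signature_genes: float = 0.04
    expression_effect_sd: float = 1.0
    n_correlated_promoters: int = 50
    n_promoter_genes: int = 200
    promoter_signal_sd_m: float = 2.0
    promoter_cpg_noise_sd_m: float = 0.2  # within-island CpGs are tightly co-methylated
    target_rho: float = -0.6
    nb_dispersion: float = 0.1
    mean_library_size: float = 64e6
    library_size_log_sd: float = 0.05
    # nuisance
    covariate_leak_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is mandatory")
        for name in ("frac_cll_dlbcl_differential", "frac_ighv_differential",
                     "frac_signature_genes", "frac_rs_cll_like_unmutated"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must be in [0,1]")
        for name in ("n_cll_u", "n_cll_m", "n_dlbcl", "n_rs_cll_like", "n_rs_dlbcl_like"):
            if getattr(self, name) < 3:
                raise ValidationError(f"{name} must be >= 3")


@dataclass
class SimulatedTruth:
    """Planted parameters against which recovery is scored."""

    cll_dlbcl_cpgs: dict = field(default_factory=dict)   # cpg_id -> signed beta effect
    ighv_cpgs: list = field(default_factory=list)
    rs_labels: dict = field(default_factory=dict)        # sample_id -> CLL_derived|DLBCL_like
    signature_up: list = field(default_factory=list)
    signature_down: list = field(default_factory=list)
    promoter_truth: list = field(default_factory=list)   # dicts: gene, target, cpgs, true_rho
    achieved_delta_beta: float = float("nan")


@dataclass
class CohortBundle:
    """One simulated cohort: matrices, annotations and ground truth."""

    config: SimulationConfig
    beta: BetaMatrix
    sheet: SampleSheet
    cpg_annotation: CpGAnnotation
    counts: CountMatrix | None = None
    gene_annotation: GeneAnnotation | None = None
    truth: SimulatedTruth | None = None

    def write(self, out_dir) -> dict:
        """Write TSV/BED artifacts plus a manifest with sha256 checksums."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_matrix(self.beta, out / "beta.tsv")
        write_sample_sheet(self.sheet, out / "samples.tsv")
        write_cpg_annotation(self.cpg_annotation, out / "cpgs.bed", out / "cpg_gene_links.tsv")
        if self.counts is not None:
            write_matrix(self.counts, out / "counts.tsv")
        if self.gene_annotation is not None:
            write_gene_annotation(self.gene_annotation, out / "genes.tsv")
        if self.truth is not None:
            with open(out / "truth.json", "w") as fh:
                json.dump(_truth_doc(self.truth), fh, indent=1)
        manifest = {
            "config": asdict(self.config),
            "files": {
                p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted(out.iterdir())
                if p.name != "manifest.json"
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        return manifest


def _truth_doc(t: SimulatedTruth) -> dict:
    d = asdict(t)
    return d


def _sigmoid2(m: np.ndarray) -> np.ndarray:
    return np.where(m >= 0, 1.0 / (1.0 + np.exp2(-m)), np.exp2(m) / (1.0 + np.exp2(m)))


def _logit2(b: float) -> float:
    return math.log2(b / (1.0 - b))


def simulate_methylation(cfg: SimulationConfig) -> CohortBundle:
    """Generate the methylation arm of a cohort (beta, sheet, annotation, truth)."""
    rng = np.random.default_rng(cfg.seed)
    truth = SimulatedTruth()

    # ---- samples -------------------------------------------------------
    sample_ids, groups, ighv = [], [], []

    def add(prefix, n, group, statuses):
        for i in range(n):
            sample_ids.append(f"{prefix}{i + 1:03d}")
            groups.append(group)
            ighv.append(statuses[i])

    add("CLLU", cfg.n_cll_u, "CLL", ["U"] * cfg.n_cll_u)
    add("CLLM", cfg.n_cll_m, "CLL", ["M"] * cfg.n_cll_m)
    add("DLB", cfg.n_dlbcl, "DLBCL", ["M"] * cfg.n_dlbcl)
    rs_cll_u = rng.random(cfg.n_rs_cll_like) < cfg.frac_rs_cll_like_unmutated
    add("RSC", cfg.n_rs_cll_like, "RS", np.where(rs_cll_u, "U", "M").tolist())
    add("RSD", cfg.n_rs_dlbcl_like, "RS", ["M"] * cfg.n_rs_dlbcl_like)
    n_samples = len(sample_ids)
    for sid in sample_ids:
        if sid.startswith("RSC"):
            truth.rs_labels[sid] = "CLL_derived"
        elif sid.startswith("RSD"):
            truth.rs_labels[sid] = "DLBCL_like"

    groups_arr = np.asarray(groups)
    is_cll_side = np.array([g == "CLL" or s.startswith("RSC") for g, s in zip(groups, sample_ids)])
    is_dlbcl_side = np.array([g == "DLBCL" or s.startswith("RSD") for g, s in zip(groups, sample_ids)])
    is_rs = groups_arr == "RS"
    is_u = np.asarray(ighv) == "U"

    # B-cell content covariate (Dirichlet-ish proportions)
    bcell = rng.beta(8, 2, size=n_samples)  # centered ~0.8, like tumor-cell content
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": groups,
                "ighv_status": ighv,
                "bcell_fraction": bcell,
                "batch": "b1",
            }
        )
    )

    # ---- CpG layout ----------------------------------------------------
    cpg_ids = np.array([f"cg{i:07d}" for i in range(cfg.n_cpgs)])
    n_diff = round(cfg.frac_cll_dlbcl_differential * cfg.n_cpgs)
    n_ighv = round(cfg.frac_ighv_differential * cfg.n_cpgs)
    n_prom_genes = min(cfg.n_promoter_genes, cfg.n_genes)
    cpgs_per_prom = rng.integers(3, 6, size=n_prom_genes)
    n_prom_cpgs = int(cpgs_per_prom.sum())
    if n_diff + n_ighv + n_prom_cpgs > cfg.n_cpgs:
        raise ValidationError("n_cpgs too small for the requested planted sets")
    perm = rng.permutation(cfg.n_cpgs)
    idx_diff = perm[:n_diff]
    idx_ighv = perm[n_diff:n_diff + n_ighv]
    idx_prom = perm[n_diff + n_ighv:n_diff + n_ighv + n_prom_cpgs]

    # ---- baseline + effects on the M scale -----------------------------
    methylated = rng.random(cfg.n_cpgs) < 0.5
    base_m = np.where(methylated, rng.normal(3.0, 1.0, cfg.n_cpgs),
                      rng.normal(-3.0, 1.0, cfg.n_cpgs))
    M = np.tile(base_m[:, None], (1, n_samples)).astype(float)

    # planted CLL-vs-DLBCL CpGs: group means set on the beta scale around 0.5
    half = cfg.delta_beta_effect / 2.0
    signs = rng.choice([-1.0, 1.0], size=n_diff)
    m_hi = _logit2(0.5 + half)
    m_lo = _logit2(0.5 - half)
    for j, (i_cpg, s) in enumerate(zip(idx_diff, signs)):
        cll_m = m_hi if s > 0 else m_lo
        dlb_m = m_lo if s > 0 else m_hi
        M[i_cpg, is_cll_side] = cll_m
        M[i_cpg, is_dlbcl_side] = dlb_m
        truth.cll_dlbcl_cpgs[cpg_ids[i_cpg]] = float(s * cfg.delta_beta_effect)

    # IGHV CpGs shift IGHV-unmutated samples in every group
    for i_cpg in idx_ighv:
        M[i_cpg, :] = rng.normal(0.0, 0.5)  # intermediate baseline
        M[i_cpg, is_u] += cfg.ighv_effect_m
    truth.ighv_cpgs = [cpg_ids[i] for i in idx_ighv]

    # promoter CpGs: per-gene activity varying across samples
    prom_gene_ids = [f"G{i + 1:05d}" for i in range(n_prom_genes)]
    prom_activity = rng.normal(0.0, 1.0, size=(n_prom_genes, n_samples))
    prom_cpg_of_gene: dict[str, list[str]] = {}
    cursor = 0
    prom_base = rng.normal(0.0, 0.7, size=n_prom_genes)
    for gi, (gene, k) in enumerate(zip(prom_gene_ids, cpgs_per_prom)):
        rows = idx_prom[cursor:cursor + k]
        cursor += k
        M[rows, :] = prom_base[gi] + cfg.promoter_signal_sd_m * prom_activity[gi][None, :]
        prom_cpg_of_gene[gene] = [cpg_ids[i] for i in rows]

    # RS global hypomethylation, nuisance leak, then noise
    M[:, is_rs] += cfg.rs_global_hypomethylation_shift
    if cfg.covariate_leak_sd > 0:
        leak = rng.normal(0.0, cfg.covariate_leak_sd, size=cfg.n_cpgs)
        M += leak[:, None] * (bcell - bcell.mean())[None, :]
    noise_sd = np.full(cfg.n_cpgs, cfg.noise_sd_m)
    noise_sd[idx_prom] = cfg.promoter_cpg_noise_sd_m
    M += rng.normal(0.0, 1.0, size=M.shape) * noise_sd[:, None]

    beta_vals = _sigmoid2(M)
    beta = BetaMatrix(pd.DataFrame(beta_vals, index=cpg_ids, columns=sample_ids))

    # achieved group beta-differential at planted CpGs
    cll_ids = [s for s, g in zip(sample_ids, groups) if g == "CLL"]
    dlb_ids = [s for s, g in zip(sample_ids, groups) if g == "DLBCL"]
    db = (
        beta.values.loc[cpg_ids[idx_diff], cll_ids].mean(axis=1)
        - beta.values.loc[cpg_ids[idx_diff], dlb_ids].mean(axis=1)
    ).abs()
    truth.achieved_delta_beta = float(db.mean()) if n_diff else float("nan")
    if n_diff and truth.achieved_delta_beta < 0.8 * cfg.delta_beta_effect:
        logger.warning(
            "achieved |delta beta| %.3f below target %.3f (baseline saturation)",
            truth.achieved_delta_beta, cfg.delta_beta_effect,
        )

    # ---- annotations ---------------------------------------------------
    chrom_of = lambda i: f"chr{(i % 22) + 1}"
    pos = np.zeros(cfg.n_cpgs, dtype=int)
    links = []
    gene_tss = {g: 100_000 * (i + 1) for i, g in enumerate(prom_gene_ids)}
    feature_cycle = ["TSS200", "TSS1500", "FirstExon"]
    for gi, gene in enumerate(prom_gene_ids):
        for k, cpg in enumerate(prom_cpg_of_gene[gene]):
            i_cpg = int(np.where(cpg_ids == cpg)[0][0])
            offset = (-1) ** k * (50 + 150 * k)  # within 2 kb of the TSS
            pos[i_cpg] = gene_tss[gene] + offset
            links.append((cpg, gene, feature_cycle[k % 3]))
    # remaining CpGs: intergenic, far from any simulated TSS
    far = pos == 0
    # offset keeps every intergenic CpG >2 kb from any simulated TSS (multiples of 100 kb)
    pos[far] = 10_000_000 + 10_000 * np.arange(int(far.sum())) + 4_000
    chroms = np.array([chrom_of(i) for i in range(cfg.n_cpgs)])
    # keep promoter CpGs on their gene's chromosome
    for gi, gene in enumerate(prom_gene_ids):
        for cpg in prom_cpg_of_gene[gene]:
            i_cpg = int(np.where(cpg_ids == cpg)[0][0])
            chroms[i_cpg] = chrom_of(gi)
    ann = CpGAnnotation(
        pd.DataFrame({"cpg_id": cpg_ids, "chrom": chroms, "pos": pos}),
        pd.DataFrame(links, columns=["cpg_id", "gene_id", "feature_class"]),
    )

    truth.promoter_truth = [
        {"gene_id": g, "target_id": f"{g}.t1", "cpg_ids": prom_cpg_of_gene[g], "true_rho": 0.0}
        for g in prom_gene_ids
    ]

    return CohortBundle(config=cfg, beta=beta, sheet=sheet, cpg_annotation=ann, truth=truth)


def _expected_spearman(r: float, n: int) -> float:
    """Moran's expectation of the sample Spearman coefficient for bivariate normals."""
    return 6.0 / (math.pi * (n + 1)) * (math.asin(r) + (n - 2) * math.asin(r / 2.0))


def _pearson_for_expected_spearman(target: float, n: int) -> float:
    """Invert Moran's formula by bisection: Pearson r whose E[spearman] hits target."""
    lo, hi = 0.0, 0.999999
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _expected_spearman(mid, n) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_expression(cfg: SimulationConfig, bundle: CohortBundle) -> CohortBundle:
    """Add the expression arm: NB counts, gene annotation, updated truth."""
    if bundle.truth is None:
        raise ValidationError("simulate methylation first")
    rng = np.random.default_rng(cfg.seed + 1)  # independent stream, still seed-driven
    truth = bundle.truth
    sheet = bundle.sheet
    sample_ids = sheet.sample_ids
    n_samples = len(sample_ids)

    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    n_prom_genes = len(truth.promoter_truth)

    # signature genes: outside the promoter block so the two plantings stay separable
    n_sig = round(cfg.frac_signature_genes * cfg.n_genes)
    n_up = round(n_sig * 122 / 215)  # published up/down ratio
    sig_pool = list(range(n_prom_genes, cfg.n_genes))
    sig_idx = rng.choice(sig_pool, size=n_sig, replace=False)
    up_idx = set(sig_idx[:n_up].tolist())
    down_idx = set(sig_idx[n_up:].tolist())
    truth.signature_up = sorted(gene_ids[i] for i in up_idx)
    truth.signature_down = sorted(gene_ids[i] for i in down_idx)

    groups = sheet.frame["group"].to_numpy()
    is_cll_side = np.array(
        [g == "CLL" or truth.rs_labels.get(s) == "CLL_derived" for s, g in zip(sample_ids, groups)]
    )

    base = rng.normal(5.0, 2.0, size=cfg.n_genes)
    log2_mu = np.tile(base[:, None], (1, n_samples)).astype(float)
    for i in up_idx:
        log2_mu[i, is_cll_side] += cfg.expression_effect_sd
    for i in down_idx:
        log2_mu[i, is_cll_side] -= cfg.expression_effect_sd

    # methylation-expression coupling at planted promoters
    beta_v = bundle.beta.values
    planted = rng.choice(n_prom_genes, size=min(cfg.n_correlated_promoters, n_prom_genes),
                         replace=False)
    sigma_e = math.sqrt(cfg.nb_dispersion) / _LN2  # log2-scale NB noise sd (large-mean limit)
    rho = cfg.target_rho
    # Spearman target -> Pearson requirement. The integrome is computed on
    # the RS compartment, so the expected sample Spearman at that n is
    # inverted via Moran's finite-n expectation for bivariate normals, then
    # the attenuation from idiosyncratic per-CpG noise is undone (each CpG =
    # shared promoter signal + own noise; expression couples to the promoter
    # mean over k CpGs, k = 4 on average).
    n_rs = cfg.n_rs_cll_like + cfg.n_rs_dlbcl_like
    r_pearson = _pearson_for_expected_spearman(abs(rho), n_rs)
    k_mean = 4.0
    s2, e2 = cfg.promoter_signal_sd_m**2, cfg.promoter_cpg_noise_sd_m**2
    attenuation = math.sqrt((s2 + e2 / k_mean) / (s2 + e2))
    r_needed = min(0.99, r_pearson / attenuation)
    coupling = r_needed / math.sqrt(1.0 - r_needed**2) * sigma_e
    for pi in planted:
        rec = truth.promoter_truth[pi]
        rec["true_rho"] = rho
        gi = gene_ids.index(rec["gene_id"])
        prom_beta = beta_v.loc[rec["cpg_ids"], :].mean(axis=0).to_numpy()
        with np.errstate(divide="ignore"):
            prom_m = np.log2(np.clip(prom_beta, 1e-6, 1 - 1e-6) /
                             (1 - np.clip(prom_beta, 1e-6, 1 - 1e-6)))
        z = (prom_m - prom_m.mean()) / prom_m.std(ddof=0)
        log2_mu[gi, :] = base[gi] + math.copysign(coupling, rho) * z

    # library sizes and NB sampling
    lib = cfg.mean_library_size * np.exp(
        rng.normal(0.0, cfg.library_size_log_sd, size=n_samples)
    )
    rel = np.exp2(log2_mu)
    mu = rel / rel.sum(axis=0, keepdims=True) * lib[None, :]
    # NB parameterized by mean mu and dispersion phi: var = mu + phi*mu^2
    phi = cfg.nb_dispersion
    r = 1.0 / phi
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)

    genes_frame = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "transcript_ids": [f"{g}.t1" for g in gene_ids],
            "chrom": [f"chr{(i % 22) + 1}" for i in range(cfg.n_genes)],
            "tss": [100_000 * (i + 1) for i in range(cfg.n_genes)],
            "strand": ["+" if i % 2 == 0 else "-" for i in range(cfg.n_genes)],
            "biotype": ["protein_coding" if rng.random() < 0.85 else "lincRNA"
                        for _ in range(cfg.n_genes)],
        }
    )
    bundle.counts = CountMatrix(counts_df)
    bundle.gene_annotation = GeneAnnotation(genes_frame)
    return bundle


def simulate_screening_cohort(
    signature_entries: pd.Series,
    n_samples: int = 100,
    frac_rs_like: float = 0.08,
    effect_sd: float = 1.0,
    n_background_genes: int = 500,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Expression cohort for screening with the linear classifier score.

    Gene rows are log2-expression draws N(mu_g, sd_g). A fraction of samples
    ("RS-like") carries the signature imprint: each signature gene shifted by
    ``effect_sd`` gene-level standard deviations in the direction of its
    weight. Returns (log2 expression frame, boolean RS-like mask).
    """
    rng = np.random.default_rng(seed)
    sig_genes = list(signature_entries.index)
    genes = sig_genes + [f"BG{i + 1:04d}" for i in range(n_background_genes)]
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    n_rs = max(1, round(frac_rs_like * n_samples))
    is_rs = np.zeros(n_samples, dtype=bool)
    is_rs[rng.choice(n_samples, size=n_rs, replace=False)] = True
    mu = rng.normal(6.0, 2.0, size=len(genes))
    sd = rng.uniform(0.5, 1.5, size=len(genes))
    x = mu[:, None] + sd[:, None] * rng.normal(size=(len(genes), n_samples))
    w = signature_entries.to_numpy(dtype=float)
    x[: len(sig_genes), :] += np.outer(w * effect_sd * sd[: len(sig_genes)], is_rs)
    return pd.DataFrame(x, index=genes, columns=sample_ids), is_rs


PRESETS = {
    "small": dict(
        n_cpgs=2_000, n_genes=500, n_cll_u=15, n_cll_m=15, n_dlbcl=15,
        n_rs_cll_like=10, n_rs_dlbcl_like=5, n_correlated_promoters=20,
        n_promoter_genes=60, mean_library_size=2e6,
    ),
    "medium": dict(
        n_cpgs=20_000, n_genes=5_000, n_cll_u=40, n_cll_m=40, n_dlbcl=60,
        n_rs_cll_like=30, n_rs_dlbcl_like=10, n_correlated_promoters=50,
        n_promoter_genes=200, mean_library_size=64e6,
    ),
}


def make_gold_cohort(preset: str, seed: int = 17, out_dir=None) -> CohortBundle:
    """Deterministic full bundle (methylation + expression) for a named preset."""
    if preset not in PRESETS:
        raise ValidationError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    cfg = SimulationConfig(seed=seed, **PRESETS[preset])
    bundle = simulate_methylation(cfg)
    bundle = simulate_expression(cfg, bundle)
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
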