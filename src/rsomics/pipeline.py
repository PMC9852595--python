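"""End-to-end orchestration: simulate/load -> differential -> LPS -> RNA-seq
prep -> integration -> signature -> LCS, with per-stage artifact writing and a
run report that records thresholds, seed and selection-funnel counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import integration, lcs, lps, rnaseq, signature
from .datamodel import (
    BetaMatrix,
    SampleSheet,
    ValidationError,
    beta_to_m,
    read_cpg_annotation,
    read_gene_annotation,
    read_matrix,
    read_sample_sheet,
    write_matrix,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and every stage threshold; defaults are the published values."""

    input_dir: str
    output_dir: str
    seed: int = 17
    fdr: float = 0.01
    delta_beta: float = 0.30
    lps_threshold: float = 0.98
    alpha: float = 0.05
    top_fraction: float = 0.25
    window: int = 2000
    min_cpgs: int = 3
    rho_cut: float = 1.0 / 3.0
    p_cut: float = 0.001
    min_samples: int = 2
    min_mean_reads: float | None = None
    prior_count: float = 0.5
    covariates: tuple[str, ...] = ()

    def validate(self) -> None:
        checks = [
            (0 < self.fdr < 1, "fdr must be in (0,1)"),
            (0 <= self.delta_beta < 1, "delta_beta must be in [0,1)"),
            (0.5 < self.lps_threshold <= 1, "lps_threshold must be in (0.5,1]"),
            (0 < self.alpha < 1, "alpha must be in (0,1)"),
            (0 < self.top_fraction <= 1, "top_fraction must be in (0,1]"),
            (self.window >= 0, "window must be >= 0"),
            (self.min_cpgs >= 1, "min_cpgs must be >= 1"),
            (0 < self.rho_cut < 1, "rho_cut must be in (0,1)"),
            (0 < self.p_cut < 1, "p_cut must be in (0,1)"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValidationError(msg)
        if not Path(self.input_dir).is_dir():
            raise ValidationError(f"input directory not found: {self.input_dir}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)


def load_inputs(input_dir):
    """Read a cohort directory (the layout written by the simulator)."""
    d = Path(input_dir)
    beta = read_matrix(d / "beta.tsv", "beta")
    sheet = read_sample_sheet(d / "samples.tsv")
    cpgs = read_cpg_annotation(d / "cpgs.bed", d / "cpg_gene_links.tsv")
    counts = read_matrix(d / "counts.tsv", "count") if (d / "counts.tsv").exists() else None
    genes = read_gene_annotation(d / "genes.tsv") if (d / "genes.tsv").exists() else None
    return beta, sheet, cpgs, counts, genes


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns the run report dictionary."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config), "stages": {}}

    def stage(name):
        logger.info("stage: %s", name)
        return report["stages"].setdefault(name, {})

    try:
        beta, sheet, cpgs, counts, genes = load_inputs(config.input_dir)
    except FileNotFoundError as exc:
        raise ValidationError(f"missing input file: {exc}") from exc

    beta = beta.align(sheet).drop_incomplete()
    m = beta_to_m(beta)
    s = stage("inputs")
    s.update(n_cpgs=beta.shape[0], n_samples=beta.shape[1])

    # --- methylation LPS -------------------------------------------------
    model, rs_results = lps.train_and_score(
        beta, m, sheet,
        fdr_cut=config.fdr, delta_cut=config.delta_beta,
        threshold=config.lps_threshold, covariate_names=tuple(config.covariates),
    )
    model.to_json(out / "lps_model.json")
    rs_results.to_csv(out / "lps_results.tsv", sep="\t", index_label="sample_id")
    s = stage("lps")
    s.update(model.selection_funnel)
    s.update(labels=rs_results["label"].value_counts().to_dict())

    if counts is None:
        report["stages"]["rnaseq"] = {"skipped": "no count matrix supplied"}
        _write_report(report, out)
        return report

    # --- expression prep --------------------------------------------------
    counts = counts.align(sheet)
    expr, factors = rnaseq.prepare(
        counts, min_samples=config.min_samples,
        min_mean_reads=config.min_mean_reads, prior_count=config.prior_count,
    )
    write_matrix(expr, out / "log2cpm.tsv")
    factors.factors.to_csv(out / "tmm_factors.tsv", sep="\t", index_label="sample_id")
    s = stage("rnaseq")
    s.update(n_features_kept=expr.shape[0], n_features_input=len(counts.feature_ids))

    # --- integration on RS samples ---------------------------------------
    rs_ids = sheet.samples_in_group("RS")
    skeleton = integration.build_integrome(cpgs, genes, window=config.window)
    t2f = {t: g for t, g in zip(skeleton["target_id"], skeleton["gene_id"])}
    assocs = integration.correlate_integrome(
        skeleton,
        BetaMatrix(beta.values.loc[:, rs_ids]),
        type(expr)(expr.values.loc[:, rs_ids]),
        target_to_feature=t2f,
    )
    assocs.to_csv(out / "integrome.tsv", sep="\t", index=False)
    significant = integration.filter_significant(assocs, p_cut=0.01, rho_cut=config.rho_cut)
    candidates, gene_lists = integration.select_candidates(
        assocs, min_cpgs=config.min_cpgs, rho_cut=config.rho_cut, p_cut=config.p_cut
    )
    integration.candidates_frame(candidates).to_csv(
        out / "candidate_regions.tsv", sep="\t", index=False
    )
    s = stage("integration")
    s.update(
        n_associations=len(assocs),
        n_significant=len(significant),
        n_candidates=len(candidates),
        n_candidate_genes=len(gene_lists["union"]),
    )

    # --- signature + LCS ---------------------------------------------------
    labelled = rs_results[rs_results["label"] != lps.LABEL_INTERMEDIATE]
    cll_ids = list(labelled.index[labelled["label"] == lps.LABEL_CLL])
    dlb_ids = list(labelled.index[labelled["label"] == lps.LABEL_DLBCL])
    sig = None
    if len(cll_ids) >= 3 and len(dlb_ids) >= 3:
        rs_expr = type(expr)(expr.values.loc[:, rs_ids])
        integrome_genes = set(significant["gene_id"])
        try:
            up, down = signature.derive_cluster_pair(rs_expr, sheet, cll_ids, dlb_ids)
            sig = signature.extract_signature(up, down, genes, integrome_genes)
        except ValidationError as exc:
            logger.warning("signature derivation failed (%s); using packaged signature", exc)
    if sig is None:
        sig = signature.load_packaged_signature()
    sig.to_tsv(out / "signature.tsv")
    s = stage("signature")
    s.update(n_up=len(sig.up_genes), n_down=len(sig.down_genes))

    lcs_results = lcs.score_cohort(
        expr, sig, params=lcs.LcsParams(alpha=config.alpha, top_fraction=config.top_fraction)
    )
    lcs_results.to_csv(out / "lcs_results.tsv", sep="\t", index_label="sample_id")
    s = stage("lcs")
    s.update(
        n_significant=int(lcs_results["significant"].sum()),
        n_top=int(lcs_results["top_quartile"].sum()),
    )

    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
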