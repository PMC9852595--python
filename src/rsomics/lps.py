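"""Methylation linear predictor score (LPS) for Richter-syndrome subgrouping.

The score assigns a transformed-lymphoma sample to the chronic lymphocytic
leukemia (CLL)-derived or the de novo DLBCL-like compartment from its
methylation profile alone. Scoring CpGs are chosen by a three-step cascade on
the CLL and DLBCL reference groups:

  (i)   keep CpGs differentially methylated between CLL and DLBCL
        (BH FDR q < fdr_cut, default 0.01), retaining each CpG's moderated
        t-statistic as its weight;
  (ii)  remove CpGs that are also differential between IGHV-unmutated and
        IGHV-mutated CLL (q < fdr_cut), so that B-cell maturation state does
        not drive the score;
  (iii) remove CpGs whose absolute group beta-value differential is not
        above delta_cut (default 0.30).

For a sample with beta-values S_i the score is LPS(S) = sum_i t_i * S_i.
Reference-group score distributions are modelled as Gaussians and a sample's
posterior of CLL membership is the two-class density ratio

  p_CLL = phi(x; mu_CLL, var_CLL) / (phi(x; mu_CLL, var_CLL) + phi(x; mu_DLBCL, var_DLBCL))

computed in log space. A sample is labelled CLL-derived when p_CLL >= 0.98,
DLBCL-like when p_DLBCL >= 0.98, and intermediate otherwise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .datamodel import BetaMatrix, MValueMatrix, SampleSheet, ValidationError
from .diffstats import ModelSpec, differential_analysis

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

LABEL_CLL = "CLL_derived"
LABEL_DLBCL = "DLBCL_like"
LABEL_INTERMEDIATE = "intermediate"


@dataclass
class LpsModel:
    """Scoring CpGs with moderated-t weights plus fitted score Gaussians."""

    scoring_cpgs: list[str]
    weights: np.ndarray
    mu_cll: float = float("nan")
    var_cll: float = float("nan")
    mu_dlbcl: float = float("nan")
    var_dlbcl: float = float("nan")
    threshold: float = 0.98
    selection_funnel: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(set(self.scoring_cpgs)) != len(self.scoring_cpgs):
            raise ValidationError("scoring CpGs must be unique")
        if len(self.scoring_cpgs) != self.weights.size:
            raise ValidationError("weights and scoring CpGs differ in length")
        if not np.all(np.isfinite(self.weights)):
            raise ValidationError("weights must be finite")
        if not 0.5 < self.threshold <= 1:
            raise ValidationError("threshold must be in (0.5, 1]")

    @property
    def is_fitted(self) -> bool:
        return np.isfinite([self.mu_cll, self.var_cll, self.mu_dlbcl, self.var_dlbcl]).all()

    def to_json(self, path) -> None:
        doc = {
            "format_version": MODEL_FORMAT_VERSION,
            "scoring_cpgs": self.scoring_cpgs,
            "weights": self.weights.tolist(),
            "mu_cll": self.mu_cll,
            "var_cll": self.var_cll,
            "mu_dlbcl": self.mu_dlbcl,
            "var_dlbcl": self.var_dlbcl,
            "threshold": self.threshold,
            "selection_funnel": self.selection_funnel,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LpsModel":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValidationError(
                f"unsupported model format version {doc.get('format_version')!r}"
            )
        return cls(
            scoring_cpgs=doc["scoring_cpgs"],
            weights=np.asarray(doc["weights"], dtype=float),
            mu_cll=doc["mu_cll"],
            var_cll=doc["var_cll"],
            mu_dlbcl=doc["mu_dlbcl"],
            var_dlbcl=doc["var_dlbcl"],
            threshold=doc["threshold"],
            selection_funnel=doc.get("selection_funnel", {}),
        )


def select_scoring_cpgs(
    m: MValueMatrix,
    b: BetaMatrix,
    sheet: SampleSheet,
    fdr_cut: float = 0.01,
    delta_cut: float = 0.30,
    covariate_names: tuple[str, ...] = (),
) -> tuple[list[str], np.ndarray, dict]:
    """Run the differential / IGHV-exclusion / delta-beta cascade.

    Returns (cpg ids, moderated-t weights, selection funnel counts).
    """
    res_main = differential_analysis(
        m, sheet, ModelSpec(contrast=("CLL", "DLBCL"), covariate_names=covariate_names), b=b
    )
    step1 = res_main.index[res_main["q"] < fdr_cut]
    ighv_cpgs = _ighv_differential(m, sheet, fdr_cut, covariate_names)
    step2 = [c for c in step1 if c not in ighv_cpgs]
    db = res_main.loc[step2, "delta_beta"].abs()
    survivors = [c for c in step2 if db[c] > delta_cut]
    funnel = {
        "n_total": int(res_main.shape[0]),
        "n_differential": int(len(step1)),
        "n_ighv_differential": int(len(ighv_cpgs)),
        "n_after_ighv_exclusion": int(len(step2)),
        "n_scoring": int(len(survivors)),
    }
    logger.info("CpG selection funnel: %s", funnel)
    if not survivors:
        raise ValidationError(
            "no scoring CpGs survived selection; relax fdr_cut or delta_cut"
        )
    weights = res_main.loc[survivors, "t_mod"].to_numpy(dtype=float)
    return survivors, weights, funnel


def _ighv_differential(m, sheet, fdr_cut, covariate_names) -> set[str]:
    """CpG ids differential between IGHV-unmutated and -mutated CLL."""
    sub_ids = sheet.samples_in_group("CLL")
    sub = sheet.subset(sub_ids)
    frame = sub.frame.copy()
    # recode U-CLL vs M-CLL as a two-group contrast on the CLL subset
    frame["group"] = np.where(frame["ighv_status"] == "U", "CLL", "DLBCL")
    recoded = SampleSheet(frame)
    if len(recoded.samples_in_group("CLL")) < 2 or len(recoded.samples_in_group("DLBCL")) < 2:
        raise ValidationError("need >=2 U-CLL and >=2 M-CLL samples for IGHV exclusion")
    res = differential_analysis(
        m, recoded, ModelSpec(contrast=("CLL", "DLBCL"), covariate_names=covariate_names)
    )
    return set(res.index[res["q"] < fdr_cut])


def compute_lps(b: BetaMatrix, model: LpsModel) -> pd.Series:
    """LPS(S) = sum_i t_i * S_i over scoring CpGs, on beta-values."""
    missing = [c for c in model.scoring_cpgs if c not in b.values.index]
    if missing:
        raise ValidationError(f"scoring CpGs absent from matrix: {missing[:10]}")
    S = b.values.loc[model.scoring_cpgs].to_numpy(dtype=float)
    scores = model.weights @ S
    return pd.Series(scores, index=b.values.columns, name="lps")


def fit_group_distributions(lps: pd.Series, sheet: SampleSheet) -> tuple[float, float, float, float]:
    """Sample mean and unbiased variance of the score within CLL and DLBCL."""
    out = []
    for g in ("CLL", "DLBCL"):
        ids = sheet.samples_in_group(g)
        if len(ids) < 3:
            raise ValidationError(f"need >=3 reference samples in {g}, got {len(ids)}")
        x = lps.loc[ids].to_numpy(dtype=float)
        mu = float(x.mean())
        var = float(x.var(ddof=1))
        if var <= 0:
            raise ValidationError(f"zero score variance in reference group {g}")
        out.extend([mu, var])
    return tuple(out)  # mu_cll, var_cll, mu_dlbcl, var_dlbcl


def posterior(lps_value, model: LpsModel):
    """Two-class Gaussian posterior, evaluated via log-densities.

    p_CLL = 1 / (1 + exp(log phi_DLBCL - log phi_CLL)); p_DLBCL = 1 - p_CLL.
    """
    x = np.asarray(lps_value, dtype=float)
    log_cll = -0.5 * (np.log(2 * np.pi * model.var_cll) + (x - model.mu_cll) ** 2 / model.var_cll)
    log_dlbcl = -0.5 * (np.log(2 * np.pi * model.var_dlbcl) + (x - model.mu_dlbcl) ** 2 / model.var_dlbcl)
    p_cll = special.expit(log_cll - log_dlbcl)
    return p_cll, 1.0 - p_cll


def classify(p_cll, p_dlbcl, threshold: float = 0.98) -> str:
    """Label from posteriors; the threshold is inclusive (>=)."""
    if p_cll >= threshold:
        return LABEL_CLL
    if p_dlbcl >= threshold:
        return LABEL_DLBCL
    return LABEL_INTERMEDIATE


def score_samples(b: BetaMatrix, model: LpsModel) -> pd.DataFrame:
    """Score and label every column of ``b`` with a fitted model."""
    if not model.is_fitted:
        raise ValidationError("model group distributions are not fitted")
    lps = compute_lps(b, model)
    p_cll, p_dlbcl = posterior(lps.to_numpy(), model)
    labels = [classify(pc, pd_, model.threshold) for pc, pd_ in zip(p_cll, p_dlbcl)]
    return pd.DataFrame(
        {"lps": lps, "p_cll": p_cll, "p_dlbcl": p_dlbcl, "label": labels},
        index=lps.index,
    )


def train(
    b: BetaMatrix,
    m: MValueMatrix,
    sheet: SampleSheet,
    fdr_cut: float = 0.01,
    delta_cut: float = 0.30,
    threshold: float = 0.98,
    covariate_names: tuple[str, ...] = (),
) -> LpsModel:
    """Select scoring CpGs on the references and fit the score Gaussians."""
    cpgs, weights, funnel = select_scoring_cpgs(
        m, b, sheet, fdr_cut=fdr_cut, delta_cut=delta_cut, covariate_names=covariate_names
    )
    model = LpsModel(scoring_cpgs=cpgs, weights=weights, threshold=threshold,
                     selection_funnel=funnel)
    ref_ids = sheet.samples_in_group("CLL") + sheet.samples_in_group("DLBCL")
    lps_ref = compute_lps(b, model).loc[ref_ids]
    mu_c, var_c, mu_d, var_d = fit_group_distributions(lps_ref, sheet.subset(ref_ids))
    model.mu_cll, model.var_cll = mu_c, var_c
    model.mu_dlbcl, model.var_dlbcl = mu_d, var_d
    return model


def train_and_score(
    b: BetaMatrix,
    m: MValueMatrix,
    sheet: SampleSheet,
    fdr_cut: float = 0.01,
    delta_cut: float = 0.30,
    threshold: float = 0.98,
    covariate_names: tuple[str, ...] = (),
) -> tuple[LpsModel, pd.DataFrame]:
    """Train on the CLL/DLBCL references, then score and label the RS samples."""
    model = train(b, m, sheet, fdr_cut=fdr_cut, delta_cut=delta_cut,
                  threshold=threshold, covariate_names=covariate_names)
    rs_ids = sheet.samples_in_group("RS")
    if not rs_ids:
        raise ValidationError("no RS samples to score")
    results = score_samples(BetaMatrix(b.values.loc[:, rs_ids]), model)
    return model, results
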