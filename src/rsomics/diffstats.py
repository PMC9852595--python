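"""Per-feature linear models with empirical-Bayes moderated t-statistics.

For each feature (CpG M-value row or log2-CPM gene row) an ordinary
least-squares model ``y ~ group + covariates`` is fitted. Residual variances
are then shrunk toward a common prior by fitting a scaled inverse-chi-square
prior with Smyth's closed-form moments estimator on log s^2, which yields the
prior degrees of freedom d0 and prior variance s0^2. The moderated t-statistic
uses the posterior variance

    s~^2_g = (d0 * s0^2 + df * s^2_g) / (d0 + df)

and is referred to a Student t distribution with df + d0 degrees of freedom
(normal when d0 is infinite). P-values are two-sided and adjusted for the
false discovery rate with the Benjamini-Hochberg step-up.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .datamodel import BetaMatrix, SampleSheet, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelSpec:
    """Which two groups to contrast and which covariates to adjust for."""

    contrast: tuple[str, str]
    covariate_names: tuple[str, ...] = ()
    # optional: restrict groups by IGHV status, e.g. {"CLL": "U"}
    ighv_within: tuple[tuple[str, str], ...] = ()


@dataclass
class LinearFit:
    """Per-feature OLS results for the contrast coefficient."""

    feature_ids: list[str]
    effect: np.ndarray          # group1 - group2 coefficient
    s2: np.ndarray              # residual variance
    df_residual: int
    stderr_unscaled: float      # sqrt of contrast entry of (X'X)^-1


@dataclass
class Moderation:
    """Empirical-Bayes variance shrinkage parameters and posteriors."""

    d0: float                   # prior df; math.inf for complete shrinkage
    s0_2: float                 # prior variance
    s2_post: np.ndarray         # posterior (moderated) variances


def _design_matrix(sheet: SampleSheet, spec: ModelSpec):
    """Build samples, design X (intercept, group indicator, covariates)."""
    g1, g2 = spec.contrast
    within = dict(spec.ighv_within)
    samples = []
    indicator = []
    for g, val in ((g1, 1.0), (g2, 0.0)):
        ids = sheet.samples_in_group(g, ighv=within.get(g))
        if len(ids) < 2:
            raise ValidationError(f"need >=2 samples in group {g!r}, got {len(ids)}")
        samples.extend(ids)
        indicator.extend([val] * len(ids))
    cols = {"intercept": np.ones(len(samples)), "group": np.asarray(indicator)}
    sub = sheet.frame.loc[samples]
    for c in spec.covariate_names:
        cols[c] = sub[c].to_numpy(dtype=float)
    X = np.column_stack(list(cols.values()))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(
            f"rank-deficient design; columns: {list(cols)} (check collinear covariates)"
        )
    return samples, X


def fit_linear_models(y, sheet: SampleSheet, spec: ModelSpec) -> LinearFit:
    """OLS per feature; the contrast coefficient is the adjusted group difference."""
    samples, X = _design_matrix(sheet, spec)
    Y = y.values.loc[:, samples].to_numpy(dtype=float)  # features x n
    n, p = X.shape
    df = n - p
    if df < 1:
        raise ValidationError("no residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ xtx_inv.T                            # features x p
    resid = Y - beta @ X.T
    s2 = (resid**2).sum(axis=1) / df
    return LinearFit(
        feature_ids=list(y.values.index),
        effect=beta[:, 1],
        s2=s2,
        df_residual=df,
        stderr_unscaled=float(np.sqrt(xtx_inv[1, 1])),
    )


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on 1/trigamma."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) / x < tol:
            break
    return x


def moderate(s2: np.ndarray, df: int) -> Moderation:
    """Estimate the inverse-chi-square prior (d0, s0^2) and posterior variances.

    Moments estimator on z = log s^2: under the hierarchical model z has mean
    digamma(df/2) - log(df/2) + log s0^2 + digamma(d0/2) - log(d0/2) and excess
    variance trigamma(d0/2) beyond trigamma(df/2).
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 2:
        raise ValidationError("need >=2 features to moderate variances")
    if df < 1:
        raise ValidationError("residual df must be >= 1")
    positive = s2[s2 > 0]
    if positive.size < s2.size:
        logger.warning("moderate: %d features with zero residual variance", s2.size - positive.size)
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_2 = float(positive.mean())
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
    return Moderation(d0=d0, s0_2=s0_2, s2_post=s2_post)


def moderated_t(effect: np.ndarray, stderr_unscaled: float, mod: Moderation, df: int):
    """Moderated t and two-sided p; df_total = df + d0 (normal if d0 infinite)."""
    s2_post = mod.s2_post
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / (stderr_unscaled * np.sqrt(s2_post))
    zero_var = s2_post <= 0
    if zero_var.any():
        logger.warning("moderated_t: %d features with zero posterior variance excluded", int(zero_var.sum()))
        t = np.where(zero_var, np.nan, t)
    if math.isinf(mod.d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
        df_total = math.inf
    else:
        df_total = df + mod.d0
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return t, p, df_total


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up: q_(i) = min_{j>=i} m*p_(j)/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    if np.any(((p < 0) | (p > 1)) & ~np.isnan(p)):
        raise ValidationError("p-values must be in [0,1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def delta_beta(b: BetaMatrix, sheet: SampleSheet, contrast: tuple[str, str],
               ighv_within: dict[str, str] | None = None) -> pd.Series:
    """Difference of group-mean beta per CpG (group1 - group2), in [-1, 1]."""
    within = ighv_within or {}
    g1 = sheet.samples_in_group(contrast[0], ighv=within.get(contrast[0]))
    g2 = sheet.samples_in_group(contrast[1], ighv=within.get(contrast[1]))
    if not g1 or not g2:
        raise ValidationError(f"empty group in contrast {contrast}")
    return b.values.loc[:, g1].mean(axis=1) - b.values.loc[:, g2].mean(axis=1)


def differential_analysis(y, sheet: SampleSheet, spec: ModelSpec,
                          b: BetaMatrix | None = None) -> pd.DataFrame:
    """Full engine: OLS -> variance moderation -> moderated t -> BH FDR.

    Returns a frame with columns feature_id, effect, delta_beta (NaN when no
    beta matrix is supplied), t_mod, p, q, df_total.
    """
    fit = fit_linear_models(y, sheet, spec)
    mod = moderate(fit.s2, fit.df_residual)
    t, p, df_total = moderated_t(fit.effect, fit.stderr_unscaled, mod, fit.df_residual)
    ok = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    if ok.any():
        q[ok] = bh_adjust(p[ok])
    out = pd.DataFrame(
        {
            "feature_id": fit.feature_ids,
            "effect": fit.effect,
            "t_mod": t,
            "p": p,
            "q": q,
            "df_total": df_total,
        }
    ).set_index("feature_id")
    if b is not None:
        within = dict(spec.ighv_within)
        out["delta_beta"] = delta_beta(b, sheet, spec.contrast, within)
    else:
        out["delta_beta"] = np.nan
    return out


def write_results(results: pd.DataFrame, path) -> None:
    cols = ["effect", "delta_beta", "t_mod", "p", "q"]
    results[cols].to_csv(path, sep="\t", index_label="feature_id")
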