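"""Gene-expression linear classifier score (LCS) for the CLL-derived imprint.

Given a cohort expression matrix and a +/-1-weighted gene signature the score
is computed per sample as

  LCS(S) = (1/n) * sum_i G_i * W_i

where G_i is the scaled (per-gene z-scored), positively-outlier-trimmed
expression of signature gene i, W_i its weight, and n the number of signature
genes retained in the dataset. Raw scores are standardized across the cohort,
the z-score is referred to the upper tail of a standard normal for a one-way
p-value, and samples are additionally flagged when they rank within the top
fraction (default quartile) of the cohort.

Scores are cohort-relative by construction: the standardization depends on
the composition of the dataset being screened, so single samples cannot be
classified in isolation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionMatrix, ValidationError
from .signature import GeneSignature

logger = logging.getLogger(__name__)


@dataclass
class LcsParams:
    alpha: float = 0.05
    top_fraction: float = 0.25
    trim_quantile: float = 0.999


def aggregate_by_gene(
    e: ExpressionMatrix,
    signature_genes: list[str],
    feature_to_gene: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Sum expression over the features matching each signature gene.

    ``feature_to_gene`` maps matrix feature ids to gene ids (identity when
    omitted). Signature genes with no matching feature are logged and dropped.
    """
    v = e.values
    if feature_to_gene is None:
        mapping = pd.Series(v.index, index=v.index)
    else:
        mapping = pd.Series(feature_to_gene)
    mapped = v.loc[v.index.intersection(mapping.index)]
    genes = mapping.loc[mapped.index]
    wanted = set(signature_genes)
    keep = genes.isin(wanted)
    if not keep.any():
        raise ValidationError("no signature genes matched the expression matrix")
    agg = mapped.loc[keep].groupby(genes[keep]).sum()
    missing = wanted - set(agg.index)
    if missing:
        logger.warning("%d signature genes unmatched and dropped: %s",
                       len(missing), sorted(missing)[:5])
    return agg.loc[[g for g in signature_genes if g in agg.index]]


def scale_genes(g: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scoring (mean 0, unbiased sd 1); zero-variance genes dropped."""
    if g.shape[1] < 2:
        raise ValidationError("need >=2 samples to scale")
    sd = g.std(axis=1, ddof=1)
    zero = sd == 0
    if zero.all():
        raise ValidationError("all genes have zero variance")
    if zero.any():
        logger.warning("dropping %d zero-variance genes before scaling", int(zero.sum()))
        g = g.loc[~zero]
        sd = sd.loc[~zero]
    return g.sub(g.mean(axis=1), axis=0).div(sd, axis=0)


def trim_positive_outliers(scaled: pd.DataFrame, quantile: float = 0.999) -> pd.DataFrame:
    """Cap values above the matrix-wide upper-permille at that permille value.

    Negative values are untouched: only the positive tail is trimmed. The
    cutoff is the order-statistic quantile (no interpolation), which makes
    trimming idempotent: re-trimming a trimmed matrix changes nothing.
    """
    cutoff = float(np.quantile(scaled.to_numpy(dtype=float), quantile, method="higher"))
    return scaled.clip(upper=cutoff)


def compute_lcs(trimmed: pd.DataFrame, signature: GeneSignature) -> pd.Series:
    """Mean of weighted gene expression per sample over retained signature genes."""
    genes = trimmed.index.intersection(signature.entries.index)
    if genes.empty:
        raise ValidationError("no signature genes in trimmed matrix")
    w = signature.entries.loc[genes].to_numpy(dtype=float)
    G = trimmed.loc[genes].to_numpy(dtype=float)
    return pd.Series((w @ G) / len(genes), index=trimmed.columns, name="lcs_raw")


def standardize_and_call(
    lcs_raw: pd.Series, alpha: float = 0.05, top_fraction: float = 0.25
) -> pd.DataFrame:
    """Cohort-standardize, one-way normal p-value, significance and top flags."""
    if lcs_raw.size < 3:
        raise ValidationError("need >=3 samples to standardize")
    sd = float(lcs_raw.std(ddof=1))
    if sd == 0:
        raise ValidationError("zero cohort score variance")
    z = (lcs_raw - float(lcs_raw.mean())) / sd
    p = stats.norm.sf(z.to_numpy(dtype=float))
    n = lcs_raw.size
    k = int(math.ceil(top_fraction * n))
    # ranks: stable sort descending by z; ties broken by sample order
    order = np.argsort(-z.to_numpy(), kind="stable")
    top = np.zeros(n, dtype=bool)
    top[order[:k]] = True
    return pd.DataFrame(
        {
            "lcs_raw": lcs_raw,
            "z": z,
            "p": p,
            "significant": p < alpha,
            "top_quartile": top,
        },
        index=lcs_raw.index,
    )


def score_cohort(
    e: ExpressionMatrix,
    signature: GeneSignature,
    feature_to_gene: pd.Series | dict | None = None,
    params: LcsParams | None = None,
) -> pd.DataFrame:
    """Full procedure: aggregate, scale, trim, score, standardize, call."""
    params = params or LcsParams()
    agg = aggregate_by_gene(e, list(signature.entries.index), feature_to_gene)
    scaled = scale_genes(agg)
    trimmed = trim_positive_outliers(scaled, params.trim_quantile)
    raw = compute_lcs(trimmed, signature)
    return standardize_and_call(raw, alpha=params.alpha, top_fraction=params.top_fraction)
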