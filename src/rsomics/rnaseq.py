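"""Count filtering, TMM scale factors, and log2-CPM transformation.

Lowly expressed features are removed (non-zero in at least ``min_samples``
samples and mean count at least ``min_mean_reads``), library sizes are
adjusted with the trimmed-mean-of-M-values (TMM) method, and counts are
converted to log2 counts-per-million with a small prior count.

TMM here follows the canonical recipe: the reference sample is the one whose
upper-quartile of count/library-size is closest to the cohort mean
upper-quartile; per sample, gene-wise log-ratios M and log-abundances A
against the reference are computed over genes expressed in both, the most
extreme 30% of M and 5% of A are trimmed, and the factor is 2 to the
precision-weighted mean of the surviving M values. Factors are rescaled to
geometric mean 1 so normalization does not change the overall scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CountMatrix, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_MIN_MEAN_READS = 20.0
LIBSIZE_FRACTION = 1.0 / 5_000_000  # mean-count floor as a fraction of mean library size


@dataclass
class NormalizationFactors:
    """Per-sample multiplicative TMM factors; geometric mean 1."""

    factors: pd.Series            # indexed by sample_id
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValidationError("TMM factors must be > 0")

    @property
    def effective_library_sizes(self) -> pd.Series:
        return self.library_sizes * self.factors


def default_min_mean_reads(c: CountMatrix) -> float:
    """max(20, mean library size / 5e6) — the printed floor wins at desk scale."""
    return max(DEFAULT_MIN_MEAN_READS, float(c.library_sizes.mean()) * LIBSIZE_FRACTION)


def filter_low_expression(
    c: CountMatrix, min_samples: int = 2, min_mean_reads: float | None = None
) -> CountMatrix:
    """Keep features non-zero in >= min_samples samples with mean >= min_mean_reads."""
    if min_mean_reads is None:
        min_mean_reads = default_min_mean_reads(c)
    v = c.values
    keep = ((v > 0).sum(axis=1) >= min_samples) & (v.mean(axis=1) >= min_mean_reads)
    if not keep.any():
        raise ValidationError("all features removed by expression filter")
    logger.info("expression filter kept %d/%d features", int(keep.sum()), len(keep))
    return CountMatrix(v.loc[keep])


def _tmm_pair(counts: np.ndarray, lib: float, ref: np.ndarray, ref_lib: float,
              trim_m: float, trim_a: float) -> float:
    both = (counts > 0) & (ref > 0)
    if both.sum() < 2:
        logger.warning("degenerate sample for TMM (<2 shared expressed features); factor=1")
        return 1.0
    c, r = counts[both] / lib, ref[both] / ref_lib
    M = np.log2(c / r)
    A = 0.5 * np.log2(c * r)
    # asymptotic (delta-method) variance of M; precision weights are 1/v
    v = (lib - counts[both]) / (lib * counts[both]) + (ref_lib - ref[both]) / (ref_lib * ref[both])
    if np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = M.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(M).rank().to_numpy()
    rank_a = pd.Series(A).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or np.sum(1.0 / v[keep]) == 0:
        return 1.0
    f = float(np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep]))
    if not np.isfinite(f):
        return 1.0
    return 2.0**f


def tmm_factors(c: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05) -> NormalizationFactors:
    """Trimmed mean of M-values scale factor per sample."""
    v = c.values.to_numpy(dtype=float)
    if v.shape[1] < 2:
        raise ValidationError("TMM requires >=2 samples")
    lib = v.sum(axis=0)
    if np.any(lib == 0):
        raise ValidationError("all-zero sample in count matrix")
    uq = np.array([np.quantile(v[:, j] / lib[j], 0.75) for j in range(v.shape[1])])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    raw = np.array(
        [
            _tmm_pair(v[:, j], lib[j], v[:, ref_idx], lib[ref_idx], trim_m, trim_a)
            for j in range(v.shape[1])
        ]
    )
    factors = raw / np.exp(np.mean(np.log(raw)))
    return NormalizationFactors(
        factors=pd.Series(factors, index=c.values.columns, name="tmm_factor"),
        library_sizes=c.library_sizes.astype(float),
    )


def log2_cpm(c: CountMatrix, f: NormalizationFactors, prior_count: float = 0.5) -> ExpressionMatrix:
    """log2((count + prior) / (effective library + 2*prior) * 1e6)."""
    eff = f.effective_library_sizes.loc[c.values.columns].to_numpy(dtype=float)
    v = c.values.to_numpy(dtype=float)
    out = np.log2((v + prior_count) / (eff + 2 * prior_count) * 1e6)
    return ExpressionMatrix(
        pd.DataFrame(out, index=c.values.index, columns=c.values.columns),
        normalization_factors=f.factors,
    )


def prepare(
    c: CountMatrix,
    min_samples: int = 2,
    min_mean_reads: float | None = None,
    prior_count: float = 0.5,
) -> tuple[ExpressionMatrix, NormalizationFactors]:
    """Filter, normalize, and transform in the standard order (filter first)."""
    filtered = filter_low_expression(c, min_samples=min_samples, min_mean_reads=min_mean_reads)
    f = tmm_factors(filtered)
    return log2_cpm(filtered, f, prior_count=prior_count), f
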