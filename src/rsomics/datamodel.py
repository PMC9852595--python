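"""Core data containers and readers/writers shared by every analysis stage.

Matrices are feature-major: rows are CpGs / genes / transcripts, columns are
samples. Methylation is carried either as beta-values (fraction methylated,
in [0, 1], used for interpretation and for the linear predictor score) or as
M-values (log2-odds of methylation, unbounded, preferred for linear-model
statistics because their variance is more homoscedastic across the range).

Genomic coordinates are 1-based inclusive throughout; BED input (0-based
half-open) is converted at the reader boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_EPS = 1e-6

FEATURE_CLASSES = frozenset(
    {"TSS200", "TSS1500", "FirstExon", "FiveUTR", "Body", "ThreeUTR", "Intergenic"}
)
GROUPS = frozenset({"CLL", "DLBCL", "RS", "NORMAL"})
IGHV_STATUSES = frozenset({"U", "M", "unknown"})


class ValidationError(ValueError):
    """An input violated a structural or range invariant."""


class ParseError(ValueError):
    """A delimited-text input could not be parsed."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        dup = pd.Index(ids)
        dup = sorted(dup[dup.duplicated()].unique())
        raise ValidationError(f"duplicate {what}: {dup[:10]}")


@dataclass
class _Matrix:
    """Shared frame-backed matrix behaviour; subclasses add invariants."""

    values: pd.DataFrame  # features x samples

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        _check_unique(list(self.values.index), "feature ids")
        _check_unique(list(self.values.columns), "sample ids")
        self._validate()

    def _validate(self) -> None:  # pragma: no cover - overridden
        pass

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def align(self, sheet: "SampleSheet") -> "_Matrix":
        """Restrict and order columns to the sample sheet.

        Extra matrix columns are dropped with a logged warning; a sheet sample
        absent from the matrix is an error.
        """
        wanted = sheet.sample_ids
        have = set(self.values.columns)
        missing = [s for s in wanted if s not in have]
        if missing:
            raise ValidationError(f"samples missing from matrix: {missing}")
        extra = [s for s in self.values.columns if s not in set(wanted)]
        if extra:
            logger.warning("align: dropping %d matrix columns not in sheet", len(extra))
        return replace(self, values=self.values.loc[:, wanted])


@dataclass
class BetaMatrix(_Matrix):
    """CpG x sample methylation fractions in [0, 1]; NaN marks missing."""

    def _validate(self) -> None:
        v = self.values.to_numpy(dtype=float)
        bad = (v < 0) | (v > 1)
        if np.any(bad & ~np.isnan(v)):
            rows = self.values.index[np.any(bad & ~np.isnan(v), axis=1)]
            raise ValidationError(
                f"beta values outside [0,1] at CpGs: {list(rows[:10])}"
            )

    def drop_incomplete(self) -> "BetaMatrix":
        """Drop CpG rows containing missing values, with a logged count."""
        mask = self.values.notna().all(axis=1)
        n_dropped = int((~mask).sum())
        if n_dropped:
            logger.warning("dropping %d CpG rows with missing beta values", n_dropped)
        return BetaMatrix(self.values.loc[mask])


@dataclass
class MValueMatrix(_Matrix):
    """CpG x sample M-values (log2-odds of methylation); all finite."""

    def _validate(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            rows = self.values.index[~np.isfinite(v).all(axis=1)]
            raise ValidationError(f"non-finite M-values at CpGs: {list(rows[:10])}")


@dataclass
class CountMatrix(_Matrix):
    """Feature x sample raw read counts (non-negative integers)."""

    def _validate(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if np.any(v < 0) or not np.allclose(v, np.round(v)):
            bad = self.values.index[
                ((v < 0) | ~np.isclose(v, np.round(v))).any(axis=1)
            ]
            raise ValidationError(
                f"counts must be non-negative integers; offending features: {list(bad[:10])}"
            )

    @property
    def library_sizes(self) -> pd.Series:
        return self.values.sum(axis=0)


@dataclass
class ExpressionMatrix(_Matrix):
    """Feature x sample normalized log2-CPM values."""

    normalization_factors: pd.Series | None = None

    def _validate(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValidationError("expression values must be finite")
        if self.normalization_factors is not None:
            f = np.asarray(self.normalization_factors, dtype=float)
            if np.any(f <= 0):
                raise ValidationError("normalization factors must be > 0")


@dataclass
class SampleSheet:
    """Per-sample annotations: group, IGHV status, covariates, batch."""

    frame: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        df = self.frame
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        _check_unique(list(df.index), "sample ids")
        if "group" not in df.columns:
            raise ValidationError("sample sheet requires a 'group' column")
        bad = set(df["group"]) - GROUPS
        if bad:
            raise ValidationError(f"unknown groups: {sorted(bad)}")
        if "ighv_status" in df.columns:
            bad = set(df["ighv_status"].dropna()) - IGHV_STATUSES
            if bad:
                raise ValidationError(f"unknown IGHV statuses: {sorted(bad)}")
        self.frame = df
        for c in self.covariate_names:
            v = pd.to_numeric(df[c], errors="coerce")
            if v.isna().any():
                raise ValidationError(f"covariate {c!r} is not numeric")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def covariate_names(self) -> list[str]:
        reserved = {"group", "ighv_status", "batch"}
        return [c for c in self.frame.columns if c not in reserved]

    def samples_in_group(self, group: str, ighv: str | None = None) -> list[str]:
        mask = self.frame["group"] == group
        if ighv is not None:
            mask &= self.frame["ighv_status"] == ighv
        return list(self.frame.index[mask])

    def subset(self, sample_ids: Sequence[str]) -> "SampleSheet":
        return SampleSheet(self.frame.loc[list(sample_ids)].copy())


@dataclass
class CpGAnnotation:
    """CpG genomic positions and gene links.

    ``frame`` columns: cpg_id (index), chrom, pos (1-based bp). ``gene_links``
    columns: cpg_id, gene_id, feature_class (TSS200/TSS1500/FirstExon/...).
    """

    frame: pd.DataFrame
    gene_links: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["cpg_id", "gene_id", "feature_class"]
        )
    )

    def __post_init__(self) -> None:
        df = self.frame
        if "cpg_id" in df.columns:
            df = df.set_index("cpg_id")
        if (df["pos"] < 1).any():
            raise ValidationError("CpG positions must be >= 1 (1-based)")
        bad = set(self.gene_links["feature_class"]) - FEATURE_CLASSES
        if bad:
            raise ValidationError(f"unknown feature classes: {sorted(bad)}")
        self.frame = df


@dataclass
class GeneAnnotation:
    """Gene/transcript annotations: TSS coordinate, strand, biotype.

    ``frame`` columns: gene_id (index), chrom, tss (1-based bp), strand,
    biotype, transcript_ids (comma-joined string; may be empty).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        if "gene_id" in df.columns:
            df = df.set_index("gene_id")
        _check_unique(list(df.index), "gene ids")
        if (df["tss"] < 1).any():
            raise ValidationError("TSS coordinates must be >= 1 (1-based)")
        if not set(df["strand"]) <= {"+", "-"}:
            raise ValidationError("strand must be '+' or '-'")
        self.frame = df

    def transcripts_of(self, gene_id: str) -> list[str]:
        raw = self.frame.loc[gene_id].get("transcript_ids", "")
        if not isinstance(raw, str) or not raw:
            return [gene_id]
        return raw.split(",")


# ---------------------------------------------------------------------------
# beta / M conversions
# ---------------------------------------------------------------------------

def beta_to_m(b: BetaMatrix, eps: float = DEFAULT_EPS) -> MValueMatrix:
    """M = log2(beta / (1 - beta)) with beta clipped into [eps, 1-eps].

    Clipping keeps fully (un)methylated probes finite on the log-odds scale.
    """
    if not 0 < eps < 0.5:
        raise ValidationError("eps must be in (0, 0.5)")
    clipped = np.clip(b.values.to_numpy(dtype=float), eps, 1 - eps)
    m = np.log2(clipped / (1 - clipped))
    return MValueMatrix(pd.DataFrame(m, index=b.values.index, columns=b.values.columns))


def m_to_beta(m: MValueMatrix) -> BetaMatrix:
    """Inverse logistic transform: beta = 2^M / (1 + 2^M)."""
    v = m.values.to_numpy(dtype=float)
    # expit in base 2, computed stably for large |M|
    b = np.where(v >= 0, 1.0 / (1.0 + np.exp2(-v)), np.exp2(v) / (1.0 + np.exp2(v)))
    return BetaMatrix(pd.DataFrame(b, index=m.values.index, columns=m.values.columns))


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

_KINDS = {"beta": BetaMatrix, "count": CountMatrix, "expression": ExpressionMatrix, "m": MValueMatrix}


def _sniff_sep(path) -> str:
    with open(path) as fh:
        head = fh.readline()
    return "," if ("," in head and "\t" not in head) else "\t"


def read_matrix(path, kind: str):
    """Read a feature x sample matrix from TSV (or CSV) and validate it.

    The first column holds feature ids; the header row holds sample ids.
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown matrix kind {kind!r}")
    try:
        df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    except pd.errors.ParserError as exc:  # surface the line number pandas reports
        raise ParseError(f"{path}: {exc}") from exc
    if df.columns.size == 0:
        raise ParseError(f"{path}: no sample columns found")
    non_numeric = df.columns[df.apply(lambda c: pd.to_numeric(c, errors="coerce").isna() & c.notna()).any()]
    if len(non_numeric):
        raise ParseError(f"{path}: non-numeric values in columns {list(non_numeric)}")
    return _KINDS[kind](df.astype(float))


def write_matrix(matrix, path) -> None:
    # %.17g guarantees read_matrix(write_matrix(x)) round-trips bit-for-bit
    matrix.values.to_csv(path, sep="\t", index_label="feature_id", float_format="%.17g")


def read_sample_sheet(path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, sep=_sniff_sep(path)))


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.frame.to_csv(path, sep="\t", index_label="sample_id")


def read_cpg_annotation(bed_path, links_path=None) -> CpGAnnotation:
    """Read CpG positions from BED (0-based half-open -> 1-based inclusive)."""
    bed = pd.read_csv(
        bed_path, sep="\t", header=None, names=["chrom", "start", "end", "cpg_id"]
    )
    frame = pd.DataFrame(
        {"cpg_id": bed["cpg_id"], "chrom": bed["chrom"], "pos": bed["start"] + 1}
    )
    links = (
        pd.read_csv(links_path, sep="\t")
        if links_path is not None
        else pd.DataFrame(columns=["cpg_id", "gene_id", "feature_class"])
    )
    return CpGAnnotation(frame, links)


def write_cpg_annotation(ann: CpGAnnotation, bed_path, links_path=None) -> None:
    bed = pd.DataFrame(
        {
            "chrom": ann.frame["chrom"],
            "start": ann.frame["pos"] - 1,
            "end": ann.frame["pos"],
            "cpg_id": ann.frame.index,
        }
    )
    bed.to_csv(bed_path, sep="\t", header=False, index=False)
    if links_path is not None:
        ann.gene_links.to_csv(links_path, sep="\t", index=False)


def read_gene_annotation(path) -> GeneAnnotation:
    return GeneAnnotation(pd.read_csv(path, sep=_sniff_sep(path)))


def write_gene_annotation(ann: GeneAnnotation, path) -> None:
    ann.frame.to_csv(path, sep="\t", index_label="gene_id")


def align(matrix, sheet: SampleSheet):
    """Module-level alias for Matrix.align (column restriction + ordering)."""
    return matrix.align(sheet)
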