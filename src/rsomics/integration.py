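"""Methylome-transcriptome integrome: associations, correlations, candidates.

CpGs are linked to transcripts either through a shared gene identifier
(array annotation) or by genomic proximity (CpG within 2 kb of the
transcript's TSS, labelled ``TSSoverlap2kb``). For each association a
Spearman correlation between per-sample promoter methylation (beta) and
expression (log2-CPM) is computed. Candidate methylation-regulated regions
are promoters carrying at least three same-direction CpGs with |rho| > 1/3
and p < 0.001 in promoter feature classes (TSS200, TSS1500, first exon, or
the 2 kb TSS overlap). Negative correlation means higher methylation with
lower expression, the canonical promoter silencing direction.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    BetaMatrix,
    CpGAnnotation,
    ExpressionMatrix,
    GeneAnnotation,
    ValidationError,
)

logger = logging.getLogger(__name__)

PROMOTER_CLASSES = frozenset({"TSS200", "TSS1500", "FirstExon", "TSSoverlap2kb"})
RHO_CUT = 1.0 / 3.0


@dataclass
class CandidateRegion:
    """A promoter with >=3 same-direction significantly correlated CpGs."""

    target_id: str
    gene_id: str
    direction: str  # "negative" | "positive"
    cpg_ids: list[str]
    feature_classes: list[str]

    def __post_init__(self) -> None:
        if len(self.cpg_ids) < 3:
            raise ValidationError("candidate region needs >=3 supporting CpGs")
        if self.direction not in {"negative", "positive"}:
            raise ValidationError("direction must be 'negative' or 'positive'")


def build_integrome(
    cpgs: CpGAnnotation, genes: GeneAnnotation, window: int = 2000
) -> pd.DataFrame:
    """Association skeleton: ID-linked pairs plus coordinate pairs within the window.

    Returns a frame with columns cpg_id, target_id, gene_id, link_method,
    feature_class (coordinate pairs labelled TSSoverlap2kb). ID links take
    precedence when both methods find the same (cpg, target) pair.
    """
    chroms_c = set(cpgs.frame["chrom"])
    chroms_g = set(genes.frame["chrom"])
    if not (chroms_c & chroms_g):
        raise ValidationError(
            f"no shared chromosomes between CpG and gene annotations; "
            f"unshared: {sorted(chroms_c ^ chroms_g)[:10]}"
        )
    rows = []
    # (i) shared-identifier links, expanded to the gene's transcripts
    gene_index = genes.frame.index
    for link in cpgs.gene_links.itertuples(index=False):
        if link.gene_id not in gene_index:
            continue
        for t in genes.transcripts_of(link.gene_id):
            rows.append((link.cpg_id, t, link.gene_id, "shared_id", link.feature_class))
    # (ii) coordinate overlap: |pos - tss| <= window on the same chromosome
    cf = cpgs.frame
    for chrom, gsub in genes.frame.groupby("chrom", sort=False):
        csub = cf[cf["chrom"] == chrom]
        if csub.empty:
            continue
        pos = csub["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos_sorted = pos[order]
        ids_sorted = csub.index.to_numpy()[order]
        for gene_id, tss in zip(gsub.index, gsub["tss"].to_numpy()):
            lo = np.searchsorted(pos_sorted, tss - window, side="left")
            hi = np.searchsorted(pos_sorted, tss + window, side="right")
            if lo == hi:
                continue
            transcripts = genes.transcripts_of(gene_id)
            for cpg_id in ids_sorted[lo:hi]:
                for t in transcripts:
                    rows.append((cpg_id, t, gene_id, "coordinate_overlap", "TSSoverlap2kb"))
    out = pd.DataFrame(
        rows, columns=["cpg_id", "target_id", "gene_id", "link_method", "feature_class"]
    )
    # ID-link precedence on duplicated (cpg, target) pairs
    out["_prio"] = (out["link_method"] != "shared_id").astype(int)
    out = (
        out.sort_values(["cpg_id", "target_id", "_prio"], kind="stable")
        .drop_duplicates(["cpg_id", "target_id"], keep="first")
        .drop(columns="_prio")
        .reset_index(drop=True)
    )
    return out


def _spearman_exact_perm(rx: np.ndarray, ry: np.ndarray) -> float:
    """Exact two-sided permutation p for small n, on mid-rank vectors."""
    n = rx.size
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = abs(np.corrcoef(rx, ry[list(perm)])[0, 1])
        count += r >= obs - 1e-12
        total += 1
    return count / total


def spearman(meth: np.ndarray, expr: np.ndarray) -> tuple[float, float]:
    """Spearman rho with mid-ranks; p via t-approximation (exact perm for n<10).

    Returns (nan, nan) for constant vectors; callers drop such associations.
    """
    meth = np.asarray(meth, dtype=float)
    expr = np.asarray(expr, dtype=float)
    ok = ~(np.isnan(meth) | np.isnan(expr))
    meth, expr = meth[ok], expr[ok]
    n = meth.size
    if n < 5:
        raise ValidationError(f"need >=5 paired samples, got {n}")
    if np.all(meth == meth[0]) or np.all(expr == expr[0]):
        return float("nan"), float("nan")
    rx = stats.rankdata(meth)
    ry = stats.rankdata(expr)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n < 10:
        p = _spearman_exact_perm(rx, ry)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho**2))
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, p


def correlate_integrome(
    skeleton: pd.DataFrame,
    beta: BetaMatrix,
    expr: ExpressionMatrix,
    target_to_feature: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Attach Spearman rho and p to every association in the skeleton.

    ``target_to_feature`` maps target ids to expression-matrix rows (identity
    by default). Associations whose CpG or target is absent, or whose vectors
    are constant, are dropped with a logged count.
    """
    samples = [s for s in beta.sample_ids if s in set(expr.sample_ids)]
    if len(samples) < 5:
        raise ValidationError("need >=5 samples shared between methylation and expression")
    t2f = pd.Series(target_to_feature) if target_to_feature is not None else None
    bv = beta.values.loc[:, samples]
    ev = expr.values.loc[:, samples]
    rhos, ps, keep = [], [], []
    n_missing = n_constant = 0
    for row in skeleton.itertuples(index=False):
        feat = t2f[row.target_id] if t2f is not None and row.target_id in t2f.index else row.target_id
        if row.cpg_id not in bv.index or feat not in ev.index:
            n_missing += 1
            continue
        rho, p = spearman(bv.loc[row.cpg_id].to_numpy(), ev.loc[feat].to_numpy())
        if math.isnan(rho):
            n_constant += 1
            continue
        rhos.append(rho)
        ps.append(p)
        keep.append(row)
    if n_missing or n_constant:
        logger.warning("integrome: dropped %d associations with missing data, %d constant",
                       n_missing, n_constant)
    out = pd.DataFrame(keep, columns=skeleton.columns)
    out["rho"] = rhos
    out["p"] = ps
    return out


def filter_significant(
    assocs: pd.DataFrame, p_cut: float = 0.01, rho_cut: float = RHO_CUT
) -> pd.DataFrame:
    """Keep associations with |rho| > rho_cut and p < p_cut."""
    mask = (assocs["rho"].abs() > rho_cut) & (assocs["p"] < p_cut)
    return assocs.loc[mask].reset_index(drop=True)


def select_candidates(
    assocs: pd.DataFrame,
    min_cpgs: int = 3,
    rho_cut: float = RHO_CUT,
    p_cut: float = 0.001,
) -> tuple[list[CandidateRegion], dict[str, list[str]]]:
    """Promoters with >= min_cpgs same-direction qualifying CpGs.

    Only promoter feature classes count as support. Returns the candidate
    regions and per-direction unique gene lists (a gene may appear in both).
    """
    promoter = assocs[assocs["feature_class"].isin(PROMOTER_CLASSES)]
    candidates: list[CandidateRegion] = []
    genes_by_dir: dict[str, set[str]] = {"negative": set(), "positive": set()}
    for (target, gene), grp in promoter.groupby(["target_id", "gene_id"], sort=True):
        for direction, mask in (
            ("negative", (grp["rho"] < -rho_cut) & (grp["p"] < p_cut)),
            ("positive", (grp["rho"] > rho_cut) & (grp["p"] < p_cut)),
        ):
            hits = grp.loc[mask]
            if len(hits) >= min_cpgs:
                candidates.append(
                    CandidateRegion(
                        target_id=target,
                        gene_id=gene,
                        direction=direction,
                        cpg_ids=list(hits["cpg_id"]),
                        feature_classes=list(hits["feature_class"]),
                    )
                )
                genes_by_dir[direction].add(gene)
    gene_lists = {d: sorted(g) for d, g in genes_by_dir.items()}
    gene_lists["union"] = sorted(genes_by_dir["negative"] | genes_by_dir["positive"])
    return candidates, gene_lists


def candidates_frame(candidates: list[CandidateRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "target_id": c.target_id,
                "gene_id": c.gene_id,
                "direction": c.direction,
                "n_cpgs": len(c.cpg_ids),
                "cpg_ids": ",".join(c.cpg_ids),
                "feature_classes": ",".join(c.feature_classes),
            }
            for c in candidates
        ],
        columns=["target_id", "gene_id", "direction", "n_cpgs", "cpg_ids", "feature_classes"],
    )


def enrichment_fold(
    selected: int, selection_size: int, background_count: int, background_size: int
) -> float:
    """Observed frequency over expected frequency."""
    if selection_size <= 0 or background_size <= 0:
        raise ValidationError("sizes must be > 0")
    expected = background_count / background_size
    if expected == 0:
        logger.warning("zero background frequency; enrichment undefined")
        return math.inf
    return (selected / selection_size) / expected


def enrichment_test(table, method: str = "fisher") -> float:
    """Two-sided p for a 2x2 contingency table (Fisher exact or Pearson chi-square)."""
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if t.shape == (2, 2) and np.allclose(t, np.round(t)) and np.all(t >= 0):
            t = t.astype(int)
        else:
            raise ValidationError("table must be 2x2 non-negative integers")
    if method == "fisher":
        return float(stats.fisher_exact(t, alternative="two-sided")[1])
    if method == "chi2":
        return float(stats.chi2_contingency(t, correction=False)[1])
    raise ValidationError("method must be 'fisher' or 'chi2'")
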