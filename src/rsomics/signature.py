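"""Derivation of the weighted +/-1 gene signature from expression clustering.

The CLL-derived Richter signature is obtained by clustering median-centered
expression profiles under the uncentered-Pearson-correlation distance,
picking the up- and down-regulated cluster pair that best contrasts the
CLL-derived and DLBCL-like subgroups, and reducing the members to
protein-coding genes supported by the methylome-transcriptome integrome.
Each surviving gene carries weight +1 (up in CLL-derived) or -1 (down).

A synthetic stand-in for the published 215-gene signature (122 genes at +1,
93 at -1) ships with the package so the linear classifier score can be
exercised without re-derivation; see ``load_packaged_signature``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .datamodel import ExpressionMatrix, GeneAnnotation, SampleSheet, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GeneCluster:
    """A set of co-expressed genes with a direction relative to CLL-derived RS."""

    gene_ids: list[str]
    direction: str  # "up" | "down"
    mean_intra_correlation: float

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValidationError("gene cluster must be non-empty")
        if self.direction not in {"up", "down"}:
            raise ValidationError("direction must be 'up' or 'down'")


@dataclass
class GeneSignature:
    """(gene_id, weight) entries with weight in {+1, -1}."""

    entries: pd.Series  # index gene_id, values +/-1
    provenance: dict | None = None

    def __post_init__(self) -> None:
        if self.entries.index.duplicated().any():
            raise ValidationError("signature gene ids must be unique")
        if not set(self.entries.unique()) <= {1, -1}:
            raise ValidationError("signature weights must be +1 or -1")

    @property
    def up_genes(self) -> list[str]:
        return list(self.entries.index[self.entries == 1])

    @property
    def down_genes(self) -> list[str]:
        return list(self.entries.index[self.entries == -1])

    def to_tsv(self, path) -> None:
        self.entries.rename("weight").to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "GeneSignature":
        df = pd.read_csv(path, sep="\t")
        return cls(entries=df.set_index("gene_id")["weight"].astype(int))


def load_packaged_signature() -> GeneSignature:
    """Synthetic stand-in for the published 215-gene signature.

    Same shape as the published list (122 up-weighted, 93 down-weighted) but
    with synthetic gene identifiers; the real list sits behind restricted
    supplementary data. Use it for plumbing and shape checks, not biology.
    """
    path = resources.files("rsomics.data").joinpath("synthetic_signature_215.tsv")
    with resources.as_file(path) as p:
        return GeneSignature.from_tsv(p)


def median_center(e: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract the row median so every feature profile has median 0."""
    v = e.values
    return ExpressionMatrix(v.sub(v.median(axis=1), axis=0),
                            normalization_factors=e.normalization_factors)


def uncentered_corr_dist(x: np.ndarray, y: np.ndarray) -> float:
    """d = 1 - <x,y> / (||x|| ||y||); ranges over [0, 2]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValidationError("uncentered correlation undefined for zero vectors")
    return float(1.0 - np.dot(x, y) / (nx * ny))


def _pairwise_uncentered_dist(v: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0):
        raise ValidationError("zero feature profile in distance computation")
    sim = (v / norms[:, None]) @ (v / norms[:, None]).T
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def hcluster_genes(e: ExpressionMatrix, method: str = "average",
                   n_clusters: int | None = None, height: float | None = None):
    """Agglomerative clustering of gene profiles under uncentered-correlation distance.

    Returns (scipy linkage matrix, flat cluster labels or None). Deterministic
    for distinct pairwise distances.
    """
    if method not in {"complete", "average"}:
        raise ValidationError("linkage must be 'complete' or 'average'")
    v = e.values.to_numpy(dtype=float)
    if v.shape[0] < 2:
        raise ValidationError("need >=2 features to cluster")
    Z = linkage(squareform(_pairwise_uncentered_dist(v), checks=False), method=method)
    labels = None
    if n_clusters is not None:
        labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    elif height is not None:
        labels = fcluster(Z, t=height, criterion="distance")
    return Z, labels


def kmeans_gene_clusters(e: ExpressionMatrix, k: int, seed: int,
                         n_restarts: int = 20) -> np.ndarray:
    """Consensus k-means on median-centered rows.

    Runs k-means ``n_restarts`` times with seeds derived from ``seed``, builds
    the co-assignment (consensus) matrix, and cuts its average-linkage tree at
    k groups. Deterministic given the seed.
    """
    v = median_center(e).values.to_numpy(dtype=float)
    n = v.shape[0]
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > n:
        raise ValidationError(f"k={k} exceeds number of features {n}")
    if k == n:
        return np.arange(1, n + 1)
    rng = np.random.default_rng(seed)
    co = np.zeros((n, n))
    for _ in range(n_restarts):
        km = KMeans(n_clusters=k, n_init=1, random_state=int(rng.integers(2**31)))
        lab = km.fit_predict(v)
        co += lab[:, None] == lab[None, :]
    co /= n_restarts
    Z = linkage(squareform(1.0 - co, checks=False), method="average")
    return fcluster(Z, t=k, criterion="maxclust")


def _cluster_contrast(v_rows: np.ndarray, cols: pd.Index, sheet: SampleSheet,
                      group1_ids: list[str], group2_ids: list[str]) -> float:
    idx1 = [cols.get_loc(s) for s in group1_ids]
    idx2 = [cols.get_loc(s) for s in group2_ids]
    return float(v_rows[:, idx1].mean() - v_rows[:, idx2].mean())


def derive_cluster_pair(
    e: ExpressionMatrix,
    sheet: SampleSheet,
    group1_ids: list[str],
    group2_ids: list[str],
    method: str = "average",
    max_clusters: int = 12,
) -> tuple[GeneCluster, GeneCluster]:
    """Pick the up- and down-regulated clusters with the strongest group contrast.

    The tree is cut at ``max_clusters`` flat clusters; among them, the cluster
    with the largest positive mean contrast (group1 minus group2) becomes the
    up cluster and the most negative one the down cluster.
    """
    centered = median_center(e)
    _, labels = hcluster_genes(centered, method=method, n_clusters=max_clusters)
    v = centered.values.to_numpy(dtype=float)
    cols = centered.values.columns
    contrasts = {}
    for lab in np.unique(labels):
        rows = v[labels == lab]
        contrasts[lab] = _cluster_contrast(rows, cols, sheet, group1_ids, group2_ids)
    up_lab = max(contrasts, key=contrasts.get)
    down_lab = min(contrasts, key=contrasts.get)
    if contrasts[up_lab] <= 0 or contrasts[down_lab] >= 0:
        raise ValidationError("no cluster pair with opposite group contrasts found")

    def _make(lab: int, direction: str) -> GeneCluster:
        ids = list(centered.values.index[labels == lab])
        rows = v[labels == lab]
        if len(ids) > 1:
            sim = 1.0 - _pairwise_uncentered_dist(rows)
            mean_corr = float(sim[np.triu_indices(len(ids), 1)].mean())
        else:
            mean_corr = 1.0
        return GeneCluster(gene_ids=ids, direction=direction, mean_intra_correlation=mean_corr)

    return _make(up_lab, "up"), _make(down_lab, "down")


def extract_signature(
    up: GeneCluster,
    down: GeneCluster,
    genes: GeneAnnotation,
    integrome_genes: set[str] | list[str],
) -> GeneSignature:
    """Reduce the cluster pair to protein-coding, integrome-supported genes."""
    if up.direction != "up" or down.direction != "down":
        raise ValidationError("expected one up and one down cluster")
    integrome_genes = set(integrome_genes)
    biotype = genes.frame["biotype"]
    entries = {}
    for cluster, w in ((up, 1), (down, -1)):
        for g in sorted(cluster.gene_ids):
            if g not in biotype.index or biotype[g] != "protein_coding":
                continue
            if g not in integrome_genes:
                continue
            entries[g] = w
    if not entries:
        raise ValidationError("signature is empty after biotype/integrome filters")
    sig = pd.Series(entries).sort_index()
    return GeneSignature(
        entries=sig,
        provenance={"n_up_input": len(up.gene_ids), "n_down_input": len(down.gene_ids)},
    )
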