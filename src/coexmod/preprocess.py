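"""Quality control, normalisation, per-donor scaling, clustering, annotation.

Single-cell normalisation is median-library-size scaling followed by log1p;
bulk normalisation is the median-of-ratios size factor (the DESeq estimator).
Donor batch effects are removed by z-scoring each gene within each donor.
Clustering is PCA -> k-nearest-neighbour graph -> modularity-based community
detection (Leiden with the RB-configuration objective), and cluster annotation
is nearest-centroid against reference mean profiles by Spearman correlation —
a deliberate simplification of anchor-based label transfer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import spearmanr
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import ExpressionMatrix

logger = logging.getLogger("coexmod")

__all__ = [
    "ClusterResult", "ReferenceCentroids",
    "qc_filter_cells", "normalize_log", "normalize_median_of_ratios",
    "scale_within_batch", "select_hvgs", "cluster_cells",
    "annotate_nearest_centroid", "subset_and_recluster",
    "fraction_double_positive", "build_reference_centroids",
]


@dataclass
class ClusterResult:
    """Cluster labels plus the parameters and quality of the partition."""

    labels: dict[str, int]            # obs_id -> dense cluster id from 0
    params: dict
    modularity: float

    def __post_init__(self) -> None:
        ids = sorted(set(self.labels.values()))
        if ids != list(range(len(ids))):
            raise ValueError("cluster ids must be dense integers from 0")

    def as_series(self, obs_ids) -> pd.Series:
        return pd.Series([self.labels[o] for o in obs_ids], index=obs_ids,
                         name="cluster")


@dataclass
class ReferenceCentroids:
    """Mean log-normalised profile per cell type over a shared gene list."""

    gene_ids: list[str]
    profiles: dict[str, np.ndarray]   # cell_type -> vector over gene_ids

    def __post_init__(self) -> None:
        for ct, v in self.profiles.items():
            if len(v) != len(self.gene_ids):
                raise ValueError(f"centroid {ct} not aligned to gene list")
            if not np.any(v):
                raise ValueError(f"centroid {ct} is all zero")


# ---------------------------------------------------------------------------
# QC and normalisation
# ---------------------------------------------------------------------------

def qc_filter_cells(m: ExpressionMatrix, min_genes: int = 200,
                    max_genes: int = 6000, max_mito_frac: float = 0.2,
                    mito_prefix: str = "MT-") -> ExpressionMatrix:
    """Keep cells by detected-gene count and mitochondrial fraction."""
    if m.layer_tag != "counts":
        raise ValueError("qc_filter_cells requires the counts layer")
    vals = m.values
    if sp.issparse(vals):
        detected = np.asarray((vals > 0).sum(axis=0)).ravel()
        totals = np.asarray(vals.sum(axis=0)).ravel()
    else:
        detected = (vals > 0).sum(axis=0)
        totals = vals.sum(axis=0)
    mito_rows = np.array([g.startswith(mito_prefix) for g in m.gene_ids])
    if mito_rows.any():
        sub = vals[mito_rows, :]
        mito = np.asarray(sub.sum(axis=0)).ravel()
    else:
        mito = np.zeros(m.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito / np.maximum(totals, 1), 1.0)
    keep = (detected >= min_genes) & (detected <= max_genes) & (mito_frac <= max_mito_frac)
    if not keep.any():
        raise ValueError("QC removed every cell; thresholds too strict for this data")
    logger.info("QC kept %d of %d cells", int(keep.sum()), m.n_obs)
    return m.subset_obs(keep)


def normalize_log(m: ExpressionMatrix, target_sum: float | None = None
                  ) -> ExpressionMatrix:
    """Median-library-size scaling followed by log1p.

    Per cell: value -> log1p(value * target_sum / cell_total), with
    target_sum defaulting to the median cell total.
    """
    if m.layer_tag != "counts":
        raise ValueError("normalize_log requires the counts layer")
    dense = m.dense()
    totals = dense.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("cell with zero total counts; run QC first")
    if target_sum is None:
        target_sum = float(np.median(totals))
    out = np.log1p(dense * (target_sum / totals)[None, :])
    return ExpressionMatrix(out, list(m.gene_ids), list(m.obs_ids),
                            m.obs_meta, "lognorm")


def normalize_median_of_ratios(bulk: ExpressionMatrix
                               ) -> tuple[ExpressionMatrix, np.ndarray]:
    """DESeq-style median-of-ratios normalisation for bulk counts.

    Size factor per sample = median over all-sample-nonzero genes of
    count / geometric-mean-across-samples; values are divided by the factor.
    """
    if bulk.layer_tag != "counts":
        raise ValueError("normalize_median_of_ratios requires the counts layer")
    dense = bulk.dense()
    everywhere = (dense > 0).all(axis=1)
    if not everywhere.any():
        raise ValueError("no gene has nonzero counts in every sample")
    logs = np.log(dense[everywhere, :])
    geo = logs.mean(axis=1)
    ratios = np.exp(logs - geo[:, None])
    factors = np.median(ratios, axis=0)
    out = dense / factors[None, :]
    em = ExpressionMatrix(out, list(bulk.gene_ids), list(bulk.obs_ids),
                          bulk.obs_meta, "counts")
    return em, factors


def scale_within_batch(m: ExpressionMatrix, batch_labels) -> ExpressionMatrix:
    """Z-score each gene within each batch (donor).

    Removes per-donor differences in average and variance; genes constant
    within a batch become zero there.
    """
    if m.layer_tag != "lognorm":
        raise ValueError("scale_within_batch requires the lognorm layer")
    batch_labels = np.asarray(batch_labels)
    if len(batch_labels) != m.n_obs:
        raise ValueError("batch label per observation required")
    dense = m.dense()
    out = np.zeros_like(dense)
    for b in np.unique(batch_labels):
        cols = batch_labels == b
        if cols.sum() < 2:
            raise ValueError(f"batch {b!r} has a single observation; SD undefined")
        block = dense[:, cols]
        mean = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=0, keepdims=True)
        centred = block - mean
        out[:, cols] = np.divide(centred, sd, out=np.zeros_like(centred),
                                 where=sd > 0)
    return ExpressionMatrix(out, list(m.gene_ids), list(m.obs_ids),
                            m.obs_meta, "scaled")


def select_hvgs(m: ExpressionMatrix, n_top: int) -> list[str]:
    """Top genes by variance of log-normalised values, ties by gene id."""
    if m.layer_tag != "lognorm":
        raise ValueError("select_hvgs requires the lognorm layer")
    if n_top > m.n_genes:
        raise ValueError(f"n_top={n_top} exceeds {m.n_genes} genes")
    var = m.dense().var(axis=1, ddof=0)
    order = sorted(range(m.n_genes), key=lambda i: (-var[i], m.gene_ids[i]))
    return [m.gene_ids[i] for i in order[:n_top]]


# ---------------------------------------------------------------------------
# Clustering and annotation
# ---------------------------------------------------------------------------

def _knn_graph(pcs: np.ndarray, k: int) -> ig.Graph:
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    edges = set()
    for i in range(idx.shape[0]):
        for j in idx[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    g = ig.Graph(n=pcs.shape[0], edges=sorted(edges))
    return g


def cluster_cells(m: ExpressionMatrix, n_pcs: int = 30, k_neighbors: int = 15,
                  resolution: float = 1.0, seed: int = 0) -> ClusterResult:
    """PCA -> kNN graph -> Leiden community detection; seeded, deterministic."""
    if m.layer_tag != "scaled":
        raise ValueError("cluster_cells requires the scaled layer")
    if k_neighbors >= m.n_obs:
        raise ValueError("k_neighbors must be below the number of cells")
    X = m.dense().T  # observations x genes
    n_pcs = min(n_pcs, min(X.shape) - 1)
    pca = PCA(n_components=n_pcs, svd_solver="full")
    pcs = pca.fit_transform(X)
    # fix component signs for bit-reproducibility across BLAS builds
    signs = np.sign(pca.components_[np.arange(n_pcs),
                                    np.abs(pca.components_).argmax(axis=1)])
    pcs = pcs * signs[None, :]
    graph = _knn_graph(pcs, k_neighbors)
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed, n_iterations=2,
    )
    membership = np.asarray(part.membership)
    # dense ids ordered by cluster size (ties by first occurrence)
    sizes = pd.Series(membership).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {c: i for i, c in enumerate(order)}
    labels = {o: remap[int(c)] for o, c in zip(m.obs_ids, membership)}
    modularity = graph.modularity(membership)
    return ClusterResult(
        labels=labels,
        params={"n_pcs": n_pcs, "k_neighbors": k_neighbors,
                "resolution": resolution, "seed": seed},
        modularity=float(modularity),
    )


def build_reference_centroids(ref_lognorm: ExpressionMatrix,
                              cell_type_col: str = "cell_type"
                              ) -> ReferenceCentroids:
    """Mean log-normalised profile per annotated cell type of a reference."""
    if ref_lognorm.obs_meta is None or cell_type_col not in ref_lognorm.obs_meta:
        raise ValueError(f"reference metadata lacks {cell_type_col!r}")
    dense = ref_lognorm.dense()
    types = ref_lognorm.obs_meta[cell_type_col].astype(str).to_numpy()
    profiles = {}
    for ct in sorted(set(types)):
        profiles[ct] = dense[:, types == ct].mean(axis=1)
    return ReferenceCentroids(list(ref_lognorm.gene_ids), profiles)


def annotate_nearest_centroid(m: ExpressionMatrix, clusters: ClusterResult,
                              ref: ReferenceCentroids, min_corr: float = 0.5
                              ) -> dict[int, str]:
    """Assign each cluster the reference cell type with the highest Spearman
    correlation of mean profiles; below ``min_corr`` -> "Unknown"."""
    if m.layer_tag != "lognorm":
        raise ValueError("annotate_nearest_centroid requires the lognorm layer")
    shared = [g for g in m.gene_ids if g in set(ref.gene_ids)]
    if len(shared) < 50:
        raise ValueError(
            f"only {len(shared)} genes shared with the reference (floor: 50)"
        )
    row_m = m.gene_index(shared)
    row_r = {g: i for i, g in enumerate(ref.gene_ids)}
    ridx = np.array([row_r[g] for g in shared])
    dense = m.dense()
    member = clusters.as_series(m.obs_ids).to_numpy()
    out: dict[int, str] = {}
    for c in sorted(set(member.tolist())):
        prof = dense[np.ix_(row_m, member == c)].mean(axis=1)
        best, best_r = "Unknown", -np.inf
        for ct in sorted(ref.profiles):
            r = spearmanr(prof, ref.profiles[ct][ridx]).statistic
            if np.isnan(r):
                r = -np.inf
            if r > best_r:
                best, best_r = ct, r
        out[c] = best if best_r >= min_corr else "Unknown"
    return out


def cluster_pipeline(lognorm: ExpressionMatrix, batch_labels, n_hvgs: int,
                     n_pcs: int, k_neighbors: int, resolution: float,
                     seed: int) -> ClusterResult:
    """HVG selection -> within-batch scaling -> cluster_cells."""
    hvgs = select_hvgs(lognorm, min(n_hvgs, lognorm.n_genes))
    sub = lognorm.subset_genes(hvgs)
    scaled = scale_within_batch(sub, batch_labels)
    return cluster_cells(scaled, n_pcs=n_pcs, k_neighbors=k_neighbors,
                         resolution=resolution, seed=seed)


def subset_and_recluster(lognorm: ExpressionMatrix, labels, target_types,
                         batch_labels=None, n_hvgs: int = 2000,
                         n_pcs: int = 30, k_neighbors: int = 15,
                         resolution: float = 1.0, seed: int = 0
                         ) -> tuple[ClusterResult, ExpressionMatrix]:
    """Re-run HVG selection, scaling and clustering on a label subset.

    ``labels`` maps obs_id to a (cluster or cell-type) label; observations
    whose label is in ``target_types`` are kept.
    """
    target = set(target_types)
    keep = np.array([labels[o] in target for o in lognorm.obs_ids])
    if not keep.any():
        raise ValueError(f"no observations labelled {sorted(target)}")
    if keep.sum() <= k_neighbors:
        raise ValueError("subset smaller than k_neighbors")
    sub = lognorm.subset_obs(keep)
    if batch_labels is None:
        if sub.obs_meta is None or "donor" not in sub.obs_meta:
            raise ValueError("batch labels required (none in metadata)")
        batch = sub.obs_meta["donor"].to_numpy()
    else:
        batch = np.asarray(batch_labels)[keep]
    res = cluster_pipeline(sub, batch, n_hvgs, n_pcs, k_neighbors,
                           resolution, seed)
    return res, sub


def fraction_double_positive(m: ExpressionMatrix, gene_a: str, gene_b: str,
                             threshold: float = 0.0
                             ) -> tuple[int, int, float]:
    """Count cells expressing both genes above ``threshold``.

    Mirrors marker co-positivity summaries such as the fraction of
    TREM2+CD9+ macrophages.
    """
    if m.layer_tag != "counts":
        raise ValueError("fraction_double_positive requires the counts layer")
    for g in (gene_a, gene_b):
        if g not in m.gene_ids:
            raise KeyError(f"gene absent from matrix: {g!r}")
    rows = m.gene_index([gene_a, gene_b])
    dense = m.dense()[rows, :]
    both = (dense[0] > threshold) & (dense[1] > threshold)
    count = int(both.sum())
    total = m.n_obs
    return count, total, count / total
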