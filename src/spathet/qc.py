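"""Quality control, normalization, HVG selection, clustering and markers.

QC follows the two regimes used for the two data sources: the ``geo``
preset keeps spots with at least 400 detected genes; the ``proprietary``
preset enforces a 200-4,000 detected-gene band and a strict < 13%
mitochondrial-content bound. "Fewer than 400" is read literally (>= 400
retained); the mitochondrial rule is a strict ``<``.

Clustering is the standard single-cell recipe: library-size normalization
to the median depth, log1p, dispersion-based HVG selection (variance/mean
z-scored within 20 mean bins), PCA on the centered/scaled HVG submatrix,
a k-nearest-neighbor graph and Leiden community detection. Markers are
one-vs-rest Wilcoxon rank-sum with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph
from statsmodels.stats.multitest import multipletests

from ._utils import logger
from .io import CountMatrix, ExpressionMatrix, GeneSetCollection

__all__ = [
    "QcThresholds",
    "QC_PRESETS",
    "filter_observations",
    "normalize_log",
    "select_hvg",
    "GraphClusterer",
    "embed_and_cluster",
    "find_markers",
    "classify_clusters",
]


@dataclass(frozen=True)
class QcThresholds:
    min_genes: int = 0
    max_genes: "int | None" = None
    max_mito_fraction: "float | None" = None

    def __post_init__(self):
        if self.min_genes < 0:
            raise ValueError("min_genes must be >= 0")
        if self.max_genes is not None and self.max_genes <= self.min_genes:
            raise ValueError("max_genes must exceed min_genes")
        if self.max_mito_fraction is not None and not 0 <= self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in [0, 1]")


#: The two QC regimes: GEO-derived sections filter on detected genes only;
#: in-house sections additionally bound gene count above and mito content.
QC_PRESETS: dict[str, QcThresholds] = {
    "geo": QcThresholds(min_genes=400),
    "proprietary": QcThresholds(min_genes=200, max_genes=4000, max_mito_fraction=0.13),
}


def mito_fraction(cm: CountMatrix) -> np.ndarray:
    """Fraction of counts on genes named ``MT-*`` per observation."""
    mt = np.array([g.upper().startswith("MT-") for g in cm.gene_ids])
    dense_tot = cm.depths().astype(float)
    mt_tot = np.asarray(cm.values[mt, :].sum(axis=0)).ravel().astype(float) if mt.any() else np.zeros_like(dense_tot)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(dense_tot > 0, mt_tot / dense_tot, 0.0)
    return frac


def filter_observations(cm: CountMatrix, thresholds: QcThresholds) -> list[str]:
    """Observation ids passing QC, in matrix order.

    Retained iff detected-gene count >= min_genes, <= max_genes (when
    set), and mitochondrial fraction strictly < max_mito_fraction (when
    set). Idempotent: filtering an already-filtered matrix is a no-op.
    """
    detected = cm.detected_genes()
    keep = detected >= thresholds.min_genes
    if thresholds.max_genes is not None:
        keep &= detected <= thresholds.max_genes
    if thresholds.max_mito_fraction is not None:
        keep &= mito_fraction(cm) < thresholds.max_mito_fraction
    return [o for o, k in zip(cm.obs_ids, keep) if k]


def normalize_log(cm: CountMatrix) -> ExpressionMatrix:
    """Depth-normalize each observation to the median depth, then log1p.

    Centering and scaling are deferred to the embedding step, so that
    signature scores and NMF inputs stay non-negative.
    """
    depths = cm.depths().astype(float)
    zero = [o for o, d in zip(cm.obs_ids, depths) if d == 0]
    if zero:
        raise ValueError(f"observations with all-zero counts: {zero[:5]}")
    med = float(np.median(depths))
    x = cm.dense().astype(float) * (med / depths)[None, :]
    return ExpressionMatrix(np.log1p(x), list(cm.gene_ids), list(cm.obs_ids))


def select_hvg(em: ExpressionMatrix, n: int, n_bins: int = 20) -> list[str]:
    """Top-``n`` highly variable genes by binned normalized dispersion.

    Dispersion = variance/mean per gene, z-scored within ``n_bins``
    equal-width bins of the gene means; ranking is by z-scored dispersion
    descending with a deterministic lexicographic tie-break on gene id.
    """
    n_genes = len(em.gene_ids)
    if n > n_genes:
        raise ValueError(f"requested {n} HVGs from {n_genes} genes")
    means = em.values.mean(axis=1)
    var = em.values.var(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(means > 0, var / means, 0.0)
    df = pd.DataFrame({"gene_id": em.gene_ids, "mean": means, "disp": disp})
    # equal-width mean bins; degenerate (constant-mean) input falls into one bin
    try:
        df["bin"] = pd.cut(df["mean"], bins=n_bins, labels=False, duplicates="drop")
    except ValueError:
        df["bin"] = 0
    df["bin"] = df["bin"].fillna(0)

    def _z(s: pd.Series) -> pd.Series:
        sd = s.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            return pd.Series(np.zeros(len(s)), index=s.index)
        return (s - s.mean()) / sd

    df["z"] = df.groupby("bin")["disp"].transform(_z)
    df = df.sort_values(["z", "gene_id"], ascending=[False, True], kind="mergesort")
    return df["gene_id"].head(n).tolist()


def _scale_rows(x: np.ndarray, clip: float = 10.0) -> np.ndarray:
    """Center and scale each row (gene) to unit variance, clipping extremes."""
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return np.clip((x - mu) / sd, -clip, clip)


class GraphClusterer(ClusterMixin, BaseEstimator):
    """PCA + kNN-graph + Leiden community detection.

    sklearn-style clusterer over an observations x features array:
    center/scale features, project to ``n_pcs`` principal components,
    build a symmetrized ``n_neighbors`` nearest-neighbor graph and run
    Leiden at the given ``resolution``. Deterministic given
    ``random_state``.
    """

    def __init__(self, n_pcs=20, n_neighbors=15, resolution=1.0, random_state=0):
        self.n_pcs = n_pcs
        self.n_neighbors = n_neighbors
        self.resolution = resolution
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2D observations x features array")
        n_obs, n_feat = X.shape
        if n_obs < self.n_pcs:
            raise ValueError(f"{n_obs} observations < n_pcs={self.n_pcs}")
        n_pcs = min(self.n_pcs, n_feat)
        Xs = _scale_rows(X.T).T
        pca = PCA(n_components=n_pcs, svd_solver="full", random_state=self.random_state)
        emb = pca.fit_transform(Xs)
        k = min(self.n_neighbors, n_obs - 1)
        adj = kneighbors_graph(emb, n_neighbors=k, mode="connectivity")
        adj = adj.maximum(adj.T).tocoo()
        edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
        g = igraph.Graph(n=n_obs, edges=edges)
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=self.resolution,
            seed=int(self.random_state),
            n_iterations=2,
        )
        self.labels_ = np.asarray(part.membership, dtype=int)
        self.embedding_ = emb
        return self


def embed_and_cluster(
    em: ExpressionMatrix,
    hvgs: list[str],
    n_pcs: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
    n_neighbors: int = 15,
) -> pd.DataFrame:
    """Cluster observations; returns a label table (obs_id, label)."""
    sub = em.subset_genes(hvgs)
    model = GraphClusterer(
        n_pcs=n_pcs, n_neighbors=n_neighbors, resolution=resolution, random_state=seed
    )
    labels = model.fit(sub.values.T).labels_
    return pd.DataFrame({"obs_id": em.obs_ids, "label": [str(c) for c in labels]})


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p per gene (rows); exact for small
    tie-free groups, normal approximation with tie correction otherwise."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = scipy.stats.mannwhitneyu(x, y, axis=1, alternative="two-sided", method="auto")
    return np.atleast_1d(res.pvalue)


def find_markers(
    em: ExpressionMatrix,
    labels: pd.DataFrame,
    max_adj_p: float = 0.05,
    min_log2_fc: float = 0.25,
    min_cluster_size: int = 3,
) -> dict[str, pd.DataFrame]:
    """One-vs-rest marker genes per cluster.

    Wilcoxon rank-sum per gene, Benjamini-Hochberg within cluster; genes
    with adjusted p < ``max_adj_p`` and log2 fold change > ``min_log2_fc``
    are reported, sorted by (adjusted p, fold change descending). The fold
    change compares mean de-logged expression with a +1 pseudocount, as
    marker callers in this field conventionally do.
    """
    lab = labels.set_index("obs_id")["label"]
    order = [o for o in em.obs_ids if o in lab.index]
    if len(order) < len(em.obs_ids):
        em = em.subset_obs(order)
    y = lab.loc[em.obs_ids].to_numpy()
    clusters = sorted(set(y))
    if len(clusters) < 2:
        raise ValueError("marker detection needs >= 2 clusters")
    out: dict[str, pd.DataFrame] = {}
    expm1 = np.expm1(em.values)
    for c in clusters:
        mask = y == c
        if mask.sum() < min_cluster_size:
            logger.warning("cluster %s has < %d observations; skipped", c, min_cluster_size)
            continue
        x_in, x_out = em.values[:, mask], em.values[:, ~mask]
        p = _rank_sum_p(x_in, x_out)
        lfc = np.log2(expm1[:, mask].mean(axis=1) + 1) - np.log2(
            expm1[:, ~mask].mean(axis=1) + 1
        )
        adj = multipletests(p, method="fdr_bh")[1]
        df = pd.DataFrame(
            {
                "gene_id": em.gene_ids,
                "log2_fold_change": lfc,
                "p_value": p,
                "adjusted_p": adj,
            }
        )
        df = df[(df["adjusted_p"] < max_adj_p) & (df["log2_fold_change"] > min_log2_fc)]
        df = df.sort_values(
            ["adjusted_p", "log2_fold_change"],
            ascending=[True, False],
            kind="mergesort",
        ).reset_index(drop=True)
        out[c] = df
    return out


def classify_clusters(
    markers: dict[str, pd.DataFrame],
    tumor_sig: list[str],
    stromal_sig: list[str],
    min_overlap: int = 5,
) -> dict[str, str]:
    """Classify clusters as tumor / stromal / unknown by marker overlap.

    A cluster is tumor when its markers overlap the tumor signature by at
    least ``min_overlap`` genes and strictly more than the stromal
    signature (symmetrically for stromal); ties and insufficient overlap
    are unknown.
    """
    if not tumor_sig or not stromal_sig:
        raise ValueError("signatures must be non-empty")
    t, s = set(tumor_sig), set(stromal_sig)
    out = {}
    for c, df in markers.items():
        genes = set(df["gene_id"])
        nt, ns = len(genes & t), len(genes & s)
        if nt >= min_overlap and nt > ns:
            out[c] = "tumor"
        elif ns >= min_overlap and ns > nt:
            out[c] = "stromal"
        else:
            out[c] = "unknown"
    return out
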