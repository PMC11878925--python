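"""Intratumor expression programs and cross-sample meta-programs.

Per tumor sample, non-negative matrix factorization of the normalized
(log1p) expression of tumor cells decomposes variation into a small
number of factors; each factor's top 50 genes by weight define an
intratumor expression program. The factorization rank is swept over
2..6 and chosen as the point just before the reconstruction-error
improvement becomes negligible (< 5% relative). Programs from all
samples are clustered by average linkage on 1 - Jaccard distance
(Jaccard = |A∩B| / |A∪B|); a cluster spanning at least two samples is a
meta-program whose signature keeps the genes shared by at least 1/3 of
its contributing samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from sklearn.base import BaseEstimator
from sklearn.decomposition import NMF

from .io import ExpressionMatrix

__all__ = [
    "Program",
    "MetaProgram",
    "fit_nmf",
    "select_rank",
    "extract_programs",
    "jaccard",
    "jaccard_matrix",
    "cluster_programs",
    "score_metaprogram",
    "ExpressionProgramNMF",
]


@dataclass(frozen=True)
class Program:
    """Top-weight gene set of one NMF factor in one sample."""

    sample_id: str
    factor_index: int
    genes: tuple  # exactly top_n gene ids, descending factor weight

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("program genes must be unique")


@dataclass
class MetaProgram:
    """Cluster of intratumor programs shared across samples."""

    member_programs: list
    contributing_samples: frozenset
    signature: list  # genes shared by >= ceil(share_fraction * samples) samples

    def __post_init__(self):
        if len(self.contributing_samples) < 2:
            raise ValueError("a meta-program needs programs from >= 2 samples")


def _nmf(X: np.ndarray, rank: int, seed: int) -> NMF:
    if (X < 0).any():
        raise ValueError("NMF input must be non-negative")
    if rank >= min(X.shape):
        raise ValueError(f"rank {rank} must be < min{X.shape}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = NMF(
            n_components=rank,
            init="nndsvda",
            solver="cd",
            tol=1e-4,
            max_iter=500,
            random_state=seed,
        )
        model.fit(X)
    return model


def fit_nmf(matrix: np.ndarray, rank: int, seed: int = 0):
    """Factorize a genes x cells matrix: returns (W genes x rank,
    H rank x cells), both non-negative; deterministic given seed."""
    X = np.asarray(matrix, dtype=float)
    model = _nmf(X, rank, seed)
    W = model.transform(X)
    H = model.components_
    return W, H


def _relative_error(X: np.ndarray, rank: int, seed: int) -> float:
    model = _nmf(X, rank, seed)
    W = model.transform(X)
    return float(np.linalg.norm(X - W @ model.components_) / np.linalg.norm(X))


def select_rank(
    matrix: np.ndarray,
    rank_min: int = 2,
    rank_max: int = 6,
    seed: int = 0,
    drop_threshold: float = 0.05,
) -> int:
    """Error-elbow rank selection over the 2..6 sweep.

    With e_k the relative Frobenius reconstruction error at rank k,
    returns the smallest k where the improvement to k+1 falls below
    ``drop_threshold`` (the point just before the gain becomes
    negligible), else ``rank_max``.
    """
    if not 2 <= rank_min < rank_max:
        raise ValueError("need 2 <= rank_min < rank_max")
    X = np.asarray(matrix, dtype=float)
    errors = {k: _relative_error(X, k, seed) for k in range(rank_min, rank_max + 1)}
    for k in range(rank_min, rank_max):
        e_k, e_next = errors[k], errors[k + 1]
        if e_k <= 0 or (e_k - e_next) / e_k < drop_threshold:
            return k
    return rank_max


def extract_programs(
    W: np.ndarray, gene_ids: list[str], sample_id: str, top_n: int = 50
) -> list[Program]:
    """One Program per factor: the ``top_n`` genes by descending factor
    weight, ties broken by lexicographic gene id."""
    W = np.asarray(W, dtype=float)
    if top_n > W.shape[0]:
        raise ValueError(f"top_n={top_n} exceeds {W.shape[0]} genes")
    programs = []
    for f in range(W.shape[1]):
        order = sorted(range(W.shape[0]), key=lambda i: (-W[i, f], gene_ids[i]))
        genes = tuple(gene_ids[i] for i in order[:top_n])
        programs.append(Program(sample_id=sample_id, factor_index=f, genes=genes))
    return programs


def jaccard(a: set, b: set) -> float:
    """|a∩b| / |a∪b|; undefined (error) when both sets are empty."""
    a, b = set(a), set(b)
    if not a and not b:
        raise ValueError("Jaccard of two empty sets is undefined")
    return len(a & b) / len(a | b)


def jaccard_matrix(programs: list[Program]) -> np.ndarray:
    """Symmetric pairwise Jaccard matrix with unit diagonal."""
    n = len(programs)
    J = np.eye(n)
    sets = [set(p.genes) for p in programs]
    for i in range(n):
        for j in range(i + 1, n):
            J[i, j] = J[j, i] = jaccard(sets[i], sets[j])
    return J


def cluster_programs(
    programs: list[Program],
    cut: float = 0.8,
    share_fraction: float = 1.0 / 3.0,
) -> list[MetaProgram]:
    """Meta-programs by average-linkage clustering on 1 - Jaccard.

    The dendrogram is cut at distance ``cut``; clusters whose programs
    span at least two samples become meta-programs. A meta-program's
    signature keeps genes occurring in programs from at least
    ``ceil(share_fraction * n_contributing_samples)`` distinct samples,
    ordered by how many samples share them (descending), then gene id.
    """
    if len(programs) < 2:
        raise ValueError("need >= 2 programs to cluster")
    J = jaccard_matrix(programs)
    dist = 1.0 - J
    np.fill_diagonal(dist, 0.0)
    Z = sch.linkage(ssd.squareform(dist, checks=False), method="average")
    flat = sch.fcluster(Z, t=cut, criterion="distance")
    out = []
    for c in sorted(set(flat)):
        members = [programs[i] for i in np.flatnonzero(flat == c)]
        samples = frozenset(p.sample_id for p in members)
        if len(samples) < 2:
            continue
        need = int(np.ceil(share_fraction * len(samples)))
        gene_samples: dict[str, set] = {}
        for p in members:
            for g in p.genes:
                gene_samples.setdefault(g, set()).add(p.sample_id)
        sig = [g for g, s in gene_samples.items() if len(s) >= need]
        sig.sort(key=lambda g: (-len(gene_samples[g]), g))
        out.append(
            MetaProgram(
                member_programs=members,
                contributing_samples=samples,
                signature=sig,
            )
        )
    return out


def score_metaprogram(em: ExpressionMatrix, mp: MetaProgram) -> dict:
    """Per-cell mean of centered, unit-scaled signature-gene expression."""
    present = [g for g in mp.signature if g in set(em.gene_ids)]
    if not present:
        raise ValueError("no signature gene present in the matrix")
    sub = em.subset_genes(present).values
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - mu) / sd
    scores = z.mean(axis=0)
    return {o: float(s) for o, s in zip(em.obs_ids, scores)}


class ExpressionProgramNMF(BaseEstimator):
    """sklearn-style estimator: NMF with rank sweep and top-gene programs.

    ``fit(X)`` takes a cells x genes non-negative array (or DataFrame,
    whose columns provide gene ids). Fitted attributes: ``rank_``,
    ``components_`` (rank x genes), ``programs_`` (list of Program).
    """

    def __init__(self, rank="auto", rank_min=2, rank_max=6, top_n=50,
                 sample_id="sample", random_state=0):
        self.rank = rank
        self.rank_min = rank_min
        self.rank_max = rank_max
        self.top_n = top_n
        self.sample_id = sample_id
        self.random_state = random_state

    def fit(self, X, y=None):
        gene_ids = None
        if hasattr(X, "columns"):
            gene_ids = [str(c) for c in X.columns]
            X = X.to_numpy()
        X = np.asarray(X, dtype=float)
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(X.shape[1])]
        Xg = X.T  # genes x cells for the factor-weight orientation
        if self.rank == "auto":
            self.rank_ = select_rank(
                Xg, self.rank_min, self.rank_max, seed=self.random_state
            )
        else:
            self.rank_ = int(self.rank)
        W, H = fit_nmf(Xg, self.rank_, seed=self.random_state)
        self.components_ = W.T  # rank x genes
        self.cell_weights_ = H.T  # cells x rank
        self.programs_ = extract_programs(
            W, gene_ids, sample_id=self.sample_id, top_n=self.top_n
        )
        return self
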