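"""Expression-inferred copy number: profiles, burden, clones, clone tree.

The profiler is a lightweight analog of reference-based CNV inference
from expression: genes are filtered at a mean-expression cutoff, log2
expression is centered on a stromal/normal reference, clipped, smoothed
along the karyotype with a moving average within each chromosome,
re-centered per observation at its median, and exponentiated to copy
ratios centered at 1. Per-observation CNV burden is

    CNV_score_i = 1 + mean_g |ratio_ig - 1|

and is normalized to [0, 1] by

    nCNV_score_i = (CNV_score_i - 1) / (maxCNV_score - 1),

so a no-CNV observation maps to exactly 0 and the highest-burden
observation to 1. Clones are average-linkage hierarchical clusters of
ratio profiles; per-clone events are maximal runs of consecutive genes
beyond gain/loss thresholds; the clone tree is a greedy perfect-phylogeny
over shared events with the diploid "normal" state as root.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin

from .io import CountMatrix, GeneSetCollection

__all__ = [
    "CnvProfile",
    "CnvScoreMap",
    "CnvEvent",
    "CloneTree",
    "CNVProfiler",
    "infer_cnv",
    "cnv_burden",
    "normalize_cnv",
    "reclassify_tumor_cells",
    "CloneCaller",
    "detect_clones",
    "segment_events",
    "build_clone_tree",
    "link_events_to_gene_sets",
]


@dataclass
class CnvProfile:
    """Observations x karyotype-ordered genes matrix of copy ratios."""

    obs_ids: list[str]
    gene_ids: list[str]  # karyotype order, post expression-cutoff
    chromosomes: list[str]  # per gene
    ratios: np.ndarray  # obs x genes, centered at 1
    window: int
    reference_obs: list[str]

    def __post_init__(self):
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.ratios.shape != (len(self.obs_ids), len(self.gene_ids)):
            raise ValueError("ratio matrix shape does not match id lists")
        if (self.ratios <= 0).any():
            raise ValueError("copy ratios must be strictly positive")

    def query_mask(self) -> np.ndarray:
        ref = set(self.reference_obs)
        return np.array([o not in ref for o in self.obs_ids])


@dataclass
class CnvScoreMap:
    """Per-observation CNV burden, raw (>= 1) and normalized to [0, 1]."""

    raw: dict  # obs_id -> CNV_score_i >= 1
    normalized: dict = field(default_factory=dict)  # obs_id -> nCNV_score_i
    max_raw: float = 1.0


@dataclass(frozen=True)
class CnvEvent:
    """A contiguous gain or loss over profile gene indices (inclusive)."""

    chromosome: str
    start_gene_index: int
    end_gene_index: int
    state: str  # "gain" | "loss"
    mean_ratio: float

    def __post_init__(self):
        if self.start_gene_index > self.end_gene_index:
            raise ValueError("event start index exceeds end index")
        if self.state not in ("gain", "loss"):
            raise ValueError(f"bad event state {self.state!r}")
        if self.state == "gain" and self.mean_ratio <= 1:
            raise ValueError("gain event requires mean_ratio > 1")
        if self.state == "loss" and self.mean_ratio >= 1:
            raise ValueError("loss event requires mean_ratio < 1")

    @property
    def n_genes(self) -> int:
        return self.end_gene_index - self.start_gene_index + 1


# ---------------------------------------------------------------------------
# profiler


class CNVProfiler(TransformerMixin, BaseEstimator):
    """Reference-relative expression CNV profiler (sklearn transformer).

    ``fit(X, y)`` takes an observations x genes count array with ``y`` a
    boolean reference mask (stromal/normal observations); gene filtering
    and the depth scale are learned from all of X, the per-gene baseline
    from the reference rows. ``transform(X)`` maps counts to copy ratios
    over the retained, karyotype-ordered genes.

    Parameters
    ----------
    gene_order : sequence of int
        Column indices of X in karyotype order (annotated genes only).
    chromosomes : sequence of str
        Chromosome of each gene in ``gene_order``.
    window : odd int, default 101
        Moving-average width (genes) within each chromosome.
    expr_cutoff : float, default 0.1
        Minimum mean depth-normalized expression to retain a gene.
    max_centered : float, default 1.0
        Symmetric clip for reference-centered log2 residuals.
    denoise_sd : float or None, default 1.5
        After smoothing, residuals within ``denoise_sd`` times the
        reference smoothed-residual SD are set to zero (ratio 1), the
        usual reference-calibrated denoising of expression CNV callers.
        None disables denoising.
    """

    def __init__(self, gene_order=None, chromosomes=None, window=101,
                 expr_cutoff=0.1, max_centered=1.0, denoise_sd=1.5):
        self.gene_order = gene_order
        self.chromosomes = chromosomes
        self.window = window
        self.expr_cutoff = expr_cutoff
        self.max_centered = max_centered
        self.denoise_sd = denoise_sd

    def fit(self, X, y=None):
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be a positive odd integer")
        X = np.asarray(X, dtype=float)
        if y is None:
            raise ValueError("fit requires a boolean reference mask y")
        ref = np.asarray(y, dtype=bool)
        if ref.shape[0] != X.shape[0]:
            raise ValueError("reference mask length does not match observations")
        if not ref.any():
            raise ValueError("empty reference")
        order = np.asarray(self.gene_order, dtype=int)
        chroms = np.asarray(self.chromosomes, dtype=object)
        if order.shape[0] != chroms.shape[0]:
            raise ValueError("gene_order and chromosomes lengths differ")

        depths = X.sum(axis=1)
        if (depths == 0).any():
            raise ValueError("observations with zero total counts")
        self.median_depth_ = float(np.median(depths))
        norm = X * (self.median_depth_ / depths)[:, None]
        keep_all = norm.mean(axis=0) >= self.expr_cutoff
        keep = keep_all[order]
        self.kept_order_ = order[keep]
        self.kept_chromosomes_ = chroms[keep]
        if self.kept_order_.size == 0:
            raise ValueError("no genes survive the expression cutoff")
        sizes = pd.Series(self.kept_chromosomes_).groupby(
            pd.Series(self.kept_chromosomes_)).size()
        if (sizes < self.window).all():
            raise ValueError(
                f"every chromosome has fewer than window={self.window} genes")
        logref = np.log2(1.0 + norm[np.ix_(ref, self.kept_order_)])
        self.reference_mean_ = logref.mean(axis=0)
        # contiguous blocks per chromosome (gene order groups chromosomes)
        self._blocks = []
        start = 0
        for i in range(1, len(self.kept_chromosomes_) + 1):
            if i == len(self.kept_chromosomes_) or self.kept_chromosomes_[i] != self.kept_chromosomes_[start]:
                self._blocks.append((start, i))
                start = i
        # noise scale of the pipeline itself, estimated on the reference
        self.noise_sd_ = float(np.std(self._smoothed(X[ref])))
        return self

    def _smoothed(self, X: np.ndarray) -> np.ndarray:
        """Centered, clipped, chromosome-wise smoothed, re-centered log2
        residuals for raw count rows."""
        depths = X.sum(axis=1)
        if (depths == 0).any():
            raise ValueError("observations with zero total counts")
        norm = X * (self.median_depth_ / depths)[:, None]
        res = np.log2(1.0 + norm[:, self.kept_order_]) - self.reference_mean_[None, :]
        np.clip(res, -self.max_centered, self.max_centered, out=res)
        sm = np.empty_like(res)
        half = self.window // 2
        for a, b in self._blocks:
            block = res[:, a:b]
            c = np.cumsum(block, axis=1)
            c = np.hstack([np.zeros((c.shape[0], 1)), c])
            n = b - a
            lo = np.maximum(np.arange(n) - half, 0)
            hi = np.minimum(np.arange(n) + half + 1, n)
            sm[:, a:b] = (c[:, hi] - c[:, lo]) / (hi - lo)[None, :]
        sm -= np.median(sm, axis=1, keepdims=True)
        return sm

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        sm = self._smoothed(X)
        if self.denoise_sd is not None:
            sm[np.abs(sm) < self.denoise_sd * self.noise_sd_] = 0.0
        return np.power(2.0, sm)


def infer_cnv(
    obs: CountMatrix,
    reference_obs: list[str],
    annotation: pd.DataFrame,
    window: int = 101,
    expr_cutoff: float = 0.1,
    max_centered: float = 1.0,
    denoise_sd: "float | None" = 1.5,
) -> CnvProfile:
    """Copy-ratio profile of all observations relative to a reference.

    ``annotation`` must already be karyotype-sorted (as the annotation
    reader returns it); genes absent from it are ignored.
    """
    if not reference_obs:
        raise ValueError("empty reference")
    missing = set(reference_obs) - set(obs.obs_ids)
    if missing:
        raise ValueError(f"reference observations not in matrix: {sorted(missing)[:5]}")
    gi = {g: i for i, g in enumerate(obs.gene_ids)}
    ann = annotation[annotation["gene_id"].isin(gi)]
    gene_order = [gi[g] for g in ann["gene_id"]]
    chroms = ann["chromosome"].tolist()
    X = obs.dense().T.astype(float)
    ref_mask = np.array([o in set(reference_obs) for o in obs.obs_ids])
    prof = CNVProfiler(
        gene_order=gene_order,
        chromosomes=chroms,
        window=window,
        expr_cutoff=expr_cutoff,
        max_centered=max_centered,
        denoise_sd=denoise_sd,
    ).fit(X, ref_mask)
    ratios = prof.transform(X)
    kept_genes = [obs.gene_ids[i] for i in prof.kept_order_]
    return CnvProfile(
        obs_ids=list(obs.obs_ids),
        gene_ids=kept_genes,
        chromosomes=list(prof.kept_chromosomes_),
        ratios=ratios,
        window=window,
        reference_obs=list(reference_obs),
    )


# ---------------------------------------------------------------------------
# burden and normalization


def cnv_burden(p: CnvProfile) -> CnvScoreMap:
    """Raw burden: 1 + mean absolute deviation of copy ratios from 1.

    The +1 shift makes the (score - 1)/(max - 1) normalization map the
    no-CNV case to exactly 0; losses contribute magnitude like gains.
    """
    raw = 1.0 + np.abs(p.ratios - 1.0).mean(axis=1)
    return CnvScoreMap(raw={o: float(v) for o, v in zip(p.obs_ids, raw)})


def normalize_cnv(scores: CnvScoreMap) -> CnvScoreMap:
    """nCNV_score_i = (CNV_score_i - 1) / (maxCNV_score - 1); all zero
    when the cohort maximum is itself 1 (no CNV anywhere)."""
    if any(v < 1 for v in scores.raw.values()):
        raise ValueError("raw CNV scores must be >= 1")
    max_raw = max(scores.raw.values())
    if max_raw > 1:
        normalized = {o: (v - 1.0) / (max_raw - 1.0) for o, v in scores.raw.items()}
    else:
        normalized = {o: 0.0 for o in scores.raw}
    return CnvScoreMap(raw=dict(scores.raw), normalized=normalized, max_raw=max_raw)


def reclassify_tumor_cells(
    labels: pd.DataFrame,
    scores: CnvScoreMap,
    threshold: float = 0.3,
    eligible_labels: tuple = ("mesothelial", "endothelial"),
) -> pd.DataFrame:
    """Relabel high-burden mesothelial/endothelial cells as tumor.

    A cell flips to "tumor" only when its label is one of
    ``eligible_labels`` and its normalized CNV score strictly exceeds
    ``threshold``; every other label is untouched.
    """
    missing = [o for o in labels["obs_id"] if o not in scores.normalized]
    if missing:
        raise ValueError(f"cells missing a CNV score: {missing[:5]}")
    out = labels.copy()
    flip = out["label"].isin(eligible_labels) & (
        out["obs_id"].map(scores.normalized) > threshold
    )
    out.loc[flip, "label"] = "tumor"
    return out


# ---------------------------------------------------------------------------
# clones


class CloneCaller(ClusterMixin, BaseEstimator):
    """Average-linkage hierarchical clustering of copy-ratio profiles.

    ``n_clones`` may be an integer or "auto", which cuts the dendrogram
    at the largest relative gap in merge heights among cuts 2..
    ``max_auto_clones``; identical profiles collapse to a single clone.
    """

    def __init__(self, n_clones="auto", max_auto_clones=12):
        self.n_clones = n_clones
        self.max_auto_clones = max_auto_clones

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if n < 2:
            raise ValueError("clone calling needs >= 2 observations")
        if self.n_clones != "auto" and self.n_clones > n:
            raise ValueError(f"n_clones={self.n_clones} exceeds {n} observations")
        Z = sch.linkage(X, method="average", metric="euclidean")
        heights = Z[:, 2]
        if self.n_clones == "auto":
            if heights[-1] <= 1e-12:
                self.labels_ = np.zeros(n, dtype=int)
                self.n_clones_ = 1
                return self
            best_k, best_gap = 2, -1.0
            for k in range(2, min(self.max_auto_clones, n) + 1):
                upper = heights[n - k]  # merge that reduces k -> k-1 clusters
                lower = heights[n - k - 1] if n - k - 1 >= 0 else 0.0
                gap = (upper - lower) / upper if upper > 0 else 0.0
                if gap > best_gap + 1e-12:
                    best_k, best_gap = k, gap
            k = best_k
        else:
            k = int(self.n_clones)
        flat = sch.fcluster(Z, t=k, criterion="maxclust")
        # renumber clusters by first occurrence for determinism
        seen: dict[int, int] = {}
        labels = np.empty(n, dtype=int)
        for i, c in enumerate(flat):
            if c not in seen:
                seen[c] = len(seen)
            labels[i] = seen[c]
        self.labels_ = labels
        self.n_clones_ = len(seen)
        return self


def detect_clones(p: CnvProfile, n_clones="auto") -> pd.DataFrame:
    """Cluster non-reference observations into clones.

    Returns a label table: reference observations get clone "normal",
    the rest "clone_1", "clone_2", ... in first-occurrence order.
    """
    qmask = p.query_mask()
    if qmask.sum() < 2:
        raise ValueError("clone detection needs >= 2 non-reference observations")
    caller = CloneCaller(n_clones=n_clones).fit(p.ratios[qmask])
    labels = {}
    qi = 0
    for o, is_q in zip(p.obs_ids, qmask):
        if is_q:
            labels[o] = f"clone_{caller.labels_[qi] + 1}"
            qi += 1
        else:
            labels[o] = "normal"
    return pd.DataFrame({"obs_id": p.obs_ids, "label": [labels[o] for o in p.obs_ids]})


def segment_events(
    p: CnvProfile,
    clones: pd.DataFrame,
    gain_thr: float = 1.05,
    loss_thr: float = 0.95,
    min_genes: int = 20,
) -> dict[str, list[CnvEvent]]:
    """3-state run-length event calls per clone.

    For each clone, genes' mean ratios are scanned within each
    chromosome; maximal runs of at least ``min_genes`` consecutive genes
    all above ``gain_thr`` (or all below ``loss_thr``) become events,
    annotated with the run's mean ratio. The "normal" clone is included
    (and is expected to yield no events on honest references).
    """
    if not loss_thr < 1 < gain_thr:
        raise ValueError("need loss_thr < 1 < gain_thr")
    lab = clones.set_index("obs_id")["label"]
    chrom_arr = np.asarray(p.chromosomes, dtype=object)
    out: dict[str, list[CnvEvent]] = {}
    for clone in pd.unique(lab):
        members = [o for o in p.obs_ids if lab.get(o) == clone]
        idx = [p.obs_ids.index(o) for o in members]
        mean_ratio = p.ratios[idx].mean(axis=0)
        state = np.zeros(len(mean_ratio), dtype=int)
        state[mean_ratio > gain_thr] = 1
        state[mean_ratio < loss_thr] = -1
        events: list[CnvEvent] = []
        i = 0
        n = len(state)
        while i < n:
            s = state[i]
            j = i
            while j + 1 < n and state[j + 1] == s and chrom_arr[j + 1] == chrom_arr[i]:
                j += 1
            if s != 0 and (j - i + 1) >= min_genes:
                events.append(
                    CnvEvent(
                        chromosome=str(chrom_arr[i]),
                        start_gene_index=i,
                        end_gene_index=j,
                        state="gain" if s == 1 else "loss",
                        mean_ratio=float(mean_ratio[i : j + 1].mean()),
                    )
                )
            i = j + 1
        out[str(clone)] = events
    return out


# ---------------------------------------------------------------------------
# clone tree


@dataclass
class CloneTree:
    """Rooted clone phylogeny; edges carry the CNV events acquired there.

    ``graph`` is a networkx DiGraph rooted at "normal"; each edge has an
    ``events`` attribute (tuple of CnvEvent representatives). ``conflict``
    flags inputs whose event sharing was not tree-compatible and was
    resolved greedily in tie-break order.
    """

    graph: nx.DiGraph
    clone_events: dict  # clone -> frozenset of event class keys
    conflict: bool = False

    @property
    def root(self) -> str:
        return "normal"

    def path_events(self, clone: str) -> frozenset:
        """Union of event classes on the root -> clone path."""
        path = nx.shortest_path(self.graph, self.root, clone)
        acc: set = set()
        for a, b in zip(path, path[1:]):
            acc.update(self.graph.edges[a, b]["event_keys"])
        return frozenset(acc)

    def to_newick(self) -> str:
        def fmt(node):
            children = sorted(self.graph.successors(node))
            label = str(node)
            if not children:
                return label
            return "(" + ",".join(fmt(c) for c in children) + ")" + label

        return fmt(self.root) + ";"

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for a, b, data in self.graph.edges(data=True):
            for ev in data["events"]:
                rows.append((a, b, ev.chromosome, ev.start_gene_index,
                             ev.end_gene_index, ev.state, ev.mean_ratio))
            if not data["events"]:
                rows.append((a, b, "", -1, -1, "", np.nan))
        return pd.DataFrame(
            rows,
            columns=["parent", "child", "chromosome", "start_gene_index",
                     "end_gene_index", "state", "mean_ratio"],
        )


def _match_events(events_by_clone: dict) -> tuple[dict, dict]:
    """Group per-clone events into cross-clone classes.

    Two events match when they share chromosome and state and their
    gene-index ranges overlap by at least 50% of the shorter range.
    Returns (clone -> frozenset of class keys, class key -> representative
    event). Class keys are the representative's (chrom, start, end, state).
    """
    reps: list[CnvEvent] = []
    clone_classes: dict[str, set] = {}
    for clone in sorted(events_by_clone):
        keys = set()
        for ev in sorted(
            events_by_clone[clone],
            key=lambda e: (e.chromosome, e.start_gene_index, e.end_gene_index, e.state),
        ):
            matched = None
            for rep in reps:
                if rep.chromosome != ev.chromosome or rep.state != ev.state:
                    continue
                lo = max(rep.start_gene_index, ev.start_gene_index)
                hi = min(rep.end_gene_index, ev.end_gene_index)
                overlap = hi - lo + 1
                shorter = min(rep.n_genes, ev.n_genes)
                if overlap >= 0.5 * shorter:
                    matched = rep
                    break
            if matched is None:
                reps.append(ev)
                matched = ev
            keys.add(
                (matched.chromosome, matched.start_gene_index,
                 matched.end_gene_index, matched.state)
            )
        clone_classes[clone] = frozenset(keys)
    rep_map = {
        (r.chromosome, r.start_gene_index, r.end_gene_index, r.state): r for r in reps
    }
    return clone_classes, rep_map


def build_clone_tree(events_by_clone: dict) -> CloneTree:
    """Greedy perfect-phylogeny over shared CNV events.

    Clones sharing events nest under shared branches: each recursion
    first factors out the events common to every clone in the group onto
    the entering branch, attaches any clone left with no private events
    as the branch's node, then splits the rest by the most widely shared
    remaining event (ties broken by event count descending, chromosome,
    start index). Event sharing that is not tree-compatible (overlapping,
    non-nested supporter sets) is resolved in tie-break order and flagged.
    """
    clones = {c: evs for c, evs in events_by_clone.items() if c != "normal"}
    clone_classes, rep_map = _match_events(clones)
    g = nx.DiGraph()
    g.add_node("normal")
    conflict = [False]
    counter = [0]

    def chrom_key(key):
        chrom = key[0]
        return (0, int(chrom)) if chrom.isdigit() else (1, chrom)

    def attach(parent: str, group: dict):
        """group: clone -> remaining frozenset of event class keys."""
        common = frozenset.intersection(*group.values()) if group else frozenset()
        remaining = {c: ev - common for c, ev in group.items()}
        done = sorted(c for c, ev in remaining.items() if not ev)
        if common or len(group) > 1 or done:
            if done:
                node = done[0]  # clone that IS this ancestral state
                extra_done = done[1:]
            else:
                counter[0] += 1
                node = f"anc_{counter[0]}"
                extra_done = []
            g.add_edge(parent, node,
                       events=tuple(rep_map[k] for k in sorted(common, key=lambda k: (chrom_key(k), k[1]))),
                       event_keys=common)
            for c in extra_done:  # identical siblings (same event set)
                g.add_edge(node, c, events=(), event_keys=frozenset())
            pending = {c: ev for c, ev in remaining.items() if ev}
            while pending:
                # most widely shared remaining event, tie-broken deterministically
                support: dict = {}
                for c, evs in pending.items():
                    for k in evs:
                        support.setdefault(k, set()).add(c)
                best = sorted(
                    support,
                    key=lambda k: (-len(support[k]), chrom_key(k), k[1]),
                )[0]
                S = support[best]
                for k, T in support.items():
                    if T & S and not (T <= S or S <= T):
                        conflict[0] = True
                attach(node, {c: pending[c] for c in sorted(S)})
                for c in S:
                    del pending[c]
        else:
            # single clone with private events only
            ((c, evs),) = group.items()
            g.add_edge(parent, c,
                       events=tuple(rep_map[k] for k in sorted(evs, key=lambda k: (chrom_key(k), k[1]))),
                       event_keys=evs)

    if clones:
        # top level: do NOT factor a global common unless it is truly shared
        pending = dict(clone_classes)
        no_events = sorted(c for c, ev in pending.items() if not ev)
        for c in no_events:
            g.add_edge("normal", c, events=(), event_keys=frozenset())
            del pending[c]
        while pending:
            support: dict = {}
            for c, evs in pending.items():
                for k in evs:
                    support.setdefault(k, set()).add(c)
            best = sorted(
                support, key=lambda k: (-len(support[k]), chrom_key(k), k[1])
            )[0]
            S = support[best]
            for k, T in support.items():
                if T & S and not (T <= S or S <= T):
                    conflict[0] = True
            attach("normal", {c: pending[c] for c in sorted(S)})
            for c in S:
                del pending[c]
    return CloneTree(graph=g, clone_events=clone_classes, conflict=conflict[0])


def link_events_to_gene_sets(
    events_by_clone: dict,
    ordered_gene_ids: list[str],
    sets: GeneSetCollection,
) -> pd.DataFrame:
    """Join every gene inside each event to the gene sets containing it.

    ``ordered_gene_ids`` is the profile's karyotype-ordered gene list the
    event indices refer to. Genes in no set appear once with set "none".
    """
    membership: dict[str, list[str]] = {}
    for name, genes in sets.items():
        for gset_gene in genes:
            membership.setdefault(gset_gene, []).append(name)
    rows = []
    for clone, events in events_by_clone.items():
        for ev in events:
            label = f"{ev.state}:{ev.chromosome}:{ev.start_gene_index}-{ev.end_gene_index}"
            for i in range(ev.start_gene_index, ev.end_gene_index + 1):
                gene_id = ordered_gene_ids[i]
                for set_name in membership.get(gene_id, [None]):
                    rows.append((clone, label, gene_id, set_name))
    return pd.DataFrame(rows, columns=["clone", "event", "gene_id", "set_name"])
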