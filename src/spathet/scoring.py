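"""MIA enrichment, signature scores, tumor score, co-localization.

Multimodal intersection analysis (MIA) tests the overlap between a
spatial cluster's marker genes and a cell type's marker genes against
the hypergeometric upper tail with all genes as background: enrichment
is -log10(p), depletion -log10(1 - p). The tumor score of a spot is the
geometric mean of its normalized CNV burden and its max-min-normalized
tumor-signature score. Co-localization of a cell type with tumor is a
per-section chi-square test on the 2x2 high/low table (dichotomized at
each section's mean, strictly greater = high) with a cell type declared
co-located when at least ``min_sections`` sections reach p < alpha —
the "at least eight of eight samples" rule, generalized to the number
of sections provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .io import ExpressionMatrix

__all__ = [
    "MiaResult",
    "mia",
    "mia_table",
    "signature_score",
    "tumor_score",
    "ColocResult",
    "colocalize",
]

_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-16


@dataclass(frozen=True)
class MiaResult:
    p: float
    enrichment: float  # -log10(p)
    depletion: float  # -log10(1 - p)
    overlap: int


def mia(query_genes: set, type_markers: set, background: set) -> MiaResult:
    """Hypergeometric overlap test of two gene sets over a background.

    ``p = P[X >= k]`` for X ~ Hypergeom(N=|background|, K=|type_markers|,
    n=|query_genes|) with k the observed overlap. p is clamped to
    [1e-300, 1 - 1e-16] before the logs so neither tail is infinite.
    """
    query, markers, bg = set(query_genes), set(type_markers), set(background)
    if not bg:
        raise ValueError("background is empty")
    if not query <= bg or not markers <= bg:
        raise ValueError("query and marker sets must be contained in the background")
    k = len(query & markers)
    N, K, n = len(bg), len(markers), len(query)
    p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, _P_FLOOR), _P_CEIL)
    return MiaResult(
        p=p,
        enrichment=float(-np.log10(p)),
        depletion=float(-np.log10(1.0 - p)),
        overlap=k,
    )


def mia_table(
    cluster_markers: dict,
    celltype_markers: dict,
    background: set,
) -> pd.DataFrame:
    """MIA over every (cluster, cell type) pair; long-format table."""
    rows = []
    for cluster, cg in cluster_markers.items():
        for ct, mg in celltype_markers.items():
            r = mia(set(cg) & background, set(mg) & background, background)
            rows.append((cluster, ct, r.overlap, r.p, r.enrichment, r.depletion))
    return pd.DataFrame(
        rows,
        columns=["cluster", "cell_type", "overlap", "p", "enrichment", "depletion"],
    )


def signature_score(
    em: ExpressionMatrix,
    genes: list[str],
    spots: pd.DataFrame,
) -> pd.DataFrame:
    """Mean signature expression per spot, max-min normalized per section.

    ``raw`` is the mean normalized expression over the signature genes
    present in the matrix; ``normalized`` rescales raw to [0, 1] within
    each section (a constant section maps to all zeros). Returns a frame
    (obs_id, section_id, raw, normalized).
    """
    present = [g for g in genes if g in set(em.gene_ids)]
    if not present:
        raise ValueError("no signature gene present in the matrix")
    sub = em.subset_genes(present)
    raw = pd.Series(sub.values.mean(axis=0), index=em.obs_ids, name="raw")
    df = spots[["obs_id", "section_id"]].copy()
    missing = [o for o in df["obs_id"] if o not in raw.index]
    if missing:
        raise ValueError(f"spots missing from the expression matrix: {missing[:5]}")
    df["raw"] = df["obs_id"].map(raw)

    def _minmax(s: pd.Series) -> pd.Series:
        lo, hi = s.min(), s.max()
        if hi == lo:
            return pd.Series(np.zeros(len(s)), index=s.index)
        return (s - lo) / (hi - lo)

    df["normalized"] = df.groupby("section_id")["raw"].transform(_minmax)
    return df


def tumor_score(ncnv: dict, nsig: dict) -> dict:
    """Geometric mean of normalized CNV and signature scores per spot.

    ``score_i = sqrt(nCNV_i * nSig_i)``; zero whenever either factor is
    zero. Both maps must cover the same observations.
    """
    only_cnv = sorted(set(ncnv) - set(nsig))
    only_sig = sorted(set(nsig) - set(ncnv))
    if only_cnv or only_sig:
        raise ValueError(
            f"score maps cover different observations; "
            f"cnv-only={only_cnv[:5]} sig-only={only_sig[:5]}"
        )
    out = {}
    for o, a in ncnv.items():
        b = nsig[o]
        if a < 0 or b < 0:
            raise ValueError(f"negative normalized score for {o}")
        out[o] = float(np.sqrt(a * b))
    return out


@dataclass
class ColocResult:
    """Per-section chi-square co-localization of one cell type with tumor."""

    cell_type: str
    sections: pd.DataFrame  # section_id, chi2, p, a, b, c, d, skipped
    n_significant: int
    colocalized: bool
    alpha: float
    min_sections: int


def colocalize(
    tumor: dict,
    celltype: dict,
    spots: pd.DataFrame,
    alpha: float = 0.05,
    min_sections: "int | None" = None,
    cell_type: str = "",
) -> ColocResult:
    """Chi-square high/low co-localization across sections.

    Per section both scores are dichotomized at that section's arithmetic
    mean (strictly greater = high) and a Pearson chi-square without
    continuity correction is run on the 2x2 table. Sections with a
    degenerate margin (all-high or all-low on either score) are skipped
    and flagged, never counted as significant. The type is co-localized
    when at least ``min_sections`` sections (default: all of them) reach
    p < alpha.
    """
    if spots.empty:
        raise ValueError("no spots provided")
    missing = [o for o in spots["obs_id"] if o not in tumor or o not in celltype]
    if missing:
        raise ValueError(f"spots missing a score: {missing[:5]}")
    section_ids = list(pd.unique(spots["section_id"]))
    if min_sections is None:
        min_sections = len(section_ids)
    rows = []
    n_sig = 0
    for sec in section_ids:
        obs = spots.loc[spots["section_id"] == sec, "obs_id"].tolist()
        t = np.array([tumor[o] for o in obs], dtype=float)
        c = np.array([celltype[o] for o in obs], dtype=float)
        t_high = t > t.mean()
        c_high = c > c.mean()
        a = int((t_high & c_high).sum())
        b = int((t_high & ~c_high).sum())
        cc = int((~t_high & c_high).sum())
        d = int((~t_high & ~c_high).sum())
        table = np.array([[a, b], [cc, d]])
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            rows.append((sec, np.nan, np.nan, a, b, cc, d, True))
            continue
        chi2, p, _, _ = scipy.stats.chi2_contingency(table, correction=False)
        sig = p < alpha
        n_sig += int(sig)
        rows.append((sec, float(chi2), float(p), a, b, cc, d, False))
    sections = pd.DataFrame(
        rows, columns=["section_id", "chi2", "p", "a", "b", "c", "d", "skipped"]
    )
    return ColocResult(
        cell_type=cell_type,
        sections=sections,
        n_significant=n_sig,
        colocalized=n_sig >= min_sections,
        alpha=alpha,
        min_sections=min_sections,
    )
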