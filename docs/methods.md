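# Methods

This note documents the models and procedures spathet implements, the
parameters that matter, what the synthetic cohorts do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Expression-inferred copy number

Copy ratios are inferred from expression relative to a reference of
presumed-diploid observations (stromal spots, or non-epithelial cell
types on the dissociated side). The profiler (`CNVProfiler`,
`infer_cnv`) proceeds:

1. depth-normalize every observation to the cohort's median total count;
2. drop genes whose mean normalized expression across all observations
   is below `expr_cutoff` (default 0.1 counts);
3. take log2(1 + x) and subtract the per-gene reference mean;
4. clip residuals to ±`max_centered` (default 1.0 on the log2 scale);
5. order genes along the karyotype (chromosomes 1..22, X by start
   position) and smooth each observation with a centered moving average
   of `window` genes (default 101, truncated at chromosome ends) within
   each chromosome;
6. re-center each observation at its median smoothed residual;
7. zero residuals smaller in magnitude than `denoise_sd` (default 1.5)
   times the reference smoothed-residual SD — the usual
   reference-calibrated denoising of expression CNV callers, estimated
   at fit time by pushing the reference itself through steps 1–6;
8. exponentiate to copy ratios centered at 1.

The denoising step matters: counts are overdispersed, and after a
101-gene moving average the residual noise SD is still roughly 0.08 log2
units, which would otherwise put an apparent ~4% burden on honest
reference spots. With denoising the bulk (~87%, the Gaussian mass within
1.5 SD) of a null profile is exactly diploid; individual tail ratios can
still reach ~0.8/1.25, so downstream callers aggregate (burden averages,
run-length segmentation) rather than trusting single genes.

Known artifact, shared with reference-based CNV inference generally:
genes differentially expressed between the query and reference cell
types (e.g. tumor marker genes when the reference is stromal) masquerade
as copy-ratio shifts where they clump along the genome. This is the same
mechanism the real workflow exploits when it reclassifies
CNV-high "normal" cells as tumor; it also means clone calls on mixed
tumor/stroma cohorts can pick up spurious low-amplitude events.

## Burden, nCNV and the reclassification rule

Per-observation burden is `CNV_score_i = 1 + mean_g |ratio_ig − 1|`: the
mean absolute deviation of copy ratios from diploid, shifted so the
normalization below maps a no-CNV observation to exactly 0. Losses
contribute magnitude, like gains. Normalization is

    nCNV_score_i = (CNV_score_i − 1) / (maxCNV_score − 1)

with all scores defined as 0 when the cohort maximum is itself 1. The
normalized score is relative to the worst observation in the cohort, so
it is comparable within a run, not across runs.

Dissociated cells labeled mesothelial or endothelial whose
`nCNV` strictly exceeds 0.3 are relabeled tumor (`reclassify_tumor_cells`);
all other labels are untouched. The boundary is strict ("exceeding"):
exactly 0.3 does not flip.

## Clones, events, tree

Clone detection (`CloneCaller`) is average-linkage hierarchical
clustering of the copy-ratio rows (Euclidean distance). With
`n_clones="auto"` the dendrogram is cut at the largest relative gap in
merge heights among cuts 2..12; identical profiles collapse to one
clone. Reference observations are assigned the clone "normal".

Events (`segment_events`) are maximal runs of at least `min_genes`
(default 20) consecutive genes within one chromosome whose clone-mean
ratio is all above `gain_thr` (1.05) or all below `loss_thr` (0.95) —
a deliberate 3-state simplification of HMM-based callers: deterministic,
desk-scale, and sufficient for chromosome-scale events.

The clone tree (`build_clone_tree`) is a greedy perfect phylogeny:
events are first matched across clones (same chromosome and state,
gene-index overlap ≥ 50% of the shorter event); each recursion factors
the events common to the whole group onto the entering branch, lets a
clone with no remaining private events *be* the ancestral node, and
splits the rest by the most widely shared remaining event (ties: event
count descending, chromosome, start index). Event sharing that is not
tree-compatible is resolved in tie-break order and flagged on the tree
(`conflict=True`) rather than rejected. By construction the union of
edge labels on any clone's root path equals its called event set.

## MIA, signature scores, tumor score, co-localization

MIA: for an ST cluster's marker set and a cell type's marker set over
the all-genes background, `p = P[X ≥ k]` under
Hypergeometric(N=|background|, K=|type markers|, n=|cluster markers|).
Enrichment is −log10 p and depletion −log10(1 − p); p is clamped to
[1e−300, 1 − 1e−16] first, capping the two logs at 300 and 16 — without
the clamp a saturated overlap yields infinite enrichment.

Signature scores are the mean normalized (log1p) expression of a gene
set per spot, max–min normalized within each section (a constant
section maps to zeros). The tumor score is the geometric mean
`sqrt(nCNV · nSig)`, which is zero when either factor is zero and lies
between the two factors otherwise.

Co-localization dichotomizes both scores at each section's arithmetic
mean (strictly greater = high) and tests the 2×2 table with Pearson's
chi-square, no continuity correction — the uncorrected statistic has the
closed form n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) used as an independent
oracle in the tests. Sections with a degenerate margin are skipped and
flagged, never counted as significant. A type co-localizes when at
least `min_sections` sections reach p < alpha; the default requires
every section, which for an 8-sample cohort is the 8-of-8 rule.
Dichotomizing at the mean makes the test invariant to affine transforms
of the scores but not to general monotone transforms.

## Programs and meta-programs

Per tumor sample, the normalized (log1p, non-negative) expression of
tumor observations restricted to that sample's HVGs is factorized with
NMF (nndsvda initialization, coordinate descent, tol 1e−4, max 500
iterations; deterministic given seed). The rank is swept 2..6 and chosen
as the smallest k whose relative Frobenius-error improvement to k+1
falls below 5% — an operationalization of "the point just before a
significant drop"; which quantity drops in such protocols is usually
unstated, and reconstruction error is the deterministic choice.

Each factor's top 50 genes by weight (ties: lexicographic gene id) form
an intratumor program. Programs from all samples are clustered by
average linkage on 1 − Jaccard and cut at distance 0.8 (i.e. programs
with Jaccard ≥ ~0.2 can co-cluster; no cut height is standard, and 0.8
reproduces the intended sharing behavior on planted-overlap structure).
Clusters spanning ≥ 2 samples become meta-programs; the signature keeps
genes occurring in programs from at least ceil(share_fraction ×
contributing samples) distinct samples, share_fraction = 1/3, with
ceiling so a 5-sample meta-program needs ≥ 2 samples per gene.

## Synthetic cohorts

`generate_cohort` emulates the paired design: several sections of spots
on a jittered grid plus a dissociated cell set. Counts are negative
binomial with mean `mu_g · f_type · f_clone · f_program` and a single
shared dispersion of 0.3; `mu_g` is lognormal around `baseline_mean`
(default 3.0 counts/gene, ~6k total counts per spot on a 2,000-gene
panel — typical spot-level depth; much shallower settings compress CNV
folds below detectability in log space). Cell types get disjoint marker
blocks with a fold (default 4); clones apply event folds (loss = divide)
over chromosome prefixes and occupy contiguous circular patches of the
tumor region, children carrying all parental events; programs multiply
their gene block in a Bernoulli-chosen subset of tumor observations of
active samples; 13 genes named `MT-*` are scaled to a per-observation
mitochondrial fraction. Everything derives from one seed
(byte-identical reruns), and the generative means are known exactly, so
recovery tests compare against closed-form expectations.

Not emulated: spatial autocorrelation of stroma, cell doublets, ambient
RNA, batch effects between sections, and realistic per-chromosome gene
counts (genes are spread evenly over a configurable chromosome subset).
Passing recovery tests therefore shows the algorithms recover the
planted generative structure at realistic depth and dispersion — not
that they are robust to every artifact of real tissue.

## Fixture scales

Tests and the acceptance script size their cohorts to isolate each
stage: CNV fixtures use 1,200 genes over chromosomes 1–5 (~235
genes/chromosome, comfortably above the 101-gene smoothing window) with
300 spots/section and clone prevalences 0.5/0.5; the program fixtures
use five 300-spot samples, three 50-gene programs at activity fold 8
("well-separated") active in four of five samples; QC boundary checks
use a purpose-built 500-spot matrix pinning detected-gene counts at
399/400, 199/200/201, 4000/4001 and mitochondrial fractions at
0.1299/0.13/0.1301. The full pipeline demo runs 3 × 400 spots, 1,500
cells and 2,000 genes over 10 chromosomes in well under a minute.

## Defaults at a glance

| parameter | default | meaning |
|---|---|---|
| `expr_cutoff` | 0.1 | min mean normalized expression to keep a gene (CNV) |
| `window` | 101 genes | within-chromosome smoothing width (odd) |
| `max_centered` | 1.0 | clip for centered log2 residuals |
| `denoise_sd` | 1.5 | reference-SD multiplier below which residuals are zeroed |
| `gain_thr` / `loss_thr` | 1.05 / 0.95 | event-calling ratio thresholds |
| `min_event_genes` | 20 | min run length for an event |
| `reclass_threshold` | 0.3 | strict nCNV bound for tumor reclassification |
| QC `geo` | ≥ 400 genes | detected-gene floor |
| QC `proprietary` | 200–4,000 genes, mito < 13% | band plus strict mito bound |
| `n_hvgs` / `n_pcs` / k | 2000 / 20 / 15 | clustering plumbing |
| marker thresholds | adj. p < 0.05, log2FC > 0.25 | Wilcoxon + BH |
| `min_overlap` | 5 | marker∩signature floor for cluster classification |
| `alpha` / `min_sections` | 0.05 / all | co-localization rule |
| `rank_min..rank_max` | 2..6 | NMF rank sweep |
| `top_n` | 50 | program size |
| `cut` | 0.8 | dendrogram cut on 1 − Jaccard |
| `share_fraction` | 1/3 | meta-program signature floor (ceiling) |
| NB dispersion | 0.3 | generator overdispersion (shared) |

## Limitations

* Copy ratios are expression proxies: no allele-specific or integer copy
  number, and cell-type expression differences leak into profiles (see
  above). Clone calls on mixed cohorts should be read jointly with the
  cluster classification.
* nCNV is cohort-relative; comparing nCNV across separately normalized
  runs is not meaningful.
* The clone tree assumes events are persistent (no reversions); true
  convergent events in distinct lineages surface as the `conflict` flag.
* Rank selection by error elbow is a stand-in for unstated protocol
  detail; on weakly separated programs it is conservative (chooses the
  smaller rank).
* The chi-square co-localization treats spots as independent; spatial
  autocorrelation would inflate significance on real sections.
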