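"""Synthetic multi-section spatial cohort with planted ground truth.

Emulates the structure of a multi-patient high-grade serous ovarian
carcinoma study: several spatial-transcriptomics sections of spots with
2D coordinates plus a matched dissociated cell set with cell-type labels.
Planted structure covers everything the downstream pipeline estimates:

* chromosome-scale CNV clones (fold multipliers over contiguous gene
  blocks, nested along a clonal ancestry) occupying spatially coherent
  circular patches of tumor spots;
* cell-type marker signatures (disjoint marker gene blocks with an
  expression fold in observations of that type);
* co-expressed gene programs active in a subset of "samples" (sections),
  switching on per tumor observation;
* mitochondrial content via 13 genes named ``MT-*`` scaled to a
  per-observation target fraction.

Counts are negative binomial with mean
``mu_g * f_type * f_clone * f_program`` and a single shared dispersion,
so every marginal mean is known in closed form and recovery tests can be
checked against the generative model directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._utils import KARYOTYPE
from .io import CountMatrix, GeneSetCollection, sort_annotation

__all__ = [
    "CellTypeSpec",
    "CloneSpec",
    "ProgramSpec",
    "CohortConfig",
    "GroundTruth",
    "SyntheticCohort",
    "generate_cohort",
]

N_MITO_GENES = 13


@dataclass(frozen=True)
class CellTypeSpec:
    name: str
    n_marker_genes: int
    marker_fold: float

    def __post_init__(self):
        if self.n_marker_genes <= 0:
            raise ValueError("n_marker_genes must be positive")
        if self.marker_fold <= 1:
            raise ValueError("marker_fold must exceed 1")


@dataclass(frozen=True)
class CloneSpec:
    """A tumor clone: CNV events plus spatial prevalence.

    ``events`` are (chromosome, fraction_of_chromosome, direction, fold)
    tuples; the event covers the first ``fraction`` of the chromosome's
    genes in position order. ``fold`` > 1 always; a loss divides the mean
    by ``fold``. A child clone carries every parental event in addition
    to its own. ``sections=None`` means the clone occurs in every section
    and in the dissociated cell set.
    """

    clone_id: str
    parent_id: "str | None"
    events: tuple  # of (chrom, fraction, direction, fold)
    prevalence: float
    sections: "tuple[str, ...] | None" = None

    def __post_init__(self):
        if not 0 < self.prevalence <= 1:
            raise ValueError("prevalence must be in (0, 1]")
        for chrom, frac, direction, fold in self.events:
            if direction not in ("gain", "loss"):
                raise ValueError(f"bad event direction {direction!r}")
            if not 0 < frac <= 1:
                raise ValueError("event fraction must be in (0, 1]")
            if fold <= 1:
                raise ValueError("event fold must exceed 1")


@dataclass(frozen=True)
class ProgramSpec:
    """A co-expressed gene module active in a subset of samples."""

    program_id: str
    gene_ids: tuple
    active_samples: "tuple[str, ...] | None"
    activity_fold: float = 3.0
    active_fraction: float = 0.5  # P(a tumor obs in an active sample expresses it)

    def __post_init__(self):
        if len(self.gene_ids) < 50:
            raise ValueError("program needs >= 50 genes so top-50 extraction is well-posed")
        if self.activity_fold <= 1:
            raise ValueError("activity_fold must exceed 1")


@dataclass(frozen=True)
class CohortConfig:
    n_sections: int = 3
    spots_per_section: int = 400
    n_cells: int = 1500
    n_genes: int = 2000
    cell_types: tuple = (
        CellTypeSpec("tumor", 100, 4.0),
        CellTypeSpec("fibroblast", 80, 4.0),
        CellTypeSpec("macrophage", 80, 4.0),
        CellTypeSpec("endothelial", 60, 4.0),
        CellTypeSpec("mesothelial", 60, 4.0),
    )
    clones: tuple = ()
    programs: tuple = ()
    baseline_mean: float = 3.0
    mito_fraction_range: tuple = (0.02, 0.10)
    tumor_spot_fraction: float = 0.5
    dispersion: float = 0.3
    chromosomes: tuple = KARYOTYPE
    seed: int = 0

    def __post_init__(self):
        for name, v in (
            ("n_sections", self.n_sections),
            ("spots_per_section", self.spots_per_section),
            ("n_cells", self.n_cells),
            ("n_genes", self.n_genes),
        ):
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_genes < N_MITO_GENES + sum(t.n_marker_genes for t in self.cell_types):
            raise ValueError("n_genes too small for mito + marker gene blocks")
        lo, hi = self.mito_fraction_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("mito_fraction_range must satisfy 0 <= lo <= hi < 1")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean and dispersion must be positive")
        if not 0 < self.tumor_spot_fraction <= 1:
            raise ValueError("tumor_spot_fraction must be in (0, 1]")

    @property
    def section_ids(self) -> list[str]:
        return [f"section_{i + 1}" for i in range(self.n_sections)]


@dataclass
class GroundTruth:
    """Planted truth for every downstream stage."""

    obs_cell_type: dict  # obs_id -> cell type name
    spot_clone: dict  # obs_id -> clone_id or "none" (tumor without clone) / "normal"
    gene_programs: dict  # gene_id -> tuple of program ids
    gene_marker_of: dict  # gene_id -> cell type name (markers only)
    clone_events: dict  # clone_id -> tuple of effective (chrom, fraction, direction, fold)
    obs_active_programs: dict  # obs_id -> tuple of program ids switched on
    marker_sets: GeneSetCollection  # cell type -> marker genes
    program_sets: GeneSetCollection  # program -> genes


@dataclass
class SyntheticCohort:
    sections: list  # of (CountMatrix, spots DataFrame)
    cells: tuple  # (CountMatrix, labels DataFrame)
    annotation: pd.DataFrame
    truth: GroundTruth
    config: CohortConfig


def _effective_events(clones) -> dict:
    """Accumulate each clone's events up its ancestry chain."""
    by_id = {c.clone_id: c for c in clones}
    if len(by_id) != len(clones):
        raise ValueError("duplicate clone ids")
    out = {}

    def resolve(cid, seen=()):
        if cid in seen:
            raise ValueError(f"clone ancestry cycle at {cid}")
        c = by_id[cid]
        own = list(c.events)
        if c.parent_id is None:
            return own
        if c.parent_id not in by_id:
            raise ValueError(f"clone {cid} names unknown parent {c.parent_id}")
        return resolve(c.parent_id, seen + (cid,)) + own

    for cid in by_id:
        out[cid] = tuple(resolve(cid))
    return out


def _gene_table(config: CohortConfig) -> pd.DataFrame:
    """Gene ids, chromosomes and positions. MT genes sit on 'MT' (dropped
    from the karyotype annotation); nuclear genes fill consecutive blocks
    per chromosome in karyotype order."""
    n_nuclear = config.n_genes - N_MITO_GENES
    chroms = list(config.chromosomes)
    per = [n_nuclear // len(chroms)] * len(chroms)
    for i in range(n_nuclear - sum(per)):
        per[i] += 1
    rows = []
    g = 0
    for chrom, k in zip(chroms, per):
        for j in range(k):
            g += 1
            start = (j + 1) * 100_000
            rows.append((f"G{g:05d}", chrom, start, start + 1_000))
    for m in range(1, N_MITO_GENES + 1):
        rows.append((f"MT-{m}", "MT", m * 1_000, m * 1_000 + 500))
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"])


def _clone_patch_assign(rng, coords, tumor_idx, clones_here, truth_clone, obs_ids):
    """Assign clones to contiguous circular patches of tumor spots."""
    unassigned = list(tumor_idx)
    for clone in clones_here:
        if not unassigned:
            break
        n_take = min(len(unassigned), int(round(clone.prevalence * len(tumor_idx))))
        if n_take == 0:
            continue
        center = coords[unassigned[int(rng.integers(len(unassigned)))]]
        d = np.linalg.norm(coords[unassigned] - center, axis=1)
        order = np.argsort(d, kind="stable")[:n_take]
        taken = [unassigned[i] for i in order]
        for i in taken:
            truth_clone[obs_ids[i]] = clone.clone_id
        unassigned = [i for i in unassigned if i not in set(taken)]
    for i in unassigned:
        truth_clone[obs_ids[i]] = "none"


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the cohort. Deterministic: same config + seed, same bytes."""
    rng = np.random.default_rng(config.seed)
    genes = _gene_table(config)
    gene_ids = genes["gene_id"].tolist()
    n_genes = len(gene_ids)
    is_mito = genes["chromosome"].eq("MT").to_numpy()

    # per-section clone prevalence check
    events_by_clone = _effective_events(config.clones)
    for sec in config.section_ids + ["cells"]:
        tot = sum(
            c.prevalence for c in config.clones if c.sections is None or sec in c.sections
        )
        if tot > 1 + 1e-9:
            raise ValueError(f"clone prevalences exceed 1 in {sec}")

    # baseline means: lognormal around baseline_mean, E[mu_g] = baseline_mean
    mu = config.baseline_mean * rng.lognormal(mean=-0.5, sigma=1.0, size=n_genes)

    # marker blocks: disjoint, drawn from nuclear genes in shuffled order
    nuclear = np.flatnonzero(~is_mito)
    shuffled = nuclear[rng.permutation(len(nuclear))]
    marker_idx: dict[str, np.ndarray] = {}
    cursor = 0
    gene_marker_of: dict[str, str] = {}
    for ct in config.cell_types:
        idx = shuffled[cursor : cursor + ct.n_marker_genes]
        cursor += ct.n_marker_genes
        marker_idx[ct.name] = idx
        for i in idx:
            gene_marker_of[gene_ids[i]] = ct.name

    # program gene indices (may overlap markers and each other)
    gid_pos = {g: i for i, g in enumerate(gene_ids)}
    prog_idx = {}
    gene_programs: dict[str, list] = {}
    for p in config.programs:
        missing = [g for g in p.gene_ids if g not in gid_pos]
        if missing:
            raise ValueError(f"program {p.program_id} names unknown genes: {missing[:5]}")
        prog_idx[p.program_id] = np.array([gid_pos[g] for g in p.gene_ids])
        for g in p.gene_ids:
            gene_programs.setdefault(g, []).append(p.program_id)

    # event gene blocks per chromosome prefix
    chrom_genes = {c: np.flatnonzero(genes["chromosome"].eq(c).to_numpy()) for c in config.chromosomes}

    def event_genes(chrom, frac):
        idx = chrom_genes.get(str(chrom))
        if idx is None or len(idx) == 0:
            raise ValueError(f"event on chromosome {chrom} with no genes")
        return idx[: max(1, int(round(frac * len(idx))))]

    type_names = [t.name for t in config.cell_types]
    stromal_types = [t for t in type_names if t != "tumor"]

    truth_type: dict[str, str] = {}
    truth_clone: dict[str, str] = {}
    obs_active: dict[str, tuple] = {}

    def sample_obs_block(obs_ids, sample_id, coords, is_spatial):
        """Build the mean matrix for one block of observations, then draw counts."""
        n_obs = len(obs_ids)
        M = np.tile(mu[:, None], (1, n_obs))

        # cell types: spatial blocks for sections, random for cells
        if is_spatial and "tumor" in type_names and config.tumor_spot_fraction < 1:
            center = coords.mean(axis=0)
            d = np.linalg.norm(coords - center, axis=1)
            r = np.quantile(d, config.tumor_spot_fraction)
            tumor_mask = d <= r
        else:
            tumor_mask = rng.random(n_obs) < (
                config.tumor_spot_fraction if "tumor" in type_names else 0.0
            )
        types = np.empty(n_obs, dtype=object)
        types[tumor_mask] = "tumor"
        n_other = int((~tumor_mask).sum())
        if stromal_types:
            types[~tumor_mask] = rng.choice(stromal_types, size=n_other)
        else:
            types[~tumor_mask] = type_names[0] if type_names else "tumor"
        for ct in config.cell_types:
            mask = types == ct.name
            if mask.any():
                M[np.ix_(marker_idx[ct.name], mask)] *= ct.marker_fold
        for o, t in zip(obs_ids, types):
            truth_type[o] = str(t)

        # clones occupy contiguous patches of tumor obs (spatial) or random
        tumor_idx = np.flatnonzero(types == "tumor")
        clones_here = [
            c for c in config.clones if c.sections is None or sample_id in c.sections
        ]
        if is_spatial:
            _clone_patch_assign(rng, coords, tumor_idx, clones_here, truth_clone, obs_ids)
        else:
            unassigned = list(tumor_idx)
            for clone in clones_here:
                n_take = min(len(unassigned), int(round(clone.prevalence * len(tumor_idx))))
                take = [unassigned[i] for i in rng.permutation(len(unassigned))[:n_take]]
                for i in take:
                    truth_clone[obs_ids[i]] = clone.clone_id
                unassigned = [i for i in unassigned if i not in set(take)]
            for i in unassigned:
                truth_clone[obs_ids[i]] = "none"
        for i in np.flatnonzero(types != "tumor"):
            truth_clone[obs_ids[i]] = "normal"

        # apply clone event folds
        for clone in clones_here:
            cols = np.array(
                [j for j, o in enumerate(obs_ids) if truth_clone[o] == clone.clone_id],
                dtype=int,
            )
            if cols.size == 0:
                continue
            for chrom, frac, direction, fold in events_by_clone[clone.clone_id]:
                gidx = event_genes(chrom, frac)
                f = fold if direction == "gain" else 1.0 / fold
                M[np.ix_(gidx, cols)] *= f

        # programs switch on per tumor observation in active samples
        for p in config.programs:
            if p.active_samples is not None and sample_id not in p.active_samples:
                continue
            on = (types == "tumor") & (rng.random(n_obs) < p.active_fraction)
            if on.any():
                M[np.ix_(prog_idx[p.program_id], on)] *= p.activity_fold
            for j in np.flatnonzero(on):
                obs_active.setdefault(obs_ids[j], [])
                obs_active[obs_ids[j]].append(p.program_id)

        # mitochondrial content: scale MT gene means to a target fraction
        target = rng.uniform(*config.mito_fraction_range, size=n_obs)
        non_mt_total = M[~is_mito].sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            mt_total = np.where(target < 1, target / (1 - target), 0.0) * non_mt_total
        M[is_mito] = mt_total / N_MITO_GENES

        # negative binomial draw: var = m + dispersion * m^2
        r = 1.0 / config.dispersion
        pmat = r / (r + M)
        counts = rng.negative_binomial(r, pmat)
        return counts.astype(np.int64), types

    sections = []
    for s, sec_id in enumerate(config.section_ids):
        n = config.spots_per_section
        side = int(math.ceil(math.sqrt(n)))
        gx, gy = np.meshgrid(np.arange(side), np.arange(side))
        coords = np.column_stack([gx.ravel(), gy.ravel()])[:n].astype(float)
        coords += rng.uniform(-0.2, 0.2, size=coords.shape)
        obs_ids = [f"{sec_id}:spot_{i + 1}" for i in range(n)]
        counts, _ = sample_obs_block(obs_ids, sec_id, coords, is_spatial=True)
        cm = CountMatrix(counts, gene_ids, obs_ids)
        spots = pd.DataFrame(
            {
                "obs_id": obs_ids,
                "section_id": sec_id,
                "x": coords[:, 0],
                "y": coords[:, 1],
            }
        )
        sections.append((cm, spots))

    cell_ids = [f"cells:cell_{i + 1}" for i in range(config.n_cells)]
    cell_counts, cell_types = sample_obs_block(
        cell_ids, "cells", np.zeros((config.n_cells, 2)), is_spatial=False
    )
    cells_cm = CountMatrix(cell_counts, gene_ids, cell_ids)
    cell_labels = pd.DataFrame({"obs_id": cell_ids, "label": [str(t) for t in cell_types]})

    annotation = sort_annotation(genes[genes["chromosome"].isin(KARYOTYPE)].copy())

    marker_sets = GeneSetCollection(
        {ct.name: [gene_ids[i] for i in marker_idx[ct.name]] for ct in config.cell_types}
    )
    program_sets = GeneSetCollection(
        {p.program_id: list(p.gene_ids) for p in config.programs}
    ) if config.programs else GeneSetCollection()

    truth = GroundTruth(
        obs_cell_type=truth_type,
        spot_clone=truth_clone,
        gene_programs={g: tuple(v) for g, v in gene_programs.items()},
        gene_marker_of=gene_marker_of,
        clone_events=events_by_clone,
        obs_active_programs={o: tuple(v) for o, v in obs_active.items()},
        marker_sets=marker_sets,
        program_sets=program_sets,
    )
    return SyntheticCohort(sections, (cells_cm, cell_labels), annotation, truth, config)
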