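"""Pipeline orchestration: config parsing, staged run, manifest.

Stages run as simulate (optional) -> qc -> cluster -> markers ->
classify -> cnv -> clones -> tree -> mia -> tumorscore -> coloc ->
programs. Every stage reads its inputs from files written by earlier
stages and writes its outputs (plain-text TSV/GMT/Newick/JSON) before
the next stage starts, so any stage can be re-run standalone from a
prior run's output directory. A JSON manifest records each stage's
parameters and the SHA-256 of every file it wrote.

All randomness flows from the single config seed via stage-name-salted
derived seeds. The config file is flat ``key = value`` text; unknown
keys are rejected and every numeric parameter is range-checked before
any stage runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnv as cnvmod
from . import io as spio
from . import programs as progmod
from . import qc as qcmod
from . import scoring as scmod
from ._utils import KARYOTYPE, logger, stage_seed
from .simulate import CloneSpec, CohortConfig, ProgramSpec, generate_cohort

__all__ = ["PipelineConfig", "validate_config", "run_all", "run_stage", "STAGES"]

STAGES = [
    "simulate", "qc", "cluster", "markers", "classify", "cnv",
    "clones", "tree", "mia", "tumorscore", "coloc", "programs",
]


@dataclass
class PipelineConfig:
    # paths
    data_dir: str = ""  # empty: the simulate stage generates a cohort
    out_dir: str = "spathet_out"
    # simulate scale
    n_sections: int = 3
    spots_per_section: int = 400
    n_cells: int = 1500
    n_genes: int = 2000
    n_chromosomes: int = 10
    # qc / clustering
    qc_preset: str = "geo"
    n_hvgs: int = 2000
    n_pcs: int = 20
    resolution: float = 1.0
    min_overlap: int = 5
    # cnv
    window: int = 101
    expr_cutoff: float = 0.1
    max_centered: float = 1.0
    gain_thr: float = 1.05
    loss_thr: float = 0.95
    min_event_genes: int = 20
    n_clones: str = "auto"
    reclass_threshold: float = 0.3
    # scoring
    alpha: float = 0.05
    min_sections: int = 0  # 0: require every section
    # programs
    rank_min: int = 2
    rank_max: int = 6
    top_n: int = 50
    cut: float = 0.8
    share_fraction: float = 1.0 / 3.0
    program_hvgs: int = 500
    # global
    seed: int = 0

    def __post_init__(self):
        if self.qc_preset not in qcmod.QC_PRESETS:
            raise ValueError(f"qc_preset must be one of {sorted(qcmod.QC_PRESETS)}")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.share_fraction <= 1:
            raise ValueError("share_fraction must be in (0, 1]")
        if not 0 < self.cut <= 1:
            raise ValueError("cut must be in (0, 1]")
        if not 2 <= self.rank_min < self.rank_max:
            raise ValueError("need 2 <= rank_min < rank_max")
        if self.top_n <= 0:
            raise ValueError("top_n must be positive")
        if not self.loss_thr < 1 < self.gain_thr:
            raise ValueError("need loss_thr < 1 < gain_thr")
        if not 0 <= self.reclass_threshold <= 1:
            raise ValueError("reclass_threshold must be in [0, 1]")
        if self.n_clones != "auto":
            if not str(self.n_clones).isdigit() or int(self.n_clones) < 1:
                raise ValueError("n_clones must be 'auto' or a positive integer")
        if not 1 <= self.n_chromosomes <= len(KARYOTYPE):
            raise ValueError(f"n_chromosomes must be in 1..{len(KARYOTYPE)}")
        if self.min_sections < 0:
            raise ValueError("min_sections must be >= 0 (0 = all sections)")
        if self.data_dir and not Path(self.data_dir).is_dir():
            raise ValueError(f"data_dir does not exist: {self.data_dir}")


_FIELDS = {f.name: f for f in dataclasses.fields(PipelineConfig)}


def validate_config(path) -> PipelineConfig:
    """Parse and range-check a flat ``key = value`` config file."""
    kwargs = {}
    text = Path(path).read_text(encoding="utf-8")
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line {lineno}: expected key = value")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in _FIELDS:
            raise ValueError(f"unknown config key: {key}")
        caster = type(_FIELDS[key].default)
        kwargs[key] = value if caster is str else caster(value)
    return PipelineConfig(**kwargs)


# ---------------------------------------------------------------------------
# synthetic cohort for the default run


def default_cohort_config(cfg: PipelineConfig) -> CohortConfig:
    """Cohort the default pipeline simulates: two nested CNV clones and
    two expression programs shared across all sections."""
    chroms = KARYOTYPE[: cfg.n_chromosomes]

    def block(start, n):
        return tuple(f"G{i:05d}" for i in range(start, start + n))

    n_nuclear = cfg.n_genes - 13
    programs = (
        ProgramSpec("P1", block(n_nuclear - 120, 60), None, 3.0),
        ProgramSpec("P2", block(n_nuclear - 60, 60), None, 3.0),
    )
    clones: tuple = (
        CloneSpec("A", None, (("7", 1.0, "gain", 1.5),), 0.4, None),
        CloneSpec("B", "A", (("3", 1.0, "loss", 1.5),), 0.3, None),
    )
    if "7" not in chroms or "3" not in chroms:
        clones = ()
    return CohortConfig(
        n_sections=cfg.n_sections,
        spots_per_section=cfg.spots_per_section,
        n_cells=cfg.n_cells,
        n_genes=cfg.n_genes,
        clones=clones,
        programs=programs,
        chromosomes=chroms,
        seed=stage_seed(cfg.seed, "simulate"),
    )


def write_cohort(cohort, data_dir: Path) -> list[Path]:
    data_dir.mkdir(parents=True, exist_ok=True)
    out: list[Path] = []

    def _w(path):
        out.append(path)
        return path

    all_spots = []
    for i, (cm, spots) in enumerate(cohort.sections, 1):
        genes_path = _w(data_dir / "genes.tsv") if i == 1 else data_dir / "genes.tsv"
        spio.write_counts(cm, _w(data_dir / f"section_{i}.mtx"), genes_path,
                          _w(data_dir / f"section_{i}_barcodes.tsv"))
        all_spots.append(spots)
    spio.write_spots(pd.concat(all_spots, ignore_index=True), _w(data_dir / "spots.tsv"))
    cells_cm, cell_labels = cohort.cells
    spio.write_counts(cells_cm, _w(data_dir / "cells.mtx"), data_dir / "genes.tsv",
                      _w(data_dir / "cells_barcodes.tsv"))
    spio.write_labels(cell_labels, _w(data_dir / "cell_labels.tsv"))
    spio.write_gene_annotation(cohort.annotation, _w(data_dir / "annotation.tsv"))
    spio.write_gmt(cohort.truth.marker_sets, _w(data_dir / "marker_sets.gmt"))
    if len(cohort.truth.program_sets):
        spio.write_gmt(cohort.truth.program_sets, _w(data_dir / "program_sets.gmt"))
    spio.write_labels(
        pd.DataFrame({"obs_id": list(cohort.truth.spot_clone),
                      "label": list(cohort.truth.spot_clone.values())}),
        _w(data_dir / "truth_clones.tsv"))
    spio.write_labels(
        pd.DataFrame({"obs_id": list(cohort.truth.obs_cell_type),
                      "label": list(cohort.truth.obs_cell_type.values())}),
        _w(data_dir / "truth_types.tsv"))
    return out


# ---------------------------------------------------------------------------
# file-backed inputs


def _data_dir(cfg: PipelineConfig, out: Path) -> Path:
    return Path(cfg.data_dir) if cfg.data_dir else out / "data"


def _load_spots(cfg, out):
    d = _data_dir(cfg, out)
    spots = spio.read_spots(d / "spots.tsv")
    n_sections = spots["section_id"].nunique()
    cm = None
    for i in range(1, n_sections + 1):
        m = spio.read_counts(d / f"section_{i}.mtx", d / "genes.tsv",
                             d / f"section_{i}_barcodes.tsv")
        cm = m if cm is None else cm.concat_obs(m)
    return cm, spots


def _load_cells(cfg, out):
    d = _data_dir(cfg, out)
    cm = spio.read_counts(d / "cells.mtx", d / "genes.tsv", d / "cells_barcodes.tsv")
    labels = spio.read_labels(d / "cell_labels.tsv")
    return cm, labels


def _load_retained_spots(cfg, out):
    cm, spots = _load_spots(cfg, out)
    retained = pd.read_csv(out / "qc_retained.tsv", sep="\t")["obs_id"].astype(str).tolist()
    cm = cm.subset_obs(retained)
    spots = spots[spots["obs_id"].isin(retained)].reset_index(drop=True)
    return cm, spots


def _load_markers(path, group_col) -> dict[str, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", dtype={group_col: str, "gene_id": str})
    return {g: sub.reset_index(drop=True) for g, sub in df.groupby(group_col)}


def _load_profile(cfg, out) -> cnvmod.CnvProfile:
    ratios = pd.read_csv(out / "cnv_ratios.tsv", sep="\t", index_col=0)
    meta = json.loads((out / "cnv_meta.json").read_text(encoding="utf-8"))
    ann = spio.read_gene_annotation(_data_dir(cfg, out) / "annotation.tsv")
    chrom_of = dict(zip(ann["gene_id"], ann["chromosome"]))
    return cnvmod.CnvProfile(
        obs_ids=[str(o) for o in ratios.index],
        gene_ids=[str(g) for g in ratios.columns],
        chromosomes=[chrom_of[str(g)] for g in ratios.columns],
        ratios=ratios.to_numpy(),
        window=meta["window"],
        reference_obs=meta["reference_obs"],
    )


def _signatures(cfg, out):
    sets = spio.read_gmt(_data_dir(cfg, out) / "marker_sets.gmt")
    tumor_sig = sets["tumor"] if "tumor" in sets else []
    stromal_sig: list[str] = []
    for name in sets.names():
        if name != "tumor":
            stromal_sig.extend(sets[name])
    return sets, tumor_sig, stromal_sig


# ---------------------------------------------------------------------------
# stages: each returns (list of output paths, dict of logged parameters)


def stage_simulate(cfg: PipelineConfig, out: Path):
    if cfg.data_dir:
        return [], {"skipped": True, "data_dir": cfg.data_dir}
    cohort = generate_cohort(default_cohort_config(cfg))
    files = write_cohort(cohort, out / "data")
    return files, {"seed": stage_seed(cfg.seed, "simulate"),
                   "n_sections": cfg.n_sections, "n_genes": cfg.n_genes}


def stage_qc(cfg: PipelineConfig, out: Path):
    cm, _ = _load_spots(cfg, out)
    retained = qcmod.filter_observations(cm, qcmod.QC_PRESETS[cfg.qc_preset])
    if not retained:
        raise ValueError("QC removed every spot")
    p = out / "qc_retained.tsv"
    pd.DataFrame({"obs_id": retained}).to_csv(p, sep="\t", index=False)
    return [p], {"preset": cfg.qc_preset, "retained": len(retained),
                 "removed": len(cm.obs_ids) - len(retained)}


def stage_cluster(cfg: PipelineConfig, out: Path):
    cm, _ = _load_retained_spots(cfg, out)
    em = qcmod.normalize_log(cm)
    n_hvgs = min(cfg.n_hvgs, len(em.gene_ids))
    hvgs = qcmod.select_hvg(em, n_hvgs)
    clusters = qcmod.embed_and_cluster(
        em, hvgs, n_pcs=cfg.n_pcs, resolution=cfg.resolution,
        seed=stage_seed(cfg.seed, "cluster"))
    p = out / "clusters.tsv"
    spio.write_labels(clusters, p)
    return [p], {"n_hvgs": n_hvgs, "n_pcs": cfg.n_pcs,
                 "resolution": cfg.resolution,
                 "n_clusters": int(clusters["label"].nunique())}


def stage_markers(cfg: PipelineConfig, out: Path):
    cm, _ = _load_retained_spots(cfg, out)
    em = qcmod.normalize_log(cm)
    clusters = spio.read_labels(out / "clusters.tsv")
    markers = qcmod.find_markers(em, clusters)
    marker_df = (pd.concat([df.assign(cluster=c) for c, df in markers.items()],
                           ignore_index=True)
                 if markers else pd.DataFrame(columns=["gene_id", "cluster"]))
    p = out / "markers.tsv"
    marker_df.to_csv(p, sep="\t", index=False)
    cells_cm, cell_labels = _load_cells(cfg, out)
    cell_em = qcmod.normalize_log(cells_cm)
    cell_markers = qcmod.find_markers(cell_em, cell_labels)
    cmark_df = (pd.concat([df.assign(cell_type=c) for c, df in cell_markers.items()],
                          ignore_index=True)
                if cell_markers else pd.DataFrame(columns=["gene_id", "cell_type"]))
    p2 = out / "cell_markers.tsv"
    cmark_df.to_csv(p2, sep="\t", index=False)
    return [p, p2], {"n_clusters": len(markers), "n_cell_types": len(cell_markers)}


def stage_classify(cfg: PipelineConfig, out: Path):
    markers = _load_markers(out / "markers.tsv", "cluster")
    _, tumor_sig, stromal_sig = _signatures(cfg, out)
    classes = qcmod.classify_clusters(markers, tumor_sig, stromal_sig,
                                      min_overlap=cfg.min_overlap)
    p = out / "cluster_classes.tsv"
    pd.DataFrame({"cluster": list(classes), "class": list(classes.values())}
                 ).to_csv(p, sep="\t", index=False)
    return [p], {"min_overlap": cfg.min_overlap,
                 "classes": dict(sorted(classes.items()))}


def stage_cnv(cfg: PipelineConfig, out: Path):
    cm, _ = _load_retained_spots(cfg, out)
    clusters = spio.read_labels(out / "clusters.tsv")
    classes = pd.read_csv(out / "cluster_classes.tsv", sep="\t", dtype=str)
    class_of = dict(zip(classes["cluster"], classes["class"]))
    cluster_of = clusters.set_index("obs_id")["label"]
    stromal = {c for c, k in class_of.items() if k == "stromal"}
    if not stromal:
        stromal = {c for c, k in class_of.items() if k != "tumor"}
    reference = [o for o in cm.obs_ids if cluster_of.get(o) in stromal]
    if not reference:
        raise ValueError("no stromal reference spots found")
    ann = spio.read_gene_annotation(_data_dir(cfg, out) / "annotation.tsv")
    profile = cnvmod.infer_cnv(cm, reference, ann, window=cfg.window,
                               expr_cutoff=cfg.expr_cutoff,
                               max_centered=cfg.max_centered)
    scores = cnvmod.normalize_cnv(cnvmod.cnv_burden(profile))
    p = out / "cnv_ratios.tsv"
    pd.DataFrame(profile.ratios, index=profile.obs_ids,
                 columns=profile.gene_ids).round(6).to_csv(p, sep="\t")
    p2 = out / "cnv_meta.json"
    p2.write_text(json.dumps({"window": profile.window,
                              "expr_cutoff": cfg.expr_cutoff,
                              "n_genes": len(profile.gene_ids),
                              "reference_obs": profile.reference_obs},
                             indent=1), encoding="utf-8")
    p3 = out / "cnv_scores.tsv"
    pd.DataFrame({"obs_id": list(scores.raw),
                  "raw": list(scores.raw.values()),
                  "normalized": [scores.normalized[o] for o in scores.raw]}
                 ).to_csv(p3, sep="\t", index=False)
    # cell-side CNV and the nCNV > threshold tumor reclassification
    cells_cm, cell_labels = _load_cells(cfg, out)
    cell_ref = [o for o, l in zip(cell_labels["obs_id"], cell_labels["label"])
                if l not in ("tumor", "mesothelial", "endothelial")]
    cell_profile = cnvmod.infer_cnv(cells_cm, cell_ref, ann, window=cfg.window,
                                    expr_cutoff=cfg.expr_cutoff,
                                    max_centered=cfg.max_centered)
    cell_scores = cnvmod.normalize_cnv(cnvmod.cnv_burden(cell_profile))
    relabeled = cnvmod.reclassify_tumor_cells(cell_labels, cell_scores,
                                              threshold=cfg.reclass_threshold)
    p4 = out / "cell_labels_reclassified.tsv"
    spio.write_labels(relabeled, p4)
    return [p, p2, p3, p4], {
        "window": cfg.window, "expr_cutoff": cfg.expr_cutoff,
        "n_reference": len(reference),
        "n_reclassified": int((relabeled["label"] != cell_labels["label"]).sum())}


def stage_clones(cfg: PipelineConfig, out: Path):
    profile = _load_profile(cfg, out)
    clone_labels = cnvmod.detect_clones(profile, n_clones=cfg.n_clones)
    p = out / "clones.tsv"
    spio.write_labels(clone_labels, p)
    n = int(clone_labels.loc[clone_labels["label"] != "normal", "label"].nunique())
    return [p], {"n_clones": n}


def stage_tree(cfg: PipelineConfig, out: Path):
    profile = _load_profile(cfg, out)
    clone_labels = spio.read_labels(out / "clones.tsv")
    events = cnvmod.segment_events(profile, clone_labels, gain_thr=cfg.gain_thr,
                                   loss_thr=cfg.loss_thr,
                                   min_genes=cfg.min_event_genes)
    tree = cnvmod.build_clone_tree(events)
    p = out / "tree.nwk"
    p.write_text(tree.to_newick() + "\n", encoding="utf-8")
    p2 = out / "tree_edges.tsv"
    tree.edge_table().to_csv(p2, sep="\t", index=False)
    d = _data_dir(cfg, out)
    link_path = d / "program_sets.gmt"
    sets = spio.read_gmt(link_path if link_path.exists() else d / "marker_sets.gmt")
    linked = cnvmod.link_events_to_gene_sets(events, profile.gene_ids, sets)
    p3 = out / "cnv_gene_sets.tsv"
    linked.to_csv(p3, sep="\t", index=False)
    return [p, p2, p3], {"conflict": tree.conflict,
                         "n_events": sum(len(v) for v in events.values())}


def stage_mia(cfg: PipelineConfig, out: Path):
    markers = _load_markers(out / "markers.tsv", "cluster")
    cell_markers = _load_markers(out / "cell_markers.tsv", "cell_type")
    cm, _ = _load_spots(cfg, out)
    background = set(cm.gene_ids)
    mia_df = scmod.mia_table(
        {c: df["gene_id"].tolist() for c, df in markers.items()},
        {c: df["gene_id"].tolist() for c, df in cell_markers.items()},
        background)
    p = out / "mia.tsv"
    mia_df.to_csv(p, sep="\t", index=False)
    return [p], {"background": len(background)}


def stage_tumorscore(cfg: PipelineConfig, out: Path):
    cm, spots = _load_retained_spots(cfg, out)
    em = qcmod.normalize_log(cm)
    _, tumor_sig, _ = _signatures(cfg, out)
    scores = pd.read_csv(out / "cnv_scores.tsv", sep="\t")
    ncnv_all = dict(zip(scores["obs_id"].astype(str), scores["normalized"]))
    sig = scmod.signature_score(em, tumor_sig, spots)
    nsig = dict(zip(sig["obs_id"], sig["normalized"]))
    ncnv = {o: ncnv_all[o] for o in nsig}
    tscore = scmod.tumor_score(ncnv, nsig)
    p = out / "tumor_score.tsv"
    spots.assign(ncnv=[ncnv[o] for o in spots["obs_id"]],
                 nsig=[nsig[o] for o in spots["obs_id"]],
                 tumor_score=[tscore[o] for o in spots["obs_id"]]
                 ).to_csv(p, sep="\t", index=False)
    return [p], {"n_spots": len(tscore)}


def stage_coloc(cfg: PipelineConfig, out: Path):
    cm, spots = _load_retained_spots(cfg, out)
    em = qcmod.normalize_log(cm)
    sets, _, _ = _signatures(cfg, out)
    ts = pd.read_csv(out / "tumor_score.tsv", sep="\t")
    tscore = dict(zip(ts["obs_id"].astype(str), ts["tumor_score"]))
    min_sections = cfg.min_sections or int(spots["section_id"].nunique())
    rows, secrows = [], []
    for ct in sets.names():
        if ct == "tumor":
            continue
        ct_sig = scmod.signature_score(em, sets[ct], spots)
        ct_map = dict(zip(ct_sig["obs_id"], ct_sig["normalized"]))
        res = scmod.colocalize(tscore, ct_map, spots, alpha=cfg.alpha,
                               min_sections=min_sections, cell_type=ct)
        rows.append((ct, res.n_significant, res.colocalized))
        secrows.append(res.sections.assign(cell_type=ct))
    p = out / "coloc.tsv"
    pd.DataFrame(rows, columns=["cell_type", "n_significant", "colocalized"]
                 ).to_csv(p, sep="\t", index=False)
    p2 = out / "coloc_sections.tsv"
    (pd.concat(secrows, ignore_index=True) if secrows else pd.DataFrame()
     ).to_csv(p2, sep="\t", index=False)
    return [p, p2], {"alpha": cfg.alpha, "min_sections": min_sections}


def stage_programs(cfg: PipelineConfig, out: Path):
    cm, spots = _load_retained_spots(cfg, out)
    em = qcmod.normalize_log(cm)
    clusters = spio.read_labels(out / "clusters.tsv")
    classes = pd.read_csv(out / "cluster_classes.tsv", sep="\t", dtype=str)
    tumor_clusters = set(classes.loc[classes["class"] == "tumor", "cluster"])
    cluster_of = clusters.set_index("obs_id")["label"]
    all_programs: list[progmod.Program] = []
    for sec in pd.unique(spots["section_id"]):
        obs = [o for o in spots.loc[spots["section_id"] == sec, "obs_id"]
               if cluster_of.get(o) in tumor_clusters]
        if len(obs) < cfg.rank_max + 2:
            logger.warning("section %s: too few tumor spots for NMF", sec)
            continue
        sec_em = em.subset_obs(obs)
        hv = qcmod.select_hvg(sec_em, min(cfg.program_hvgs, len(sec_em.gene_ids)))
        sub = sec_em.subset_genes(hv)
        model = progmod.ExpressionProgramNMF(
            rank="auto", rank_min=cfg.rank_min, rank_max=cfg.rank_max,
            top_n=cfg.top_n, sample_id=str(sec),
            random_state=stage_seed(cfg.seed, f"programs:{sec}"),
        ).fit(pd.DataFrame(sub.values.T, columns=sub.gene_ids))
        all_programs.extend(model.programs_)
    outputs = []
    prog_coll = (spio.GeneSetCollection(
        {f"{pr.sample_id}.f{pr.factor_index}": list(pr.genes) for pr in all_programs})
        if all_programs else spio.GeneSetCollection({"none": ["none"]}))
    p = out / "programs.gmt"
    spio.write_gmt(prog_coll, p)
    outputs.append(p)
    metas = (progmod.cluster_programs(all_programs, cut=cfg.cut,
                                      share_fraction=cfg.share_fraction)
             if len(all_programs) >= 2 else [])
    meta_coll = (spio.GeneSetCollection(
        {f"MP{i + 1}": (mp.signature or ["none"]) for i, mp in enumerate(metas)})
        if metas else spio.GeneSetCollection({"none": ["none"]}))
    p2 = out / "metaprograms.gmt"
    spio.write_gmt(meta_coll, p2)
    outputs.append(p2)
    if all_programs:
        J = progmod.jaccard_matrix(all_programs)
        names = [f"{pr.sample_id}.f{pr.factor_index}" for pr in all_programs]
        p3 = out / "jaccard.tsv"
        pd.DataFrame(J, index=names, columns=names).round(4).to_csv(p3, sep="\t")
        outputs.append(p3)
    return outputs, {"n_programs": len(all_programs), "n_metaprograms": len(metas),
                     "rank_min": cfg.rank_min, "rank_max": cfg.rank_max,
                     "top_n": cfg.top_n}


_STAGE_FN = {
    "simulate": stage_simulate, "qc": stage_qc, "cluster": stage_cluster,
    "markers": stage_markers, "classify": stage_classify, "cnv": stage_cnv,
    "clones": stage_clones, "tree": stage_tree, "mia": stage_mia,
    "tumorscore": stage_tumorscore, "coloc": stage_coloc,
    "programs": stage_programs,
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_stage(stage: str, cfg: PipelineConfig, out_dir=None) -> dict:
    """Run one stage standalone against a prior run's output directory."""
    if stage not in _STAGE_FN:
        raise ValueError(f"unknown stage {stage!r}; one of {STAGES}")
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs, params = _STAGE_FN[stage](cfg, out)
    return {"parameters": params,
            "outputs": {str(p): _sha256(p) for p in outputs},
            "status": "ok"}


def run_all(cfg: PipelineConfig, out_dir=None) -> dict:
    """Run every stage in order; returns (and writes) the manifest."""
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    if logger.level == logging.NOTSET or logger.level > logging.INFO:
        logger.setLevel(logging.INFO)
    manifest: dict = {}
    t0 = time.time()
    try:
        for stage in STAGES:
            logger.info("stage %s: start", stage)
            try:
                manifest[stage] = run_stage(stage, cfg, out)
            except Exception as e:
                logger.error("stage %s failed: %s", stage, e)
                raise RuntimeError(f"pipeline aborted at stage {stage!r}: {e}") from e
            logger.info("stage %s: ok (%d outputs)", stage,
                        len(manifest[stage]["outputs"]))
    finally:
        logger.removeHandler(handler)
        handler.close()
    manifest["_run"] = {"seed": cfg.seed, "elapsed_s": round(time.time() - t0, 2)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1),
                                       encoding="utf-8")
    return manifest
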