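"""CNV profiling, burden/nCNV, clone detection, events, clone tree."""

import numpy as np
import pandas as pd
import pytest

from spathet._utils import KARYOTYPE
from spathet.cnv import (
    CloneCaller,
    CnvEvent,
    CnvScoreMap,
    build_clone_tree,
    cnv_burden,
    detect_clones,
    infer_cnv,
    link_events_to_gene_sets,
    normalize_cnv,
    reclassify_tumor_cells,
    segment_events,
)
from spathet.io import GeneSetCollection
from spathet.simulate import CloneSpec, CohortConfig, generate_cohort

from conftest import make_two_clone_cohort, stromal_obs, tumor_obs


def _profile(cohort, window=101, **kw):
    cm, _ = cohort.sections[0]
    ref = stromal_obs(cohort) or cm.obs_ids[:100]
    if not stromal_obs(cohort):
        ref = cm.obs_ids[:100]
    return cm, ref, infer_cnv(cm, ref, cohort.annotation, window=window, **kw)


class TestInferCnv:
    def test_null_profile_flat(self, null_cohort):
        """Queries drawn from the reference distribution give ratios
        tightly centered at 1 and honest reference burden (<= 1.05)."""
        cm, ref, p = _profile(null_cohort)
        # denoising zeroes residuals within 1.5 reference SD, so the bulk
        # of a null profile is exactly diploid (Gaussian mass ~87%)
        assert np.mean(p.ratios == 1.0) >= 0.8
        assert np.mean((p.ratios >= 0.9) & (p.ratios <= 1.1)) >= 0.9
        assert p.ratios.max() <= 2.0 and p.ratios.min() >= 0.5  # clip bounds
        raw = cnv_burden(p)
        assert max(raw.raw[o] for o in ref) <= 1.05

    def test_reference_centered_at_one(self, null_cohort):
        cm, ref, p = _profile(null_cohort)
        ref_rows = [i for i, o in enumerate(p.obs_ids) if o in set(ref)]
        per_gene = p.ratios[ref_rows].mean(axis=0)
        assert per_gene.min() >= 0.95 and per_gene.max() <= 1.05

    def test_planted_gain_separates_clone(self, gain_cohort):
        """Chr-3 gain at fold 1.5 lifts the clone's mean chr-3 ratio at
        least 0.15 above non-clone spots."""
        cm, ref, p = _profile(gain_cohort)
        chr3 = np.array([c == "3" for c in p.chromosomes])
        assert chr3.sum() >= 200
        in_clone = np.array(
            [gain_cohort.truth.spot_clone[o] == "A" for o in p.obs_ids])
        gap = (p.ratios[np.ix_(in_clone, chr3)].mean()
               - p.ratios[np.ix_(~in_clone, chr3)].mean())
        assert gap >= 0.15

    def test_window_one_is_identity(self, null_cohort):
        """window=1 (no smoothing, no denoising) returns the clipped,
        reference-centered, median-recentered per-gene residuals."""
        cm, ref, p = _profile(null_cohort, window=1, denoise_sd=None)
        x = cm.dense().T.astype(float)
        depths = x.sum(axis=1)
        norm = x * (np.median(depths) / depths)[:, None]
        gi = {g: i for i, g in enumerate(cm.gene_ids)}
        ann = null_cohort.annotation
        order = [gi[g] for g in ann["gene_id"] if g in gi]
        keep = norm.mean(axis=0)[order] >= 0.1
        cols = np.array(order)[keep]
        log = np.log2(1 + norm[:, cols])
        ref_rows = np.array([o in set(ref) for o in cm.obs_ids])
        res = np.clip(log - log[ref_rows].mean(axis=0), -1, 1)
        res -= np.median(res, axis=1, keepdims=True)
        np.testing.assert_allclose(p.ratios, 2.0**res, rtol=1e-10)

    def test_empty_reference_rejected(self, null_cohort):
        cm, _ = null_cohort.sections[0]
        with pytest.raises(ValueError, match="empty reference"):
            infer_cnv(cm, [], null_cohort.annotation)

    def test_even_window_rejected(self, null_cohort):
        cm, _ = null_cohort.sections[0]
        with pytest.raises(ValueError, match="odd"):
            infer_cnv(cm, cm.obs_ids[:10], null_cohort.annotation, window=4)

    def test_window_larger_than_every_chromosome_rejected(self, null_cohort):
        cm, _ = null_cohort.sections[0]
        with pytest.raises(ValueError, match="fewer than window"):
            infer_cnv(cm, cm.obs_ids[:10], null_cohort.annotation, window=1001)

    def test_burden_monotone_in_fold(self):
        """Raising a planted event's fold never lowers the clone's mean
        burden (folds 1.2 / 1.5 / 2.0, fixed seed)."""
        burdens = []
        for fold in (1.2, 1.5, 2.0):
            co = generate_cohort(CohortConfig(
                n_sections=1, spots_per_section=200, n_cells=50, n_genes=1000,
                chromosomes=KARYOTYPE[:4],
                clones=(CloneSpec("A", None, (("2", 1.0, "gain", fold),), 0.5,
                                  None),),
                seed=13,
            ))
            cm, _ = co.sections[0]
            ref = stromal_obs(co)
            p = infer_cnv(cm, ref, co.annotation, window=101)
            raw = cnv_burden(p)
            clone = [o for o in p.obs_ids if co.truth.spot_clone[o] == "A"]
            burdens.append(np.mean([raw.raw[o] for o in clone]))
        assert burdens[0] <= burdens[1] <= burdens[2]


class TestBurdenAndNormalization:
    def _profile_from_ratios(self, ratios):
        from spathet.cnv import CnvProfile

        n_obs, n_genes = ratios.shape
        return CnvProfile(
            obs_ids=[f"o{i}" for i in range(n_obs)],
            gene_ids=[f"g{i}" for i in range(n_genes)],
            chromosomes=["1"] * n_genes,
            ratios=ratios,
            window=1,
            reference_obs=[],
        )

    def test_burden_arithmetic(self):
        p = self._profile_from_ratios(np.array([
            np.ones(10),                      # diploid -> 1.0
            [1.5] * 5 + [1.0] * 5,            # half gained -> 1.25
            [0.5] * 10,                       # all lost -> 1.5
        ]))
        raw = cnv_burden(p)
        assert raw.raw["o0"] == pytest.approx(1.0)
        assert raw.raw["o1"] == pytest.approx(1.25)
        assert raw.raw["o2"] == pytest.approx(1.5)

    def test_ncnv_formula(self):
        s = normalize_cnv(CnvScoreMap(raw={"a": 1.0, "b": 1.5, "c": 2.0}))
        assert s.normalized == pytest.approx({"a": 0.0, "b": 0.5, "c": 1.0})
        assert s.max_raw == 2.0

    def test_ncnv_degenerate_max(self):
        s = normalize_cnv(CnvScoreMap(raw={"a": 1.0, "b": 1.0}))
        assert s.normalized == {"a": 0.0, "b": 0.0}

    def test_ncnv_single_observation_is_max(self):
        s = normalize_cnv(CnvScoreMap(raw={"only": 1.7}))
        assert s.normalized["only"] == pytest.approx(1.0)

    def test_ncnv_scale_invariance(self):
        """Scaling raw deviations (raw-1) by a positive factor leaves the
        normalized scores unchanged; a shift does not."""
        raw = {"a": 1.0, "b": 1.2, "c": 1.8}
        base = normalize_cnv(CnvScoreMap(raw=raw)).normalized
        scaled = normalize_cnv(CnvScoreMap(
            raw={k: 1 + 3.0 * (v - 1) for k, v in raw.items()})).normalized
        assert scaled == pytest.approx(base)
        shifted = normalize_cnv(CnvScoreMap(
            raw={k: v + 0.5 for k, v in raw.items()})).normalized
        assert shifted != pytest.approx(base)

    def test_raw_below_one_rejected(self):
        with pytest.raises(ValueError):
            normalize_cnv(CnvScoreMap(raw={"a": 0.9}))


class TestReclassify:
    def _scores(self, vals):
        return CnvScoreMap(raw={k: 1 + v for k, v in vals.items()},
                           normalized=dict(vals), max_raw=2.0)

    def test_exceeding_threshold_flips(self):
        labels = pd.DataFrame({"obs_id": ["c1"], "label": ["mesothelial"]})
        out = reclassify_tumor_cells(labels, self._scores({"c1": 0.31}))
        assert out["label"].tolist() == ["tumor"]

    def test_exactly_at_threshold_unchanged(self):
        labels = pd.DataFrame({"obs_id": ["c1"], "label": ["mesothelial"]})
        out = reclassify_tumor_cells(labels, self._scores({"c1": 0.30}))
        assert out["label"].tolist() == ["mesothelial"]

    def test_ineligible_label_unchanged(self):
        labels = pd.DataFrame({"obs_id": ["c1"], "label": ["fibroblast"]})
        out = reclassify_tumor_cells(labels, self._scores({"c1": 0.9}))
        assert out["label"].tolist() == ["fibroblast"]

    def test_missing_score_lists_ids(self):
        labels = pd.DataFrame({"obs_id": ["c1", "c2"],
                               "label": ["mesothelial", "endothelial"]})
        with pytest.raises(ValueError, match="c2"):
            reclassify_tumor_cells(labels, self._scores({"c1": 0.5}))


class TestDetectClones:
    def test_identical_observations_single_clone(self):
        x = np.ones((20, 50))
        labels = CloneCaller(n_clones="auto").fit(x).labels_
        assert len(set(labels)) == 1

    def test_singleton_clones(self):
        rng = np.random.default_rng(0)
        x = rng.random((6, 30)) + 0.5
        caller = CloneCaller(n_clones=6).fit(x)
        assert len(set(caller.labels_)) == 6

    def test_n_clones_exceeds_observations(self):
        with pytest.raises(ValueError, match="exceeds"):
            CloneCaller(n_clones=10).fit(np.ones((4, 5)))

    def test_two_clone_recovery_across_seeds(self):
        from sklearn.metrics import adjusted_rand_score

        for seed in (1, 2, 3, 4, 5):
            co = make_two_clone_cohort(seed)
            cm, _ = co.sections[0]
            ref = stromal_obs(co)
            p = infer_cnv(cm, ref, co.annotation, window=101)
            cl = detect_clones(p, n_clones="auto")
            lab = cl.set_index("obs_id")["label"]
            q = tumor_obs(co)
            ari = adjusted_rand_score(
                [co.truth.spot_clone[o] for o in q], [lab[o] for o in q])
            assert ari >= 0.9
            assert (lab[ref] == "normal").all()


class TestSegmentEvents:
    def _profile(self, ratios, chroms):
        from spathet.cnv import CnvProfile

        return CnvProfile(
            obs_ids=[f"o{i}" for i in range(ratios.shape[0])],
            gene_ids=[f"g{i}" for i in range(ratios.shape[1])],
            chromosomes=chroms,
            ratios=ratios,
            window=1,
            reference_obs=[],
        )

    def _labels(self, p, label="c1"):
        return pd.DataFrame({"obs_id": p.obs_ids, "label": label})

    def test_whole_chromosome_gain(self, gain_cohort):
        cm, _ = gain_cohort.sections[0]
        ref = stromal_obs(gain_cohort)
        p = infer_cnv(cm, ref, gain_cohort.annotation, window=101)
        truth_labels = pd.DataFrame({
            "obs_id": p.obs_ids,
            "label": [gain_cohort.truth.spot_clone[o] for o in p.obs_ids]})
        events = segment_events(p, truth_labels)
        chr3_genes = sum(c == "3" for c in p.chromosomes)
        gains = [e for e in events["A"] if e.chromosome == "3" and e.state == "gain"]
        assert len(gains) == 1
        assert gains[0].n_genes >= 0.8 * chr3_genes

    def test_flat_clone_no_events(self):
        p = self._profile(np.ones((5, 60)), ["1"] * 60)
        events = segment_events(p, self._labels(p), min_genes=10)
        assert events["c1"] == []

    def test_alternating_ratios_no_events(self):
        row = np.tile([1.2, 0.8], 30)
        p = self._profile(np.tile(row, (4, 1)), ["1"] * 60)
        events = segment_events(p, self._labels(p), min_genes=10)
        assert events["c1"] == []

    def test_run_respects_chromosome_boundary(self):
        row = np.full(60, 1.2)
        p = self._profile(np.tile(row, (3, 1)), ["1"] * 30 + ["2"] * 30)
        events = segment_events(p, self._labels(p), min_genes=10)
        assert [(e.chromosome, e.state) for e in events["c1"]] == [
            ("1", "gain"), ("2", "gain")]


def _ev(chrom, start, end, state):
    return CnvEvent(chrom, start, end, state,
                    1.3 if state == "gain" else 0.7)


class TestCloneTree:
    def test_nested_events_force_lineage(self):
        e1 = _ev("1", 0, 99, "gain")
        e2 = _ev("2", 0, 99, "loss")
        tree = build_clone_tree({"A": [e1], "B": [e1, e2]})
        g = tree.graph
        assert list(g.predecessors("A")) == ["normal"]
        assert list(g.predecessors("B")) == ["A"]
        assert tree.path_events("B") == tree.clone_events["B"]
        assert not tree.conflict

    def test_disjoint_clones_branch_from_root(self):
        tree = build_clone_tree({
            "A": [_ev("1", 0, 99, "gain")],
            "B": [_ev("2", 0, 99, "loss")],
        })
        g = tree.graph
        assert list(g.predecessors("A")) == ["normal"]
        assert list(g.predecessors("B")) == ["normal"]

    def test_single_clone(self):
        tree = build_clone_tree({"A": [_ev("1", 0, 50, "gain")]})
        assert list(tree.graph.successors("normal")) == ["A"]
        assert len(tree.path_events("A")) == 1

    def test_event_matching_by_overlap(self):
        # 60% overlap of the shorter event: same class
        tree = build_clone_tree({
            "A": [_ev("1", 0, 99, "gain")],
            "B": [_ev("1", 30, 99, "gain")],
        })
        assert tree.clone_events["A"] == tree.clone_events["B"]

    def test_conflict_flagged_and_resolved(self):
        e1, e2, e3 = (_ev("1", 0, 99, "gain"), _ev("2", 0, 99, "loss"),
                      _ev("3", 0, 99, "gain"))
        # e1 shared by {A,B}, e2 by {B,C}: overlapping, non-nested
        tree = build_clone_tree({"A": [e1], "B": [e1, e2], "C": [e2, e3]})
        assert tree.conflict
        for clone in ("A", "B", "C"):
            assert tree.path_events(clone) == tree.clone_events[clone]

    def test_path_union_equals_event_set_on_recovered_clones(
            self, two_clone_cohort):
        co = two_clone_cohort
        cm, _ = co.sections[0]
        p = infer_cnv(cm, stromal_obs(co), co.annotation, window=101)
        cl = detect_clones(p, n_clones="auto")
        events = segment_events(p, cl)
        tree = build_clone_tree(events)
        for clone in tree.clone_events:
            assert tree.path_events(clone) == tree.clone_events[clone]

    def test_newick_and_edge_table(self):
        tree = build_clone_tree({
            "A": [_ev("1", 0, 99, "gain")],
            "B": [_ev("1", 0, 99, "gain"), _ev("2", 0, 50, "loss")],
        })
        nwk = tree.to_newick()
        assert nwk.endswith(";") and "A" in nwk and "B" in nwk
        table = tree.edge_table()
        assert {"parent", "child", "state"} <= set(table.columns)


class TestLinkEvents:
    def test_membership_rows(self):
        genes = [f"g{i}" for i in range(10)]
        sets = GeneSetCollection({"ESTROGEN": ["g2", "g9"]})
        events = {"A": [_ev("1", 1, 3, "loss")]}
        table = link_events_to_gene_sets(events, genes, sets)
        hit = table[table["gene_id"] == "g2"]
        assert hit["set_name"].tolist() == ["ESTROGEN"]
        none_rows = table[table["set_name"].isna()]
        assert set(none_rows["gene_id"]) == {"g1", "g3"}

    def test_empty_events_empty_table(self):
        table = link_events_to_gene_sets({}, ["g0"], GeneSetCollection({"s": ["g0"]}))
        assert table.empty
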