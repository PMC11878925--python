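"""QC filtering, normalization, HVG selection, clustering, markers."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from spathet._utils import KARYOTYPE
from spathet.io import CountMatrix, ExpressionMatrix
from spathet.qc import (
    QC_PRESETS,
    QcThresholds,
    classify_clusters,
    embed_and_cluster,
    filter_observations,
    find_markers,
    normalize_log,
    select_hvg,
)
from spathet.simulate import CellTypeSpec, CohortConfig, generate_cohort

from conftest import tumor_obs


def _matrix_with_detected(detected_per_obs, n_genes=500, count=2):
    """Observations with exactly the requested detected-gene counts."""
    n = len(detected_per_obs)
    x = np.zeros((n_genes, n), dtype=int)
    for j, d in enumerate(detected_per_obs):
        x[:d, j] = count
    return CountMatrix(x, [f"g{i}" for i in range(n_genes)],
                       [f"o{j}" for j in range(n)])


class TestFilterObservations:
    def test_min_genes_boundary(self):
        cm = _matrix_with_detected([399, 400, 401])
        kept = filter_observations(cm, QcThresholds(min_genes=400))
        assert kept == ["o1", "o2"]

    def test_mito_strictly_less_than(self):
        # 13 MT genes among 100; counts arranged for exact fractions
        genes = [f"MT-{i}" for i in range(1, 14)] + [f"g{i}" for i in range(87)]
        x = np.zeros((100, 3), dtype=int)
        # obs0: mito 13/100, obs1: 12/100, obs2: 14/100
        for j, mito in enumerate([13, 12, 14]):
            x[0, j] = mito
            x[13:, j] = 1  # 87 non-mito counts
        # pad totals to 100 via one non-mito gene
        for j, mito in enumerate([13, 12, 14]):
            x[13, j] += 100 - mito - 87
        cm = CountMatrix(x, genes, ["o0", "o1", "o2"])
        kept = filter_observations(
            cm, QcThresholds(min_genes=0, max_mito_fraction=0.13))
        assert kept == ["o1"]  # exactly 0.13 is dropped, strict <

    def test_vacuous_thresholds_keep_all(self):
        cm = _matrix_with_detected([1, 50, 499])
        assert filter_observations(cm, QcThresholds(0, None, None)) == cm.obs_ids

    def test_max_genes_band(self):
        cm = _matrix_with_detected([150, 200, 300, 450])
        kept = filter_observations(cm, QcThresholds(min_genes=200, max_genes=300))
        assert kept == ["o1", "o2"]

    def test_idempotent(self):
        cm = _matrix_with_detected([100, 399, 400, 450])
        t = QC_PRESETS["geo"]
        kept = filter_observations(cm, t)
        again = filter_observations(cm.subset_obs(kept), t)
        assert again == kept

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            QcThresholds(min_genes=-1)
        with pytest.raises(ValueError):
            QcThresholds(min_genes=10, max_genes=5)


class TestNormalizeLog:
    def test_depth_invariance(self):
        base = np.array([[1, 2], [3, 6], [0, 0], [2, 4]])
        cm = CountMatrix(base, ["a", "b", "c", "d"], ["o1", "o2"])
        em = normalize_log(cm)
        np.testing.assert_allclose(em.values[:, 0], em.values[:, 1])

    def test_all_zero_observation_named(self):
        cm = CountMatrix(np.array([[1, 0], [2, 0]]), ["a", "b"], ["ok", "empty"])
        with pytest.raises(ValueError, match="empty"):
            normalize_log(cm)

    def test_single_observation(self):
        cm = CountMatrix(np.array([[3], [0]]), ["a", "b"], ["o1"])
        em = normalize_log(cm)
        np.testing.assert_allclose(em.values[:, 0], np.log1p([3.0, 0.0]))


class TestSelectHvg:
    def test_n_equals_gene_count(self):
        rng = np.random.default_rng(0)
        em = ExpressionMatrix(rng.random((30, 10)), [f"g{i}" for i in range(30)],
                              [f"o{j}" for j in range(10)])
        assert sorted(select_hvg(em, 30)) == sorted(em.gene_ids)
        with pytest.raises(ValueError):
            select_hvg(em, 31)

    def test_tie_break_lexicographic(self):
        # two identical high-dispersion genes; deterministic pick
        x = np.ones((4, 6))
        x[0] = [0, 4, 0, 4, 0, 4]
        x[1] = [0, 4, 0, 4, 0, 4]
        em = ExpressionMatrix(x, ["gb", "ga", "gc", "gd"], [f"o{j}" for j in range(6)])
        top = select_hvg(em, 1)
        assert top == ["ga"]

    def test_planted_variable_genes_recovered(self):
        """>= 45 of 50 planted high-variance program genes among 2,000
        genes land inside the top-200 HVGs."""
        from spathet.simulate import ProgramSpec

        co = generate_cohort(CohortConfig(
            n_sections=1, spots_per_section=250, n_cells=50, n_genes=2000,
            chromosomes=KARYOTYPE[:10],
            cell_types=(CellTypeSpec("tumor", 60, 4.0),),
            tumor_spot_fraction=1.0,
            programs=(ProgramSpec(
                "P1", tuple(f"G{i:05d}" for i in range(1500, 1550)),
                None, 8.0, 0.5),),
            baseline_mean=1.0, seed=7))
        cm, _ = co.sections[0]
        em = normalize_log(cm)
        top200 = set(select_hvg(em, 200))
        planted = set(co.truth.program_sets["P1"])
        assert len(planted & top200) >= 45


@pytest.fixture(scope="module")
def two_pop():
    return generate_cohort(
        CohortConfig(
            n_sections=1, spots_per_section=300, n_cells=50, n_genes=600,
            chromosomes=KARYOTYPE[:5],
            cell_types=(CellTypeSpec("tumor", 60, 5.0),
                        CellTypeSpec("fibroblast", 60, 5.0)),
            tumor_spot_fraction=0.5, seed=4,
        )
    )


class TestEmbedAndCluster:

    def test_two_population_recovery(self, two_pop):
        from sklearn.metrics import adjusted_rand_score

        co = two_pop
        cm, _ = co.sections[0]
        em = normalize_log(cm)
        hv = select_hvg(em, 300)
        for seed in range(5):
            lab = embed_and_cluster(em, hv, n_pcs=20, resolution=0.3, seed=seed)
            truth = [co.truth.obs_cell_type[o] for o in lab["obs_id"]]
            assert adjusted_rand_score(truth, lab["label"].tolist()) >= 0.9

    def test_deterministic_given_seed(self, two_pop):
        co = two_pop
        cm, _ = co.sections[0]
        em = normalize_log(cm)
        hv = select_hvg(em, 200)
        a = embed_and_cluster(em, hv, seed=7)
        b = embed_and_cluster(em, hv, seed=7)
        assert a.equals(b)

    def test_resolution_to_zero_single_cluster(self):
        # the limit applies to a connected kNN graph: one population
        co = generate_cohort(CohortConfig(
            n_sections=1, spots_per_section=200, n_cells=50, n_genes=600,
            chromosomes=KARYOTYPE[:5],
            cell_types=(CellTypeSpec("tumor", 60, 4.0),),
            tumor_spot_fraction=1.0, seed=4))
        cm, _ = co.sections[0]
        em = normalize_log(cm)
        hv = select_hvg(em, 200)
        lab = embed_and_cluster(em, hv, resolution=1e-4, seed=0)
        assert lab["label"].nunique() == 1
        assert embed_and_cluster(em, hv, resolution=1.0,
                                 seed=0)["label"].nunique() > 1

    def test_too_few_observations(self):
        em = ExpressionMatrix(np.random.default_rng(0).random((30, 5)),
                              [f"g{i}" for i in range(30)],
                              [f"o{j}" for j in range(5)])
        with pytest.raises(ValueError, match="n_pcs"):
            embed_and_cluster(em, em.gene_ids, n_pcs=20)


def _exact_mwu_p(x, y):
    """Two-sided exact Wilcoxon rank-sum p by full enumeration (tie-free)."""
    combined = np.concatenate([x, y])
    n1 = len(x)
    obs_u = sum(1 for a in x for b in y if a > b) + 0.5 * sum(
        1 for a in x for b in y if a == b)
    us = []
    for idx in itertools.combinations(range(len(combined)), n1):
        g1 = combined[list(idx)]
        g2 = np.delete(combined, list(idx))
        us.append(sum(1 for a in g1 for b in g2 if a > b))
    us = np.array(us, dtype=float)
    p_ge = np.mean(us >= obs_u)
    p_le = np.mean(us <= obs_u)
    return min(1.0, 2 * min(p_ge, p_le))


class TestFindMarkers:
    def test_exact_oracle_small_groups(self):
        """p-values agree with full-enumeration Wilcoxon for groups <= 8."""
        from spathet.qc import _rank_sum_p

        rng = np.random.default_rng(1)
        for n1, n2 in [(4, 5), (6, 6), (8, 7)]:
            x = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # tie-free
            a, b = x[:n1], x[n1:]
            got = _rank_sum_p(a[None, :], b[None, :])[0]
            want = _exact_mwu_p(a, b)
            assert got == pytest.approx(want, abs=1e-12)

    def test_planted_marker_detected(self):
        rng = np.random.default_rng(3)
        n = 60  # 60 per side
        x = rng.poisson(2.0, size=(100, 2 * n)).astype(float)
        x[0, :n] = rng.poisson(12.0, size=n)  # 6-fold gene in cluster A
        em = ExpressionMatrix(np.log1p(x), [f"g{i}" for i in range(100)],
                              [f"o{j}" for j in range(2 * n)])
        labels = pd.DataFrame({"obs_id": em.obs_ids,
                               "label": ["A"] * n + ["B"] * n})
        markers = find_markers(em, labels)
        assert "g0" in markers["A"]["gene_id"].tolist()

    def test_permutation_null_fdr(self):
        """Across 20 label permutations the marker-call fraction stays
        at or below the nominal 5%."""
        rng = np.random.default_rng(5)
        x = np.log1p(rng.poisson(2.0, size=(200, 80)).astype(float))
        em = ExpressionMatrix(x, [f"g{i}" for i in range(200)],
                              [f"o{j}" for j in range(80)])
        fracs = []
        for _ in range(20):
            lab = rng.permutation(["A"] * 40 + ["B"] * 40)
            labels = pd.DataFrame({"obs_id": em.obs_ids, "label": lab})
            markers = find_markers(em, labels)
            fracs.append(sum(len(df) for df in markers.values()) / (2 * 200))
        assert np.mean(fracs) <= 0.05

    def test_identical_clusters_empty(self):
        x = np.tile(np.arange(10.0)[:, None], (1, 20))
        em = ExpressionMatrix(x, [f"g{i}" for i in range(10)],
                              [f"o{j}" for j in range(20)])
        labels = pd.DataFrame({"obs_id": em.obs_ids,
                               "label": ["A"] * 10 + ["B"] * 10})
        markers = find_markers(em, labels)
        assert all(df.empty for df in markers.values())

    def test_tiny_cluster_skipped(self, caplog):
        x = np.random.default_rng(0).random((20, 10))
        em = ExpressionMatrix(x, [f"g{i}" for i in range(20)],
                              [f"o{j}" for j in range(10)])
        labels = pd.DataFrame({"obs_id": em.obs_ids,
                               "label": ["A"] * 8 + ["B"] * 2})
        with caplog.at_level("WARNING", logger="spathet"):
            markers = find_markers(em, labels)
        assert "B" not in markers

    def test_adjusted_p_dominates_raw(self, program_cohort):
        co = program_cohort
        cm, _ = co.sections[0]
        em = normalize_log(cm)
        labels = pd.DataFrame({
            "obs_id": em.obs_ids,
            "label": [co.truth.obs_cell_type[o] for o in em.obs_ids]})
        markers = find_markers(em, labels)
        for df in markers.values():
            assert (df["adjusted_p"] >= df["p_value"] - 1e-15).all()


class TestClassifyClusters:
    def _markers(self, genes):
        return {"c": pd.DataFrame({"gene_id": genes,
                                   "log2_fold_change": 1.0,
                                   "p_value": 0.001, "adjusted_p": 0.01})}

    def test_tumor_call(self):
        m = self._markers([f"t{i}" for i in range(6)])
        classes = classify_clusters(m, [f"t{i}" for i in range(10)],
                                    ["s1", "s2"], min_overlap=5)
        assert classes["c"] == "tumor"

    def test_tie_is_unknown(self):
        m = self._markers(["t1", "s1"])
        classes = classify_clusters(m, ["t1"], ["s1"], min_overlap=1)
        assert classes["c"] == "unknown"

    def test_empty_markers_unknown(self):
        m = self._markers([])
        classes = classify_clusters(m, ["t1"], ["s1"], min_overlap=1)
        assert classes["c"] == "unknown"

    def test_empty_signature_rejected(self):
        with pytest.raises(ValueError):
            classify_clusters(self._markers(["a"]), [], ["s"], 1)
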