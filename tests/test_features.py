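import itertools

import numpy as np
import pytest

from latentflow import (SubjectSeries, edge_metastability, edge_time_series,
                        fcd_matrix, fcd_distribution, functional_complexity,
                        louvain_cpm, cpm_quality, modularity_signed)
from latentflow.features import bipartition_cpm


class TestFcd:
    def test_diagonal_is_one(self, random_series):
        fcd = fcd_matrix(random_series(8, 200), 30, 10)
        np.testing.assert_allclose(np.diag(fcd.data), 1.0, atol=1e-12)

    def test_periodic_series_recur(self):
        # windows one period apart see identical data
        base = np.random.default_rng(0).normal(size=(6, 40))
        data = np.tile(base, (1, 6))
        fcd = fcd_matrix(SubjectSeries(data), window_length=40, window_step=40)
        assert np.all(fcd.data > 0.99)

    def test_white_noise_offdiagonal_near_zero(self):
        s = SubjectSeries(np.random.default_rng(1).normal(size=(20, 600)))
        fcd = fcd_matrix(s, 30, 10)
        vals = fcd_distribution(fcd)
        assert np.mean(np.abs(vals)) < 0.15

    def test_distribution_count_and_range(self, random_series):
        fcd = fcd_matrix(random_series(6, 120), 30, 30)
        vals = fcd_distribution(fcd)
        assert vals.size == fcd.n_windows * (fcd.n_windows - 1) // 2
        assert np.all((-1 <= vals) & (vals <= 1))

    def test_too_few_windows_errors(self, random_series):
        with pytest.raises(ValueError, match="2 windows"):
            fcd_matrix(random_series(4, 50), window_length=50, window_step=10)

    def test_pooled_group_contrast_on_cohort(self, desk_cohort):
        # FCD distributions pooled across subjects separate the groups
        from scipy import stats

        from latentflow import zscore_rows

        ctrl, pat = [], []
        for rec in desk_cohort.records:
            tp = "control" if rec.group == "control" else "2wk"
            s = zscore_rows(desk_cohort.get_series(rec.subject_id, tp))
            vals = fcd_distribution(fcd_matrix(s, 30, 3))
            (ctrl if rec.group == "control" else pat).append(vals)
        t, p = stats.ttest_ind(np.concatenate(ctrl), np.concatenate(pat),
                               equal_var=False)
        assert p < 0.05


class TestMetastability:
    def test_constant_edges_zero(self):
        from latentflow.edges import EdgeSeries

        e = EdgeSeries(np.ones((3, 50)), np.zeros((3, 2), int))
        assert edge_metastability(e) == 0.0

    def test_alternating_rss_hand_case(self):
        from latentflow.edges import EdgeSeries

        e = EdgeSeries(np.array([[1.0, 3, 1, 3, 1, 3]]), np.zeros((1, 2), int))
        assert edge_metastability(e) == pytest.approx(1.0)

    def test_scale_invariance_after_zscore(self, random_series):
        from latentflow import zscore_rows

        s = random_series(6, 100, seed=4)
        scaled = SubjectSeries(s.data * 17.3)
        a = edge_metastability(edge_time_series(zscore_rows(s)))
        b = edge_metastability(edge_time_series(zscore_rows(scaled)))
        assert a == pytest.approx(b, abs=1e-10)

    def test_per_edge_variant(self, random_series):
        e = edge_time_series(random_series(5, 80, seed=2))
        expected = np.mean(np.std(e.data, axis=1))
        assert edge_metastability(e, "per_edge") == pytest.approx(expected)


def _brute_force_best_partition_q(w, gamma, max_k=None):
    """Exhaustive search over all partitions (n <= 8) by direct formula."""
    n = w.shape[0]
    best = -np.inf
    best_labels = None
    # enumerate set partitions via restricted growth strings
    def grow(labels, k):
        nonlocal best, best_labels
        i = len(labels)
        if i == n:
            if max_k is None or len(set(labels)) <= max_k:
                q = cpm_quality(w, np.array(labels), gamma)
                if q > best:
                    best, best_labels = q, list(labels)
            return
        for c in range(k + 1):
            grow(labels + [c], max(k, c + 1))
    grow([0], 1)
    return best, np.array(best_labels)


class TestModularity:
    def test_four_node_hand_case(self):
        fc = np.array([[1.0, .9, -.2, -.2], [.9, 1, -.2, -.2],
                       [-.2, -.2, 1, .9], [-.2, -.2, .9, 1]])
        part = bipartition_cpm(fc, 0.0, n_restarts=10, seed=0)
        assert set(map(tuple, [np.where(part.labels == c)[0]
                               for c in (0, 1)])) == {(0, 1), (2, 3)}
        best, _ = _brute_force_best_partition_q(fc, 0.0, max_k=2)
        assert part.q == pytest.approx(best, abs=1e-12)

    def test_quality_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            w = rng.normal(size=(8, 8))
            w = 0.5 * (w + w.T)
            np.fill_diagonal(w, 1.0)
            labels = rng.integers(0, 3, size=8)
            gamma = rng.uniform(0, 0.5)
            # direct double-loop evaluation
            num = sum((w[i, j] - gamma)
                      for i in range(8) for j in range(8)
                      if i != j and labels[i] == labels[j])
            denom = sum(abs(w[i, j]) for i in range(8) for j in range(8)
                        if i != j)
            assert cpm_quality(w, labels, gamma) == pytest.approx(
                num / denom, abs=1e-12)

    def test_louvain_matches_exhaustive_on_random_signed(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            w = rng.normal(scale=0.5, size=(8, 8))
            w = 0.5 * (w + w.T)
            np.fill_diagonal(w, 0.0)
            gamma = float(rng.uniform(0.0, 0.2))
            part = bipartition_cpm(w, gamma, n_restarts=30, seed=1)
            best, _ = _brute_force_best_partition_q(w, gamma, max_k=2)
            assert part.q == pytest.approx(best, abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        w = rng.normal(size=(10, 10))
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        perm = rng.permutation(10)
        q1 = bipartition_cpm(w, 0.05, n_restarts=20, seed=5).q
        q2 = bipartition_cpm(w[np.ix_(perm, perm)], 0.05,
                             n_restarts=20, seed=5).q
        assert q1 == pytest.approx(q2, abs=1e-12)

    def test_no_bipartition_raises_by_default(self):
        w = -np.ones((6, 6))            # all-negative: immediate fragmentation
        np.fill_diagonal(w, 0.0)
        with pytest.raises(ValueError, match="bipartition"):
            modularity_signed(w, np.array([0.5, 0.6, 0.7]), n_restarts=3)


class TestFunctionalComplexity:
    def test_delta_distribution_zero(self):
        fc = np.full((10, 10), 0.42)
        np.fill_diagonal(fc, 1.0)
        assert functional_complexity(fc, 20) == 0.0

    def test_uniform_histogram_one(self):
        # 6 edges spread evenly over m = 6 bins
        vals = np.array([-0.9, -0.5, -0.2, 0.2, 0.5, 0.9])
        fc = np.eye(4)
        iu = np.triu_indices(4, 1)
        fc[iu] = vals
        fc = fc + fc.T - np.eye(4) * (np.diag(fc) - 1)
        np.fill_diagonal(fc, 1.0)
        assert functional_complexity(fc, 6) == pytest.approx(1.0)

    def test_half_split_hand_case(self):
        # mass 1/2 in each of two bins, m = 4: C = 1/3
        vals = np.array([-0.9, -0.9, -0.9, 0.9, 0.9, 0.9])
        fc = np.eye(4)
        iu = np.triu_indices(4, 1)
        fc[iu] = vals
        fc = fc + fc.T
        np.fill_diagonal(fc, 1.0)
        assert functional_complexity(fc, 4) == pytest.approx(1 / 3, abs=1e-12)

    def test_node_permutation_invariance(self, rng):
        w = rng.normal(size=(12, 12))
        fc = np.clip(0.5 * (w + w.T) / 3, -1, 1)
        np.fill_diagonal(fc, 1.0)
        perm = rng.permutation(12)
        assert functional_complexity(fc) == pytest.approx(
            functional_complexity(fc[np.ix_(perm, perm)]), abs=1e-15)

    def test_rejects_small_m(self):
        with pytest.raises(ValueError, match="m"):
            functional_complexity(np.eye(3), m=1)
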