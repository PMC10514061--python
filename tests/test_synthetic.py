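import numpy as np
import pytest
from scipy import stats

from latentflow import (build_coupling, generate_cohort, lesion_coupling,
                        simulate_series, zscore_rows)
from latentflow.outcomes import mean_deficit_change
from latentflow.synthetic import (BEHAVIOR_DOMAINS, CohortParams,
                                  read_cohort, var1_stationary_cov,
                                  variance_stable, write_cohort)


class TestBuildCoupling:
    def test_symmetric_when_no_asymmetry(self):
        c = build_coupling(20, 2, 1.0, 0.1, 0.5, asymmetry=0.0, seed=1)
        np.testing.assert_array_equal(c.weights, c.weights.T)

    def test_spectral_radius_enforced(self):
        c = build_coupling(30, 3, 0.4, -0.1, 0.3, asymmetry=0.1,
                           target_radius=0.8, seed=2)
        assert abs(c.spectral_radius() - 0.8) < 1e-9

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError, match="even"):
            build_coupling(21, 2)
        with pytest.raises(ValueError, match="target_radius"):
            build_coupling(20, 2, target_radius=1.2)

    def test_homotopic_pairs_share_module(self):
        c = build_coupling(20, 2, seed=0)
        pairs = c.homotopic_pairs()
        assert np.all(c.module_assignment[pairs[:, 0]]
                      == c.module_assignment[pairs[:, 1]])
        assert np.all(c.hemisphere_assignment[pairs[:, 0]] == 0)
        assert np.all(c.hemisphere_assignment[pairs[:, 1]] == 1)

    def test_planted_modules_recovered_by_louvain(self):
        # exhaustive bipartition oracle on the 20-node symmetrized weights
        from latentflow.features import cpm_quality, modularity_signed

        c = build_coupling(20, 2, 1.0, 0.1, 0.5, asymmetry=0.0,
                           target_radius=0.9, seed=1)
        w = 0.5 * (c.weights + c.weights.T)
        part = modularity_signed(w, np.arange(0.0, 0.06, 0.005),
                                 n_restarts=10, seed=0)
        assert part.n_communities == 2
        # labels match the planted split up to relabeling
        planted = c.module_assignment
        flip = 1 - part.labels
        assert (np.array_equal(part.labels, planted)
                or np.array_equal(flip, planted))
        # and its quality is the exhaustive-search optimum at that gamma
        best = _brute_force_bipartition_q(w, part.gamma)
        assert abs(part.q - best) < 1e-12


def _brute_force_bipartition_q(w, gamma):
    """Enumerate all 2^(n-1)-1 bipartitions, vectorized."""
    from latentflow.features import cpm_quality

    n = w.shape[0]
    b = w - gamma
    np.fill_diagonal(b, 0.0)
    codes = np.arange(1, 2 ** (n - 1))
    x = ((codes[:, None] >> np.arange(n)) & 1).astype(float)
    # Q numerator = x'Bx + (1-x)'B(1-x)
    bx = x @ b
    tot = b.sum()
    q_num = 2 * np.einsum("ij,ij->i", bx, x) - 2 * (x @ b.sum(1)) + tot
    denom = np.abs(w[~np.eye(n, dtype=bool)]).sum()
    return q_num.max() / denom


class TestLesionCoupling:
    def test_identity_at_zero_severity(self):
        c = build_coupling(12, 2, seed=3)
        out = lesion_coupling(c, 0.0, n_lesioned=0)
        np.testing.assert_array_equal(out.weights, c.weights)

    def test_full_severity_kills_homotopic(self):
        c = build_coupling(12, 2, seed=3)
        out = lesion_coupling(c, 1.0, k_homotopic=1.0, k_asym=0.0,
                              n_lesioned=0)
        pairs = c.homotopic_pairs()
        assert np.all(out.weights[pairs[:, 0], pairs[:, 1]] == 0.0)

    def test_rejects_severity_outside_unit_interval(self):
        c = build_coupling(12, 2, seed=3)
        with pytest.raises(ValueError, match="severity"):
            lesion_coupling(c, 1.5)

    def test_lesion_lowers_interhemispheric_fc(self):
        c = build_coupling(20, 2, 1.0, 0.1, 0.5, asymmetry=0.0,
                           target_radius=0.9, seed=1)
        damaged = lesion_coupling(c, 0.5, k_homotopic=0.9, k_asym=0.0,
                                  n_lesioned=0, seed=4)
        fc_h = np.mean([np.corrcoef(simulate_series(c, 2000, seed=s).data)
                        for s in range(5)], axis=0)
        fc_d = np.mean([np.corrcoef(simulate_series(damaged, 2000, seed=s).data)
                        for s in range(5)], axis=0)
        hemi = c.hemisphere_assignment
        inter = hemi[:, None] != hemi[None, :]
        pairs = c.homotopic_pairs()
        homo = np.zeros((20, 20), bool)
        homo[pairs[:, 0], pairs[:, 1]] = homo[pairs[:, 1], pairs[:, 0]] = True
        # interhemispheric FC drops, and the drop is largest on the
        # homotopic pairs that were directly down-weighted
        assert fc_d[inter].mean() < fc_h[inter].mean()
        assert (fc_h[homo].mean() - fc_d[homo].mean()
                > fc_h[inter & ~homo].mean() - fc_d[inter & ~homo].mean())


class TestSimulateSeries:
    def test_white_noise_limit(self):
        from latentflow.synthetic import CouplingMatrix

        zero = CouplingMatrix(np.zeros((4, 4)), np.zeros(4, int),
                              np.array([0, 0, 1, 1]), 0.9)
        s = simulate_series(zero, 5000, seed=0)
        z = zscore_rows(s).data
        lag1 = z[:, :-1] @ z[:, 1:].T / (z.shape[1] - 1)
        assert np.all(np.abs(lag1) < 0.05)

    def test_deterministic_under_seed(self):
        c = build_coupling(10, 2, seed=0)
        a = simulate_series(c, 100, seed=42)
        b = simulate_series(c, 100, seed=42)
        np.testing.assert_array_equal(a.data, b.data)

    def test_rejects_unstable_coupling(self):
        from latentflow.synthetic import CouplingMatrix

        w = np.eye(4) * 1.1
        c = CouplingMatrix(w, np.zeros(4, int), np.array([0, 0, 1, 1]), 0.9)
        with pytest.raises(ValueError, match="unstable"):
            simulate_series(c, 100)

    def test_matches_analytic_var1_covariance(self):
        # closed-form Lyapunov oracle for the lag-1 correlation
        from latentflow.synthetic import CouplingMatrix

        w = np.array([[0.9, 0.4], [0.0, 0.9]])
        c = CouplingMatrix(w, np.zeros(2, int), np.array([0, 1]), 0.95)
        s = simulate_series(c, 20000, seed=5, burn_in=500)
        cov = var1_stationary_cov(w)
        d = np.sqrt(np.diag(cov))
        # corr(x_i(t), x_j(t+1)) = (W S)_{ji} / (d_i d_j)
        expected = (w @ cov).T / np.outer(d, d)
        x = s.data
        xc = x - x.mean(1, keepdims=True)
        emp = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                emp[i, j] = np.corrcoef(x[i, :-1], x[j, 1:])[0, 1]
        np.testing.assert_allclose(emp, expected, atol=0.02)

    def test_variance_stability(self):
        c = build_coupling(20, 2, seed=0)
        s = simulate_series(c, 896, seed=1)
        assert variance_stable(s)


class TestGenerateCohort:
    def test_reproducible(self):
        params = CohortParams(n_controls=2, n_patients=2, n_roi=10,
                              n_frames=60)
        a = generate_cohort(params, seed=3)
        b = generate_cohort(params, seed=3)
        for key in a.series:
            np.testing.assert_array_equal(a.series[key].data,
                                          b.series[key].data)
        assert [r.severity for r in a.records] == [r.severity for r in b.records]

    def test_control_invariants(self, small_cohort):
        for rec in small_cohort.controls():
            assert rec.severity == 0 and rec.lesion_volume == 0 and rec.nihss == 0
        for rec in small_cohort.patients():
            assert rec.severity > 0

    def test_control_behavior_distribution(self):
        params = CohortParams(n_controls=25, n_patients=2, n_roi=8,
                              n_frames=40)
        cohort = generate_cohort(params, seed=9)
        scores = np.array([
            [rec.behavior[tp][d] for d in BEHAVIOR_DOMAINS
             for tp in params.timepoints]
            for rec in cohort.controls()]).ravel()
        assert abs(scores.mean()) < 0.1
        assert 0.4 < scores.std() < 0.6

    def test_severity_decays_over_followup(self, small_cohort):
        for rec in small_cohort.patients():
            assert rec.severity_at("1yr") < rec.severity_at("2wk")

    def test_severity_anticorrelates_with_behavioral_recovery(self, desk_cohort):
        recs = desk_cohort.patients()
        sev = [r.severity for r in recs]
        recovery = [mean_deficit_change(r) for r in recs]
        r, _ = stats.pearsonr(sev, recovery)
        assert r < -0.3        # severe patients shed more deficit magnitude

    def test_roundtrip_to_disk(self, tmp_path):
        params = CohortParams(n_controls=2, n_patients=2, n_roi=8,
                              n_frames=30)
        cohort = generate_cohort(params, seed=5)
        write_cohort(cohort, tmp_path)
        back = read_cohort(tmp_path)
        assert len(back.records) == 4
        for key in cohort.series:
            np.testing.assert_allclose(back.series[key].data,
                                       cohort.series[key].data)
        np.testing.assert_allclose(back.sc_template, cohort.sc_template)
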