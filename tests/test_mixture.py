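"""Mixture core: trajectory arithmetic, mixture likelihood vs brute force,
EM fitting and recovery, BIC, posterior assignment."""

import numpy as np
import pytest

from multitraj import (EmptySubjectError, MultiTrajModel, PanelData,
                       ScaleSpec, bic, fit_multitrajectory, generate_cohort,
                       group_membership_probs, posterior_assignments,
                       select_model, subject_loglik, trajectory_mean)
from multitraj.censnorm import censored_normal_loglik
from multitraj.mixture import design_matrix

from conftest import assert_em_monotone, small_config


@pytest.mark.parametrize("coeffs, age, want", [
    ((10, 0, 0), 11, 10.0),
    ((0, 1, 0), 13, 2.0),
    ((1, 2, 3), 13, 17.0),     # 1 + 2*2 + 3*4 on c = age - 11
])
def test_trajectory_mean_examples(coeffs, age, want):
    assert trajectory_mean(np.array(coeffs, float), age) == pytest.approx(want)


def test_trajectory_mean_rejects_nonfinite():
    with pytest.raises(ValueError):
        trajectory_mean(np.array([1.0, np.nan, 0.0]), 10)


class TestMembershipProbs:
    @pytest.mark.parametrize("theta, want", [
        ((0, 0), (0.5, 0.5)),
        ((0, 0, 0), (1 / 3, 1 / 3, 1 / 3)),
        ((np.log(2), 0), (2 / 3, 1 / 3)),
    ])
    def test_examples(self, theta, want):
        np.testing.assert_allclose(group_membership_probs(theta), want, atol=1e-12)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            th = rng.normal(size=4) * 5
            c = rng.normal() * 10
            np.testing.assert_allclose(group_membership_probs(th),
                                       group_membership_probs(th + c), atol=1e-12)


def _toy_model(J=2):
    scales = [ScaleSpec("a", 0.0, 30.0), ScaleSpec("b", 0.0, 50.0)]
    ages = np.array([9.0, 13.0])
    coeffs = np.array([
        [[10.0, 0.5, 0.0], [20.0, -1.0, 0.1]],
        [[15.0, -0.3, 0.05], [25.0, 0.8, 0.0]],
        [[12.0, 0.0, 0.2], [18.0, 0.0, 0.0]],
    ])[:J]
    theta = np.array([0.0, 0.4, -0.3])[:J]
    sigma = np.array([2.0, 3.0])
    return MultiTrajModel(theta=theta - theta[0], coeffs=coeffs, sigma=sigma,
                          scales=scales, ages=ages)


def _toy_panel(scores):
    scales = [ScaleSpec("a", 0.0, 30.0), ScaleSpec("b", 0.0, 50.0)]
    return PanelData(np.arange(len(scores)), np.array([9.0, 13.0]), scales,
                     np.asarray(scores, float))


def _brute_force_subject_ll(panel, model):
    """Naive direct summation oracle: explicit loops, plain arithmetic."""
    out = []
    pi = np.exp(model.theta) / np.exp(model.theta).sum()
    for i in range(panel.n_subjects):
        total = 0.0
        for j in range(model.n_groups):
            term = pi[j]
            for k, s in enumerate(panel.scales):
                for t, age in enumerate(panel.ages):
                    y = panel.scores[i, k, t]
                    if np.isnan(y):
                        continue
                    c = age - 11.0
                    mu = (model.coeffs[j, k, 0] + model.coeffs[j, k, 1] * c
                          + model.coeffs[j, k, 2] * c * c)
                    term *= np.exp(float(censored_normal_loglik(
                        y, mu, model.sigma[k], s.lo, s.hi)))
            total += term
        out.append(np.log(total))
    return np.array(out)


class TestSubjectLoglik:
    def test_matches_brute_force_oracle(self):
        model = _toy_model(J=2)
        panel = _toy_panel([
            [[11.0, 14.0], [22.0, 19.0]],
            [[0.0, 30.0], [50.0, 25.0]],       # boundary values
            [[np.nan, 14.0], [22.0, np.nan]],  # partial missingness
        ])
        got = subject_loglik(panel, model)
        want = _brute_force_subject_ll(panel, model)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_single_group_reduces_to_emission_sum(self):
        model = _toy_model(J=1)
        panel = _toy_panel([[[11.0, 14.0], [22.0, 19.0]]])
        got = subject_loglik(panel, model)[0]
        want = 0.0
        for k, s in enumerate(panel.scales):
            for t, age in enumerate(panel.ages):
                mu = trajectory_mean(model.coeffs[0, k], age)
                want += float(censored_normal_loglik(
                    panel.scores[0, k, t], mu, model.sigma[k], s.lo, s.hi))
        assert got == pytest.approx(want, abs=1e-10)

    def test_identical_groups_equal_single_group(self):
        m1 = _toy_model(J=1)
        m3 = _toy_model(J=3)
        m3.coeffs = np.repeat(m1.coeffs, 3, axis=0)
        m3.theta = np.array([0.0, 1.0, -2.0])  # arbitrary weights, same emissions
        panel = _toy_panel([[[11.0, 14.0], [22.0, 19.0]],
                            [[5.0, 25.0], [10.0, 40.0]]])
        np.testing.assert_allclose(subject_loglik(panel, m3),
                                   subject_loglik(panel, m1), atol=1e-10)

    def test_empty_subject_rejected(self):
        panel = _toy_panel([[[np.nan, np.nan], [np.nan, np.nan]]])
        with pytest.raises(EmptySubjectError):
            subject_loglik(panel, _toy_model())

    def test_group_relabelling_invariance(self):
        model = _toy_model(J=3)
        panel = _toy_panel([[[11.0, 14.0], [22.0, 19.0]],
                            [[5.0, 25.0], [10.0, 40.0]]])
        perm = np.array([2, 0, 1])
        np.testing.assert_allclose(subject_loglik(panel, model.relabelled(perm)),
                                   subject_loglik(panel, model), atol=1e-9)


class TestBic:
    def test_arithmetic(self):
        m = _toy_model(J=1)
        m.loglik = -100.0
        assert bic(m, 100) == pytest.approx(200.0 + m.n_params * np.log(100))
        # a 5-parameter model with loglik -100 on n=100: 200 + 5 log 100
        assert 200.0 + 5 * np.log(100) == pytest.approx(223.0259, abs=1e-4)
        m.loglik = 0.0
        assert bic(m, 100) == pytest.approx(m.n_params * np.log(100))

    def test_extra_parameters_add_log_n_each(self):
        m_shared, m_free = _toy_model(J=2), _toy_model(J=2)
        m_shared.loglik = m_free.loglik = -50.0
        m_free.sigma_shared = False
        m_free.sigma = np.tile(m_shared.sigma, (2, 1))
        n = 250
        extra = m_free.n_params - m_shared.n_params
        assert extra == 2   # per-group residual SDs free two parameters here
        assert bic(m_free, n) - bic(m_shared, n) == pytest.approx(extra * np.log(n))


class TestFit:
    def test_single_group_parameter_recovery(self):
        cfg = small_config(n=500, J=1, sigma=2.0)
        cfg.groups[0].coeffs = np.array([[22.0, 0.8, -0.1]])
        panel, _, _ = generate_cohort(cfg, seed=21)
        m = fit_multitrajectory(panel, 1, seed=0, n_starts=1)
        assert_em_monotone(m)
        # SE oracle: information of an (uncensored) polynomial regression;
        # censoring is negligible for this configuration
        X = design_matrix(panel.ages, 2)
        XtX_inv = np.linalg.inv(X.T @ X * panel.n_subjects)
        se = 2.0 * np.sqrt(np.diag(XtX_inv))
        err = np.abs(m.coeffs[0, 0] - cfg.groups[0].coeffs[0])
        assert np.all(err < 3 * se)
        assert m.sigma[0] == pytest.approx(2.0, rel=0.1)

    def test_two_group_proportion_recovery(self):
        # groups separated by 4 sigma at every wave
        cfg = small_config(n=400, J=2, sep=8.0, sigma=2.0)
        panel, _, truth = generate_cohort(cfg, seed=22)
        m = fit_multitrajectory(panel, 2, seed=1, n_starts=2)
        assert_em_monotone(m)
        assert abs(np.sort(m.pi)[0] - 0.5) < 0.06

    def test_subject_order_permutation_invariance(self):
        cfg = small_config(n=200, J=2, sep=8.0)
        panel, _, _ = generate_cohort(cfg, seed=23)
        m = fit_multitrajectory(panel, 2, seed=2, n_starts=2)
        perm = np.random.default_rng(3).permutation(panel.n_subjects)
        shuffled = PanelData(panel.subject_ids[perm], panel.ages,
                             list(panel.scales), panel.scores[perm])
        m2 = fit_multitrajectory(shuffled, 2, init=m)
        assert m2.loglik == pytest.approx(m.loglik, abs=1e-6)

    def test_warm_start_never_hurts(self):
        cfg = small_config(n=150, J=2, sep=6.0)
        panel, _, _ = generate_cohort(cfg, seed=24)
        m = fit_multitrajectory(panel, 2, seed=4, n_starts=2)
        m2 = fit_multitrajectory(panel, 2, init=m)
        assert m2.loglik >= m.loglik - 1e-8

    def test_invalid_group_count_rejected(self):
        cfg = small_config(n=50)
        panel, _, _ = generate_cohort(cfg, seed=1)
        with pytest.raises(ValueError):
            fit_multitrajectory(panel, 0)


class TestPosterior:
    def test_identical_groups_posterior_equals_prior(self):
        m3 = _toy_model(J=3)
        m3.coeffs = np.repeat(_toy_model(J=1).coeffs, 3, axis=0)
        m3.theta = np.array([0.0, 0.7, -0.2])
        panel = _toy_panel([[[11.0, 14.0], [22.0, 19.0]],
                            [[5.0, 25.0], [10.0, 40.0]]])
        pa = posterior_assignments(panel, m3)
        for row in pa.probs:
            np.testing.assert_allclose(row, m3.pi, atol=1e-12)

    def test_rows_sum_to_one(self):
        cfg = small_config(n=80, J=2)
        panel, _, _ = generate_cohort(cfg, seed=30)
        m = fit_multitrajectory(panel, 2, seed=5, n_starts=1)
        pa = posterior_assignments(panel, m)
        np.testing.assert_allclose(pa.probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(pa.app[np.isfinite(pa.app)] >= 1 / 2 - 1e-12)

    def test_distant_subject_assigned_confidently(self):
        # one subject sits > 6 sigma from every group profile but one
        model = _toy_model(J=2)
        model.sigma = np.array([1.0, 1.0])
        mu0 = model.predicted_means()[0]
        panel = _toy_panel([np.clip(mu0, 0.5, 29.5)])
        pa = posterior_assignments(panel, model)
        assert pa.probs[0, 0] > 0.99


class TestSelectModel:
    def test_table_has_one_row_per_candidate(self):
        cfg = small_config(n=150, J=2, sep=8.0)
        panel, _, _ = generate_cohort(cfg, seed=31)
        table, chosen, models = select_model(panel, [1, 2], seed=6,
                                             n_starts=1, max_iter=80)
        assert list(table["J"]) == [1, 2]
        assert chosen in (1, 2)
        assert set(models) <= {1, 2}
        for m in models.values():
            assert_em_monotone(m)
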