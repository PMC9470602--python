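"""Joint distal-outcome model: likelihood reduction/factorisation, the
brute-force oracle, warm-start guarantees, equivariance, stability check."""

import numpy as np
import pandas as pd
import pytest

from multitraj import (fit_joint, fit_multitrajectory, generate_cohort,
                       joint_posteriors, joint_subject_loglik,
                       posterior_assignments, subject_loglik,
                       trajectory_stability_check)
from multitraj.distal import JointModel

from conftest import assert_em_monotone, small_config

from test_mixture import _toy_model, _toy_panel


def _toy_joint(J=2, means=None, sd=1.5):
    base = _toy_model(J)
    means = np.array([[4.0], [7.0], [5.0]])[:J] if means is None else means
    return JointModel(base=base, outcome_names=["out"],
                      outcome_means=means, outcome_sd=np.array([sd]))


def _outcomes_frame(panel, values):
    return pd.DataFrame({"out": values}, index=pd.Index(panel.subject_ids,
                                                        name="subject_id"))


class TestJointLoglik:
    def test_no_outcomes_reduces_to_trajectory_loglik(self):
        panel = _toy_panel([[[11.0, 14.0], [22.0, 19.0]],
                            [[5.0, 25.0], [10.0, 40.0]]])
        jm = _toy_joint()
        z = _outcomes_frame(panel, [np.nan, np.nan])
        np.testing.assert_allclose(joint_subject_loglik(panel, z, jm),
                                   subject_loglik(panel, jm.base), atol=1e-12)

    def test_shared_outcome_means_factorise(self):
        # identical means across groups: outcome shifts the loglik but not
        # the group posterior
        panel = _toy_panel([[[11.0, 14.0], [22.0, 19.0]],
                            [[5.0, 25.0], [10.0, 40.0]]])
        jm = _toy_joint(means=np.array([[5.0], [5.0]]))
        z = _outcomes_frame(panel, [4.2, 6.1])
        post_joint = joint_posteriors(panel, z, jm)
        post_traj = posterior_assignments(panel, jm.base).probs
        np.testing.assert_allclose(post_joint, post_traj, atol=1e-12)

    def test_matches_brute_force_two_term_sum(self):
        panel = _toy_panel([[[11.0, 14.0], [22.0, 19.0]]])
        jm = _toy_joint()
        z = _outcomes_frame(panel, [5.5])
        got = joint_subject_loglik(panel, z, jm)[0]

        pi = jm.base.pi
        traj = subject_loglik(panel, jm.base)  # not usable directly; redo per group
        total = 0.0
        for j in range(2):
            emis = 0.0
            from multitraj import trajectory_mean
            from multitraj.censnorm import censored_normal_loglik
            for k, s in enumerate(panel.scales):
                for t, age in enumerate(panel.ages):
                    mu = trajectory_mean(jm.base.coeffs[j, k], age)
                    emis += float(censored_normal_loglik(
                        panel.scores[0, k, t], mu, jm.base.sigma[k], s.lo, s.hi))
            out_ll = (-np.log(jm.outcome_sd[0])
                      - 0.5 * ((5.5 - jm.outcome_means[j, 0]) / jm.outcome_sd[0]) ** 2
                      - 0.5 * np.log(2 * np.pi))
            total += pi[j] * np.exp(emis + out_ll)
        assert got == pytest.approx(np.log(total), abs=1e-10)

    def test_outcome_information_removed_recovers_trajectory_posterior(self):
        cfg = small_config(n=120, J=2, sep=7.0)
        panel, outcomes, _ = generate_cohort(cfg, seed=40)
        tm = fit_multitrajectory(panel, 2, seed=7, n_starts=1)
        jm = fit_joint(panel, outcomes, 2, start=tm, compute_se=False)
        post_no_out = joint_posteriors(panel, None, jm)
        np.testing.assert_allclose(
            post_no_out, posterior_assignments(panel, jm.base).probs, atol=1e-9)


class TestFitJoint:
    def test_joint_loglik_at_least_warm_start(self):
        cfg = small_config(n=200, J=2, sep=6.0, outcome_gap=2.0)
        panel, outcomes, _ = generate_cohort(cfg, seed=41)
        tm = fit_multitrajectory(panel, 2, seed=8, n_starts=2)
        jm = fit_joint(panel, outcomes, 2, start=tm)
        assert jm.loglik >= jm.loglik_start - 1e-8
        trace = np.asarray(jm.loglik_trace)
        assert np.diff(trace).min() > -1e-8

    def test_group_mean_recovery_with_separated_outcomes(self):
        cfg = small_config(n=400, J=2, sep=8.0, outcome_gap=3.0, outcome_sd=1.0)
        panel, outcomes, truth = generate_cohort(cfg, seed=42)
        tm = fit_multitrajectory(panel, 2, seed=9, n_starts=2)
        jm = fit_joint(panel, outcomes, 2, start=tm)
        got = np.sort(jm.outcome_means[:, 0])
        np.testing.assert_allclose(got, [10.0, 13.0], atol=0.4)
        assert jm.se_available
        assert np.all(jm.outcome_se > 0)

    def test_scaling_outcomes_scales_means_and_sd(self):
        cfg = small_config(n=150, J=2, sep=7.0, outcome_gap=2.0)
        panel, outcomes, _ = generate_cohort(cfg, seed=43)
        tm = fit_multitrajectory(panel, 2, seed=10, n_starts=1)
        jm1 = fit_joint(panel, outcomes, 2, start=tm, compute_se=False)
        jm2 = fit_joint(panel, outcomes * 2.0, 2, start=tm, compute_se=False)
        np.testing.assert_allclose(jm2.outcome_means, 2 * jm1.outcome_means,
                                   rtol=1e-6)
        np.testing.assert_allclose(jm2.outcome_sd, 2 * jm1.outcome_sd, rtol=1e-6)

    def test_mismatched_group_count_rejected(self):
        cfg = small_config(n=60, J=2)
        panel, outcomes, _ = generate_cohort(cfg, seed=44)
        tm = fit_multitrajectory(panel, 2, seed=11, n_starts=1)
        with pytest.raises(ValueError):
            fit_joint(panel, outcomes, 3, start=tm)


class TestStabilityCheck:
    def test_identity_when_outcomes_merely_appended(self):
        jm = _toy_joint()
        rep = trajectory_stability_check(jm.base, jm)
        assert rep.max_abs_diff == 0.0
        assert rep.passed

    def test_label_permutation_invariance(self):
        jm = _toy_joint(J=2)
        rep1 = trajectory_stability_check(jm.base, jm)
        rep2 = trajectory_stability_check(jm.base, jm.relabelled(np.array([1, 0])))
        assert rep1.max_abs_diff == pytest.approx(rep2.max_abs_diff, abs=1e-12)

    def test_group_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            trajectory_stability_check(_toy_model(J=3), _toy_joint(J=2))

    def test_joint_refit_preserves_trajectories(self):
        cfg = small_config(n=300, J=2, sep=8.0, outcome_gap=2.0)
        panel, outcomes, _ = generate_cohort(cfg, seed=45)
        tm = fit_multitrajectory(panel, 2, seed=12, n_starts=2)
        jm = fit_joint(panel, outcomes, 2, start=tm)
        rep = trajectory_stability_check(tm, jm, tol=1.0)
        assert rep.passed, f"max diff {rep.max_abs_diff}"


class TestNullCalibration:
    def test_ci_screen_rarely_flags_null_outcome_differences(self):
        """With zero true group-mean gap, non-overlap of 95% CIs should
        almost never fire (it is a conservative screen), and group means
        should sit within 3 pooled SEs of each other in nearly all runs."""
        from multitraj import ci_from_pooled, compare_groups_ci

        n_reps = 20
        flags = 0
        within_3se = 0
        for rep in range(n_reps):
            cfg = small_config(n=250, J=2, sep=7.0, outcome_gap=0.0,
                               outcome_sd=1.5)
            panel, outcomes, _ = generate_cohort(cfg, seed=100 + rep)
            tm = fit_multitrajectory(panel, 2, seed=rep, n_starts=1)
            jm = fit_joint(panel, outcomes, 2, start=tm)
            if not jm.se_available:
                continue
            cis = [ci_from_pooled(jm.outcome_means[j, 0], jm.outcome_se[j, 0])
                   for j in range(2)]
            sig = compare_groups_ci(cis)
            flags += int(sig[0, 1])
            gap = abs(jm.outcome_means[0, 0] - jm.outcome_means[1, 0])
            pooled_se = np.sqrt((jm.outcome_se[:, 0] ** 2).sum())
            within_3se += int(gap < 3 * pooled_se)
        assert flags / n_reps < 0.05
        assert within_3se / n_reps >= 0.90
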