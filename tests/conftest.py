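import numpy as np
import pytest

from multitraj.config import (CohortConfig, GroupTruth, MissingnessSpec,
                              OutcomeTruth, ScaleSpec)


def small_config(n=300, J=2, sep=6.0, sigma=2.0, n_ages=6,
                 outcome_gap=2.0, outcome_sd=1.0, seed=0,
                 missing_rate=0.0):
    """A one-phenotype, well-separated test cohort; cheap to fit."""
    ages = np.arange(7.0, 7.0 + n_ages)
    scale = ScaleSpec("symptom", 0.0, 60.0)
    groups = []
    for j in range(J):
        groups.append(GroupTruth(
            name=f"g{j}", proportion=1.0 / J,
            coeffs=np.array([[20.0 + j * sep, 0.3 * (j - (J - 1) / 2), 0.0]]),
            sigma=np.array([sigma])))
    outcomes = [OutcomeTruth("out", group_means=10.0 + outcome_gap * np.arange(J),
                             sd=outcome_sd)]
    missing = None
    if missing_rate > 0:
        missing = MissingnessSpec(
            target_rates=np.full((1, n_ages), missing_rate), gamma=0.3)
    return CohortConfig(n_subjects=n, ages=ages, groups=groups,
                        scales=[scale], outcomes=outcomes,
                        missingness=missing, seed=seed)


def assert_em_monotone(model, tol=1e-8):
    """EM log-likelihood must never decrease (within tolerance)."""
    trace = np.asarray(model.loglik_trace)
    assert trace.size >= 1
    if trace.size > 1:
        assert np.diff(trace).min() > -tol, (
            f"EM decreased by {-np.diff(trace).min():.3e}")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
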