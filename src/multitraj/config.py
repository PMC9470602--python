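"""Study-design configuration: scales, latent groups, outcomes, missingness.

The default configuration (:func:`default_cohort_config`) emulates a
community cohort of n = 1620 children assessed at ages 7, 8, 9, 10, 11, 12,
13 and 15 on three teacher-rated symptom composites — ADHD (7–35),
internalising problems (7–35) and externalising problems (17–85) — with six
latent trajectory groups, wave-specific missingness and twelve age-20 distal
outcomes. Trajectory polynomial coefficients are evaluated on centered age
``c = age - 11``.

The six default group trajectory-coefficient sets are synthetic package
defaults shaped to the qualitative group profiles (flat-low; mildly elevated
and maturing out; stably elevated internalising only; multimorbid late
onset; multimorbid remitting; multimorbid with remitting externalising) —
they are not estimates from any dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

AGE_CENTER = 11.0


@dataclass(frozen=True)
class ScaleSpec:
    """A bounded sum-score scale; ``lo``/``hi`` are the censoring bounds."""

    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"scale {self.name}: lo must be < hi")


@dataclass
class GroupTruth:
    """Generating parameters for one latent trajectory group.

    ``coeffs`` has shape (K phenotypes, order+1): polynomial coefficients
    (intercept, linear, quadratic, ...) on centered age. ``sigma`` is the
    per-phenotype residual SD of the latent (pre-censoring) score.
    """

    name: str
    proportion: float
    coeffs: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.coeffs = np.atleast_2d(np.asarray(self.coeffs, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if not 0 < self.proportion <= 1:
            raise ValueError(f"group {self.name}: proportion must be in (0,1]")
        if np.any(self.sigma <= 0):
            raise ValueError(f"group {self.name}: sigma must be > 0")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError(f"group {self.name}: non-finite coefficients")


@dataclass
class OutcomeTruth:
    """A distal outcome with group-specific generating means."""

    name: str
    group_means: np.ndarray
    sd: float
    observed_fraction: float = 1.0

    def __post_init__(self):
        self.group_means = np.asarray(self.group_means, dtype=float)
        if self.sd <= 0:
            raise ValueError(f"outcome {self.name}: sd must be > 0")
        if not 0 < self.observed_fraction <= 1:
            raise ValueError(f"outcome {self.name}: observed_fraction must be in (0,1]")


@dataclass
class MissingnessSpec:
    """MAR deletion mechanism for phenotype-wave observations.

    Each observation is deleted with probability
    ``logistic(alpha_{k,t} + gamma * z_prev)`` where ``z_prev`` is the
    subject's most recent *observed* prior-wave score of the same phenotype,
    standardised (0 if no prior wave is observed). The intercepts
    ``alpha_{k,t}`` are calibrated so the marginal per-wave deletion rate
    matches ``target_rates[k, t]``.

    ``monotone=True`` switches to dropout: once a phenotype is missing for a
    subject it stays missing at all later waves (requires non-decreasing
    target rates).
    """

    target_rates: np.ndarray  # (K, T)
    gamma: float = 0.3
    monotone: bool = False

    def __post_init__(self):
        self.target_rates = np.atleast_2d(np.asarray(self.target_rates, dtype=float))
        if np.any(self.target_rates < 0) or np.any(self.target_rates >= 1):
            raise ValueError("missingness target rates must lie in [0, 1)")


@dataclass
class CohortConfig:
    n_subjects: int
    ages: np.ndarray
    groups: list[GroupTruth]
    scales: list[ScaleSpec]
    outcomes: list[OutcomeTruth] = field(default_factory=list)
    missingness: MissingnessSpec | None = None
    seed: int = 0
    lognormal_outcomes: bool = False

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        total = sum(g.proportion for g in self.groups)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"group proportions must sum to 1 (got {total!r})")
        K = len(self.scales)
        for g in self.groups:
            if g.coeffs.shape[0] != K or g.sigma.shape[0] != K:
                raise ValueError(f"group {g.name}: expected parameters for {K} phenotypes")
        J = len(self.groups)
        for o in self.outcomes:
            if o.group_means.shape[0] != J:
                raise ValueError(f"outcome {o.name}: expected {J} group means")
        if self.missingness is not None:
            if self.missingness.target_rates.shape != (K, len(self.ages)):
                raise ValueError("missingness target_rates must have shape (n_phenotypes, n_ages)")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def proportions(self) -> np.ndarray:
        return np.array([g.proportion for g in self.groups])

    # ---- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["ages"] = [float(a) for a in self.ages]
        for g in d["groups"]:
            g["coeffs"] = np.asarray(g["coeffs"]).tolist()
            g["sigma"] = np.asarray(g["sigma"]).tolist()
        for o in d["outcomes"]:
            o["group_means"] = np.asarray(o["group_means"]).tolist()
        if d["missingness"] is not None:
            d["missingness"]["target_rates"] = np.asarray(
                d["missingness"]["target_rates"]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        d.pop("analysis", None)   # analysis-stage settings live elsewhere
        d["groups"] = [GroupTruth(**g) for g in d.get("groups", [])]
        d["scales"] = [ScaleSpec(**s) for s in d.get("scales", [])]
        d["outcomes"] = [OutcomeTruth(**o) for o in d.get("outcomes", [])]
        if d.get("missingness") is not None:
            d["missingness"] = MissingnessSpec(**d["missingness"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Default study-like configuration
# ---------------------------------------------------------------------------

DEFAULT_AGES = (7.0, 8.0, 9.0, 10.0, 11.0, 12.0, 13.0, 15.0)
DEFAULT_N = 1620

# Printed group shares; they total 0.999 at 3 dp and are renormalised below.
_GROUP_SHARES = {
    "unaffected": 0.325,
    "normative_maturing": 0.279,
    "internalising": 0.106,
    "multimorbid_late_onset": 0.135,
    "multimorbid_remitting": 0.120,
    "multimorbid_remitting_externalising": 0.034,
}

# Per-wave observed counts (of 1620) used to calibrate MAR deletion rates.
_WAVE_NS = {
    "adhd": (1312, 1305, 1283, 1252, 1053, 970, 1242, 1276),
    "internalising": (1302, 1303, 1281, 1240, 1034, 967, 1232, 1265),
    "externalising": (1263, 1266, 1240, 1213, 1039, 953, 1207, 1221),
}

# Synthetic default trajectory shapes on centered age (intercept, linear,
# quadratic) per phenotype (adhd, internalising, externalising).
_GROUP_COEFFS = {
    "unaffected": [[10.5, 0.0, 0.0], [10.5, 0.0, 0.0], [19.5, 0.0, 0.0]],
    "normative_maturing": [[13.0, -0.70, 0.05], [11.5, -0.45, 0.04], [24.0, -1.20, 0.08]],
    "internalising": [[11.5, 0.0, 0.0], [19.5, 0.20, 0.0], [21.0, 0.0, 0.0]],
    "multimorbid_late_onset": [[16.5, 1.30, 0.06], [14.5, 1.00, 0.05], [29.0, 2.20, 0.12]],
    "multimorbid_remitting": [[17.0, -1.50, 0.08], [14.5, -1.00, 0.06], [30.0, -2.00, 0.10]],
    "multimorbid_remitting_externalising": [[21.5, 0.0, 0.0], [18.5, 0.20, 0.0], [27.0, -2.40, 0.15]],
}

_GROUP_SIGMA = (4.0, 3.5, 5.0)  # residual SD per phenotype

# Distal outcomes: (name, group means in default group order, residual SD,
# observed count of 1620). Group means follow the reported young-adult
# group-mean profile for each outcome; SDs are marginal descriptive SDs.
_OUTCOMES = [
    ("social_exclusion", (9.94, 12.45, 12.16, 12.43, 12.33, 12.81), 3.54, 1176),
    ("optimism", (12.96, 11.70, 11.91, 11.98, 12.15, 12.11), 2.29, 1177),
    ("stress", (11.19, 12.16, 11.95, 11.64, 11.89, 12.14), 3.72, 1180),
    ("physical_ipv_perpetration", (6.99, 7.93, 7.90, 8.26, 8.00, 8.25), 1.03, 774),
    ("sexual_ipv_perpetration", (4.20, 4.44, 4.43, 4.55, 4.51, 4.54), 0.29, 774),
    ("psychological_ipv_perpetration", (3.82, 4.49, 4.48, 4.66, 4.57, 4.86), 0.99, 773),
    ("monitoring_ipv_perpetration", (6.54, 7.45, 7.59, 7.71, 7.58, 8.00), 2.38, 774),
    ("physical_ipv_victimisation", (7.44, 8.95, 8.75, 9.61, 9.44, 10.00), 1.35, 774),
    ("sexual_ipv_victimisation", (4.71, 5.41, 5.30, 5.56, 5.48, 5.82), 0.72, 775),
    ("psychological_ipv_victimisation", (4.26, 5.14, 5.05, 5.42, 5.49, 5.68), 1.47, 772),
    ("monitoring_ipv_victimisation", (6.87, 8.54, 8.59, 9.07, 8.86, 9.13), 2.95, 775),
    ("delinquency", (4.82, 7.33, 7.31, 8.97, 7.74, 7.94), 2.19, 1174),
]

DEFAULT_GROUP_ORDER = tuple(_GROUP_SHARES)


def default_cohort_config(n_subjects: int = DEFAULT_N, seed: int = 0,
                          with_missingness: bool = True,
                          outcome_names: Sequence[str] | None = None) -> CohortConfig:
    """Build the default six-group cohort configuration.

    Group shares are the printed shares renormalised to sum exactly to 1.
    ``outcome_names`` restricts the distal outcomes to a subset (order kept);
    default is all twelve.
    """
    share_total = sum(_GROUP_SHARES.values())
    groups = [
        GroupTruth(name=name, proportion=_GROUP_SHARES[name] / share_total,
                   coeffs=np.array(_GROUP_COEFFS[name]), sigma=np.array(_GROUP_SIGMA))
        for name in DEFAULT_GROUP_ORDER
    ]
    scales = [
        ScaleSpec("adhd", 7.0, 35.0),
        ScaleSpec("internalising", 7.0, 35.0),
        ScaleSpec("externalising", 17.0, 85.0),
    ]
    rows = _OUTCOMES
    if outcome_names is not None:
        by_name = {r[0]: r for r in _OUTCOMES}
        rows = [by_name[n] for n in outcome_names]
    outcomes = [
        OutcomeTruth(name=name, group_means=np.array(means), sd=sd,
                     observed_fraction=n_obs / DEFAULT_N)
        for name, means, sd, n_obs in rows
    ]
    missingness = None
    if with_missingness:
        rates = np.array([
            [1.0 - n / DEFAULT_N for n in _WAVE_NS[s.name]] for s in scales
        ])
        missingness = MissingnessSpec(target_rates=rates)
    return CohortConfig(
        n_subjects=n_subjects, ages=np.array(DEFAULT_AGES), groups=groups,
        scales=scales, outcomes=outcomes, missingness=missingness, seed=seed,
    )


# Back-compatible alias used in a few call sites
default_zproso_config = default_cohort_config
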