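"""Long-format longitudinal panel container.

``PanelData`` holds one bounded score per subject x phenotype x assessment
age on a shared age grid, with NaN marking missing observations. This is
the in-memory form every model in the package consumes; conversion to and
from the long delimited-text layout lives in :mod:`multitraj.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ScaleSpec


class EmptySubjectError(ValueError):
    """A subject contributes no non-missing observation."""


@dataclass
class PanelData:
    subject_ids: np.ndarray          # (n,)
    ages: np.ndarray                 # (T,) strictly increasing, shared grid
    scales: list[ScaleSpec]          # length K
    scores: np.ndarray               # (n, K, T), NaN = missing

    def __post_init__(self):
        self.subject_ids = np.asarray(self.subject_ids)
        self.ages = np.asarray(self.ages, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        n, K, T = self.scores.shape
        if len(self.subject_ids) != n or len(self.scales) != K or len(self.ages) != T:
            raise ValueError("inconsistent panel dimensions")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        for k, s in enumerate(self.scales):
            yk = self.scores[:, k, :]
            obs = yk[np.isfinite(yk)]
            if obs.size and (obs.min() < s.lo or obs.max() > s.hi):
                raise ValueError(f"scores outside bounds for scale {s.name}")

    @property
    def n_subjects(self) -> int:
        return self.scores.shape[0]

    @property
    def n_phenotypes(self) -> int:
        return self.scores.shape[1]

    @property
    def n_ages(self) -> int:
        return self.scores.shape[2]

    @property
    def phenotypes(self) -> list[str]:
        return [s.name for s in self.scales]

    def copy(self) -> "PanelData":
        return PanelData(self.subject_ids.copy(), self.ages.copy(),
                         list(self.scales), self.scores.copy())

    def observed_counts(self) -> np.ndarray:
        """Number of non-missing observations per phenotype x wave, (K, T)."""
        return np.isfinite(self.scores).sum(axis=0)

    def require_nonempty_subjects(self) -> None:
        obs = np.isfinite(self.scores).any(axis=(1, 2))
        if not obs.all():
            bad = self.subject_ids[~obs]
            raise EmptySubjectError(
                f"{len(bad)} subject(s) have no observations (e.g. {bad[:5].tolist()})")

    def to_long(self) -> pd.DataFrame:
        n, K, T = self.scores.shape
        df = pd.DataFrame({
            "subject_id": np.repeat(self.subject_ids, K * T),
            "age": np.tile(np.repeat(self.ages, 1), n * K),
            "phenotype": np.tile(np.repeat(self.phenotypes, T), n),
            "score": self.scores.reshape(-1),
        })
        return df

    @classmethod
    def from_long(cls, df: pd.DataFrame, scales: list[ScaleSpec]) -> "PanelData":
        names = [s.name for s in scales]
        unknown = set(df["phenotype"]) - set(names)
        if unknown:
            raise ValueError(f"unknown phenotype label(s): {sorted(unknown)}")
        dup = df.duplicated(subset=["subject_id", "age", "phenotype"])
        if dup.any():
            rows = df.index[dup][:5].tolist()
            raise ValueError(f"duplicate subject-age-phenotype rows at index {rows}")
        subjects = pd.unique(df["subject_id"])
        ages = np.sort(pd.unique(df["age"].astype(float)))
        n, K, T = len(subjects), len(scales), len(ages)
        sub_idx = pd.Series(np.arange(n), index=subjects)
        age_idx = pd.Series(np.arange(T), index=ages)
        phe_idx = pd.Series(np.arange(K), index=names)
        scores = np.full((n, K, T), np.nan)
        i = sub_idx[df["subject_id"]].to_numpy()
        k = phe_idx[df["phenotype"]].to_numpy()
        t = age_idx[df["age"].astype(float)].to_numpy()
        scores[i, k, t] = df["score"].to_numpy(dtype=float)
        return cls(np.asarray(subjects), ages, list(scales), scores)
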