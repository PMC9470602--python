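"""Delimited-text readers/writers, model serialisation and run manifests.

Column contracts
----------------
panel:     ``subject_id, age, phenotype, score`` (empty score = missing)
outcomes:  ``subject_id, outcome, value`` (empty value = missing)
truth:     ``subject_id, group``
models:    JSON with all parameters; manifests: JSON with config snapshot,
           seeds, stage timings and sha256 digests of every artifact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ScaleSpec
from .distal import JointModel
from .mixture import MultiTrajModel
from .panel import PanelData


# ---------------------------------------------------------------------------
# Panel / outcomes text IO
# ---------------------------------------------------------------------------

def write_panel(panel: PanelData, path) -> None:
    df = panel.to_long()
    df.to_csv(path, index=False)


def read_panel(path, scales: list[ScaleSpec]) -> PanelData:
    """Read and validate a long-format panel file.

    Rejects unknown phenotype labels, duplicate subject-age-phenotype rows,
    non-numeric ages, and out-of-bounds scores (naming offending rows).
    Empty score cells become missing values.
    """
    df = pd.read_csv(path)
    required = {"subject_id", "age", "phenotype", "score"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"panel file missing column(s): {sorted(missing_cols)}")
    ages = pd.to_numeric(df["age"], errors="coerce")
    if ages.isna().any():
        rows = (df.index[ages.isna()] + 2)[:5].tolist()   # 1-based incl. header
        raise ValueError(f"non-numeric age at file line(s) {rows}")
    df["age"] = ages
    df["score"] = pd.to_numeric(df["score"], errors="coerce")
    by_name = {s.name: s for s in scales}
    for name, sub in df.groupby("phenotype"):
        if name not in by_name:
            raise ValueError(f"unknown phenotype label: {name!r}")
        s = by_name[name]
        bad = sub["score"].notna() & ((sub["score"] < s.lo) | (sub["score"] > s.hi))
        if bad.any():
            rows = (sub.index[bad] + 2)[:5].tolist()
            raise ValueError(
                f"score outside [{s.lo}, {s.hi}] for {name} at file line(s) {rows}")
    return PanelData.from_long(df, scales)


def write_outcomes(outcomes: pd.DataFrame, path) -> None:
    long = outcomes.reset_index().melt(id_vars="subject_id", var_name="outcome",
                                       value_name="value")
    long.to_csv(path, index=False)


def read_outcomes(path) -> pd.DataFrame:
    long = pd.read_csv(path)
    wide = long.pivot(index="subject_id", columns="outcome", values="value")
    # preserve first-appearance column order from the file
    order = list(pd.unique(long["outcome"]))
    return wide[order]


def write_truth(labels: np.ndarray, subject_ids: np.ndarray, path) -> None:
    pd.DataFrame({"subject_id": subject_ids, "group": labels}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Model JSON serialisation
# ---------------------------------------------------------------------------

def model_to_dict(model: MultiTrajModel) -> dict:
    return {
        "theta": model.theta.tolist(),
        "coeffs": model.coeffs.tolist(),
        "sigma": model.sigma.tolist(),
        "sigma_shared": model.sigma_shared,
        "scales": [{"name": s.name, "lo": s.lo, "hi": s.hi} for s in model.scales],
        "ages": model.ages.tolist(),
        "order": model.order,
        "loglik": None if np.isnan(model.loglik) else model.loglik,
        "converged": model.converged,
        "n_iter": model.n_iter,
        "n_restarts": model.n_restarts,
    }


def model_from_dict(d: dict) -> MultiTrajModel:
    return MultiTrajModel(
        theta=np.array(d["theta"]), coeffs=np.array(d["coeffs"]),
        sigma=np.array(d["sigma"]), sigma_shared=d.get("sigma_shared", True),
        scales=[ScaleSpec(**s) for s in d["scales"]], ages=np.array(d["ages"]),
        order=d["order"],
        loglik=np.nan if d.get("loglik") is None else d["loglik"],
        converged=d.get("converged", False), n_iter=d.get("n_iter", 0),
        n_restarts=d.get("n_restarts", 0))


def save_model(model: MultiTrajModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def load_model(path) -> MultiTrajModel:
    return model_from_dict(json.loads(Path(path).read_text()))


def joint_model_to_dict(model: JointModel) -> dict:
    return {
        "base": model_to_dict(model.base),
        "outcome_names": model.outcome_names,
        "outcome_means": model.outcome_means.tolist(),
        "outcome_sd": model.outcome_sd.tolist(),
        "outcome_se": None if model.outcome_se is None
        else np.where(np.isfinite(model.outcome_se), model.outcome_se, None).tolist(),
        "se_available": model.se_available,
        "loglik": None if np.isnan(model.loglik) else model.loglik,
    }


def joint_model_from_dict(d: dict) -> JointModel:
    se = d.get("outcome_se")
    return JointModel(
        base=model_from_dict(d["base"]), outcome_names=list(d["outcome_names"]),
        outcome_means=np.array(d["outcome_means"]),
        outcome_sd=np.array(d["outcome_sd"]),
        outcome_se=None if se is None else np.array(
            [[np.nan if v is None else v for v in row] for row in se], dtype=float),
        se_available=d.get("se_available", True),
        loglik=np.nan if d.get("loglik") is None else d["loglik"])


def save_joint_model(model: JointModel, path) -> None:
    Path(path).write_text(json.dumps(joint_model_to_dict(model), indent=1))


def load_joint_model(path) -> JointModel:
    return joint_model_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

def sha256_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    master_seed: int
    stage_seeds: dict = field(default_factory=dict)
    package_version: str = ""
    timings: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)   # relative path -> sha256

    def record_artifact(self, out_dir, path) -> None:
        rel = str(Path(path).relative_to(out_dir))
        self.artifacts[rel] = sha256_digest(path)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
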