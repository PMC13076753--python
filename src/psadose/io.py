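"""CSV/JSON/YAML interchange and run configuration.

All tabular artifacts are plain CSV (UTF-8, "." decimal); models, trees and
reports are JSON; run configuration is YAML.  Every artifact bundle embeds
the seed and a hash of the generating configuration for provenance.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import VariableRoles
from .synthetic import SimConfig, TrueEffectSpec

__all__ = ["load_visits", "RunConfig", "config_hash", "write_json", "split_truth_columns"]

REQUIRED_VISIT_COLUMNS = ("patient_id", "visit_index", "dose")
VALID_DOSES = (150.0, 300.0)


def load_visits(path) -> pd.DataFrame:
    """Read a long-format visit CSV; empty strings become missing.

    The dose column is coerced to {150, 300, missing}; unparseable or
    out-of-range doses are set to missing with a counted warning.  Unknown
    extra columns are preserved.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_VISIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path} lacks required columns {missing}; found {list(df.columns)}"
        )
    raw = df["dose"]
    dose = pd.to_numeric(raw, errors="coerce")
    bad_parse = int((dose.isna() & raw.notna() & (raw.astype(str).str.strip() != "")).sum())
    bad_value = int((~dose.isin(VALID_DOSES) & dose.notna()).sum())
    dose = dose.where(dose.isin(VALID_DOSES))
    if bad_parse or bad_value:
        warnings.warn(
            f"{path}: {bad_parse} unparseable and {bad_value} out-of-range dose "
            "values set to missing"
        )
    df["dose"] = dose
    df["visit_index"] = pd.to_numeric(df["visit_index"], errors="raise").astype(int)
    return df


def split_truth_columns(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Separate hidden ``_true_*`` columns from the observable table."""
    truth_cols = [c for c in table.columns if c.startswith("_true_")]
    keys = [c for c in ("patient_id", "visit_index") if c in table.columns]
    return table.drop(columns=truth_cols), table[keys + truth_cols].copy()


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n"
    )


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    out_dir: str = "results/run"
    input_csv: str | None = None  # when None, simulate a cohort
    seed: int = 0
    sim: SimConfig | None = None
    roles: VariableRoles = field(default_factory=VariableRoles)
    k_folds: int = 5
    learner: str = "gbt"
    effect_modifiers: tuple = ("bmi",)
    tree_min_leaf: int = 50
    tree_max_depth: int = 3
    policy_thresholds: tuple = (0.0, 0.2, 0.5)
    max_missing_fraction: float = 0.5

    def to_dict(self) -> dict:
        d = {
            "out_dir": self.out_dir,
            "input_csv": self.input_csv,
            "seed": self.seed,
            "k_folds": self.k_folds,
            "learner": self.learner,
            "effect_modifiers": list(self.effect_modifiers),
            "tree_min_leaf": self.tree_min_leaf,
            "tree_max_depth": self.tree_max_depth,
            "policy_thresholds": list(self.policy_thresholds),
            "max_missing_fraction": self.max_missing_fraction,
            "roles": {
                "y": self.roles.y,
                "t": self.roles.t,
                "w": list(self.roles.w),
                "x": list(self.roles.x),
            },
        }
        if self.sim is not None:
            d["sim"] = {
                "n_patients": self.sim.n_patients,
                "noise_sd": self.sim.noise_sd,
                "switch_rate": self.sim.switch_rate,
                "missing_mechanism": self.sim.missing_mechanism,
                "seed": self.sim.seed,
                "missing_rates": dict(self.sim.missing_rates),
                "effect_spec": {
                    "base_effect": self.sim.effect_spec.base_effect,
                    "modifiers": [list(m) for m in self.sim.effect_spec.modifiers],
                },
            }
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in (
            "out_dir",
            "input_csv",
            "seed",
            "k_folds",
            "learner",
            "max_missing_fraction",
            "tree_min_leaf",
            "tree_max_depth",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        for key in ("effect_modifiers", "policy_thresholds"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        if "roles" in raw:
            r = raw["roles"]
            kwargs["roles"] = VariableRoles(
                y=r.get("y", "psaid_reduction"),
                t=r.get("t", "high_dose"),
                w=tuple(r.get("w", VariableRoles().w)),
                x=tuple(r.get("x", VariableRoles().x)),
            )
        if "sim" in raw:
            s = dict(raw["sim"])
            if "effect_spec" in s:
                es = s.pop("effect_spec")
                s["effect_spec"] = TrueEffectSpec(
                    base_effect=es.get("base_effect", 0.14),
                    modifiers=tuple(tuple(m) for m in es.get("modifiers", ())),
                )
            kwargs["sim"] = SimConfig(**s)
        return cls(**kwargs)


def config_hash(config: RunConfig) -> str:
    """Hash of the scientific configuration (output location excluded)."""
    payload = config.to_dict()
    payload.pop("out_dir", None)
    payload = json.dumps(payload, sort_keys=True, default=_jsonable)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
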