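"""Patient selection, outcome engineering and variable-role handling.

Turns a long-format visit table into one analysis row per eligible patient:
the treated/control contrast is the 300 mg vs 150 mg starting dose, the
outcome Y is the score *reduction* from baseline to Visit 3 (falling back to
Visit 4 when Visit 3 is missing), so positive Y means improvement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VariableRoles",
    "select_patients",
    "filter_variables",
    "categorize_psaid",
    "flag_effective",
    "impute_baseline",
    "PSAID_CATEGORIES",
]

PSAID_CATEGORIES = ("remission", "low", "moderate", "high")

#: PsAID reduction counted as effective treatment (points).
EFFECTIVE_THRESHOLD = 3.0

#: latest admissible treatment start relative to baseline (weeks before).
MAX_START_LEAD_WEEKS = 4

REQUIRED_VISIT_COLUMNS = ("patient_id", "visit_index", "dose")


@dataclass(frozen=True)
class VariableRoles:
    """Y/T/W/X column partition driving all estimation.

    W holds the declared confounders (variables that move both the dose
    decision and the outcome); X holds the remaining outcome-only covariates.
    """

    y: str = "psaid_reduction"
    t: str = "high_dose"
    w: tuple = (
        "psaid_baseline",
        "bmi",
        "pasi_baseline",
        "tnfi_months",
        "biologics_count",
        "plaque_psoriasis",
    )
    x: tuple = (
        "age",
        "female",
        "crp_baseline",
        "bdi_baseline",
        "phga_baseline",
        "pga_baseline",
        "spi2_baseline",
        "smoking",
    )

    def __post_init__(self) -> None:
        cols = [self.y, self.t, *self.w, *self.x]
        if len(set(cols)) != len(cols):
            raise ValueError("Y, T, W, X must be pairwise disjoint")

    @property
    def features(self) -> tuple:
        return tuple(self.x) + tuple(self.w)


def categorize_psaid(score):
    """Map a PsAID score (0-10) to its burden category.

    Boundaries: remission < 2; low in [2, 3]; moderate in (3, 6); high >= 6.
    Missing or out-of-range scores map to missing.  Accepts scalars or
    array-likes (returns an object array for the latter).
    """

    def one(s):
        if s is None or (isinstance(s, float) and np.isnan(s)):
            return np.nan
        s = float(s)
        if not 0.0 <= s <= 10.0:
            return np.nan
        if s < 2.0:
            return "remission"
        if s <= 3.0:
            return "low"
        if s < 6.0:
            return "moderate"
        return "high"

    if np.ndim(score) == 0:
        return one(score)
    return np.array([one(s) for s in np.asarray(score, dtype=float)], dtype=object)


def flag_effective(reduction):
    """True iff the PsAID reduction reaches the 3-point effectiveness bar."""
    arr = np.asarray(reduction, dtype=float)
    out = arr >= EFFECTIVE_THRESHOLD
    if np.ndim(reduction) == 0:
        return bool(out)
    return out


def _baseline_covariates(base_row: pd.Series, score: str) -> dict:
    cov = {}
    static = (
        "age",
        "female",
        "bmi",
        "smoking",
        "plaque_psoriasis",
        "biologics_count",
        "tnfi_months",
    )
    for c in static:
        if c in base_row.index:
            cov[c] = base_row[c]
    for s in ("psaid", "bdi", "phga", "pga", "spi2", "pasi", "crp"):
        if s in base_row.index:
            cov[f"{s}_baseline"] = base_row[s]
    return cov


def select_patients(
    visits: pd.DataFrame, outcome: str = "psaid"
) -> tuple[pd.DataFrame, dict]:
    """Apply the three eligibility rules and build the analysis table.

    A patient is kept when (1) the treatment started no earlier than 4 weeks
    before baseline, (2) the outcome score is recorded at baseline and at
    Visit 3 — or Visit 4 when Visit 3 is missing — and (3) the dose is
    recorded and unchanged from baseline through the endpoint visit used.
    Returns ``(analysis_table, exclusion_log)`` where the log counts patients
    per first-failing rule.
    """
    missing = [c for c in REQUIRED_VISIT_COLUMNS if c not in visits.columns]
    if missing:
        raise ValueError(f"visit table lacks required columns: {missing}")
    if outcome not in visits.columns:
        raise ValueError(f"outcome column {outcome!r} not in visit table")

    log = {
        "total": 0,
        "started_too_early": 0,
        "no_baseline_outcome": 0,
        "no_followup_outcome": 0,
        "dose_changed_or_missing": 0,
        "included": 0,
    }
    rows = []
    for pid, grp in visits.groupby("patient_id", sort=True):
        log["total"] += 1
        byv = grp.set_index("visit_index")
        if 1 not in byv.index:
            log["no_baseline_outcome"] += 1
            continue
        base = byv.loc[1]
        offset = base.get("treatment_start_offset_weeks", 0)
        if pd.notna(offset) and offset < -MAX_START_LEAD_WEEKS:
            log["started_too_early"] += 1
            continue
        if pd.isna(base.get(outcome, np.nan)):
            log["no_baseline_outcome"] += 1
            continue
        endpoint = None
        for v in (3, 4):
            if v in byv.index and pd.notna(byv.loc[v, outcome]):
                endpoint = v
                break
        if endpoint is None:
            log["no_followup_outcome"] += 1
            continue
        window = byv.loc[[v for v in byv.index if 1 <= v <= endpoint], "dose"]
        if window.isna().any() or window.nunique() != 1:
            log["dose_changed_or_missing"] += 1
            continue
        dose = window.iloc[0]
        if dose not in (150, 300):
            log["dose_changed_or_missing"] += 1
            continue

        y = float(base[outcome]) - float(byv.loc[endpoint, outcome])
        row = {
            "patient_id": pid,
            "high_dose": int(dose == 300),
            "dose": int(dose),
            f"{outcome}_reduction": y,
            "followup_visit": endpoint,
            f"{outcome}_followup": float(byv.loc[endpoint, outcome]),
        }
        row.update(_baseline_covariates(base, outcome))
        if outcome == "psaid":
            row["psaid_category_baseline"] = categorize_psaid(row["psaid_baseline"])
            row["psaid_category_followup"] = categorize_psaid(row["psaid_followup"])
            row["effective"] = flag_effective(y)
        for c in ("_true_theta", "_true_response", "_true_propensity"):
            if c in base.index:
                row[c] = base[c]
        rows.append(row)
        log["included"] += 1

    table = pd.DataFrame(rows)
    return table, log


def filter_variables(
    table: pd.DataFrame,
    roles: VariableRoles,
    max_missing_fraction: float = 0.5,
) -> tuple[pd.DataFrame, list[str]]:
    """Drop candidate feature columns with too much missingness.

    A column is dropped when its missing fraction is >= the threshold (the
    boundary is inclusive).  Y, T and the declared confounders W are exempt:
    they are warned about but retained.  Returns the filtered table and the
    list of dropped columns.
    """
    if not 0.0 < max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in (0, 1]")
    protected = {roles.y, roles.t, *roles.w}
    dropped = []
    for col in roles.x:
        if col not in table.columns:
            continue
        frac = table[col].isna().mean()
        if frac >= max_missing_fraction:
            dropped.append(col)
    for col in protected:
        if col in table.columns and table[col].isna().mean() >= max_missing_fraction:
            warnings.warn(
                f"protected column {col!r} has >= {max_missing_fraction:.0%} missing; kept"
            )
    return table.drop(columns=dropped), dropped


def impute_baseline(
    table: pd.DataFrame, columns, add_indicators: bool = True
) -> pd.DataFrame:
    """Median-impute numeric (mode for categorical) baseline covariates.

    Adds a ``<col>_was_missing`` indicator for every column that actually had
    gaps, so the information that a value was absent stays available to the
    nuisance learners.
    """
    out = table.copy()
    for col in columns:
        if col not in out.columns:
            continue
        mask = out[col].isna()
        if not mask.any():
            continue
        if pd.api.types.is_numeric_dtype(out[col]):
            fill = out[col].median()
        else:
            modes = out[col].mode(dropna=True)
            fill = modes.iloc[0] if len(modes) else np.nan
        out[col] = out[col].fillna(fill)
        if add_indicators:
            out[f"{col}_was_missing"] = mask.astype(int)
    return out
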