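"""Synthetic confounded PsA registry cohorts with known ground-truth dose effects.

The real registry behind the analysis (a German non-interventional secukinumab
study) is not public, so this module generates longitudinal visit tables that
emulate its structure: six visits (baseline plus weeks 4, 16, 28, 40, 52), a
150 mg vs 300 mg starting dose assigned by a severity-driven logistic model
(confounded-by-indication), patient-reported and clinical scores with realistic
marginal distributions, and heavy, score-specific missingness.

Every cohort carries hidden ``_true_*`` columns (per-patient treatment effect
theta(x), prognostic response, assignment propensity) so estimator bias can be
measured exactly in tests.  Those columns are for evaluation only and are
written to a separate file by the I/O layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrueEffectSpec",
    "SimConfig",
    "true_cate",
    "simulate_cohort",
    "inject_missingness",
    "DEFAULT_COVARIATES",
    "DEFAULT_ASSIGNMENT",
    "DEFAULT_MISSING_RATES",
    "PROTECTED_COLUMNS",
]

#: visit_index -> scheduled week
VISIT_WEEKS = {1: 0, 2: 4, 3: 16, 4: 28, 5: 40, 6: 52}

#: Columns that carry identity/treatment structure and must never be masked.
PROTECTED_COLUMNS = frozenset(
    {"patient_id", "visit_index", "week", "dose", "treatment_start_offset_weeks"}
)

# Marginal covariate distributions.  Location/scale pairs follow the pooled
# baseline table of the registry cohort (e.g. PsAID 5.2 +/- 2.1 on 0-10,
# BMI 29.4 +/- 6.1); the distribution families are modelling choices:
# truncated normals for bounded instruments, a lognormal for the right-skewed
# CRP (matched to mean 8.4, SD 13.7 mg/L), Bernoulli/categorical for
# sex/plaque/smoking, Poisson for prior-biologic counts and a zero-inflated
# exponential for months of prior TNF-alpha-inhibitor exposure.
DEFAULT_COVARIATES: dict[str, tuple] = {
    "age": ("normal", 52.8, 11.5),
    "female": ("bernoulli", 0.576),
    "bmi": ("truncnorm", 29.4, 6.1, 14.0, 60.0),
    "crp_baseline": ("lognormal", 8.4, 13.7),
    "psaid_baseline": ("truncnorm", 5.2, 2.1, 0.0, 10.0),
    "pasi_baseline": ("truncnorm", 7.3, 10.9, 0.0, 72.0),
    "bdi_baseline": ("truncnorm", 12.7, 9.5, 0.0, 63.0),
    "phga_baseline": ("truncnorm", 5.55, 2.05, 0.0, 10.0),
    "pga_baseline": ("truncnorm", 5.3, 2.5, 0.0, 10.0),
    "spi2_baseline": ("truncnorm", 42.5, 9.7, 16.8, 65.9),
    "smoking": ("categorical", ("active", "ex", "never"), (0.25, 0.30, 0.45)),
    "plaque_psoriasis": ("bernoulli", 0.70),
    "biologics_count": ("poisson", 1.2),
    "tnfi_months": ("zero_inflated_exp", 0.55, 24.0),
}

# Severity -> high-dose logistic assignment.  Confounding enters only through
# covariates that are part of the declared confounder set W, so the estimand
# stays identifiable by construction.  The intercept centres the high-dose
# share near 1/2.
DEFAULT_ASSIGNMENT: dict[str, float] = {
    "intercept": -2.11,
    "psaid_baseline": 0.10,
    "bmi": 0.035,
    "pasi_baseline": 0.02,
    "biologics_count": 0.15,
    "plaque_psoriasis": 0.20,
}

# Per-column missing fractions; the primary outcome (PsAID) is the most
# complete and the skin score (PASI) the least, spanning roughly 38%-76%.
DEFAULT_MISSING_RATES: dict[str, float] = {
    "psaid": 0.38,
    "bdi": 0.44,
    "phga": 0.42,
    "pga": 0.55,
    "spi2": 0.60,
    "pasi": 0.76,
    "crp": 0.50,
    "bmi": 0.03,
}

#: score column -> (lower, upper) instrument range
SCORE_BOUNDS = {
    "psaid": (0.0, 10.0),
    "bdi": (0.0, 63.0),
    "phga": (0.0, 10.0),
    "pga": (0.0, 10.0),
    "spi2": (16.8, 65.9),
    "pasi": (0.0, 72.0),
    "crp": (0.0, np.inf),
}

# Gaussian-copula correlation between baseline PsAID and BDI (depression and
# disease impact are moderately correlated in this population).
PSAID_BDI_CORR = 0.45

# Prognostic (non-treatment) part of the Visit-3/4 PsAID reduction: sicker and
# more depressed patients regress further irrespective of dose.
RESPONSE_COEFS = {"psaid_baseline": 0.22, "bdi_baseline": 0.022}


@dataclass(frozen=True)
class TrueEffectSpec:
    """Ground-truth CATE function theta(x): extra PsAID reduction from 300 mg.

    ``modifiers`` is a list of ``(covariate, threshold_or_level, increment)``
    terms.  A numeric threshold contributes ``increment`` when the covariate
    exceeds it; a string level contributes when the covariate equals it.
    theta(x) is deterministic in baseline covariates only.
    """

    base_effect: float = 0.14
    modifiers: tuple = (("bmi", 32.5, 0.38),)

    def null(self) -> "TrueEffectSpec":
        return TrueEffectSpec(base_effect=0.0, modifiers=())


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults are the study conditions emulated."""

    n_patients: int = 1235
    covariate_specs: Mapping[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )
    assignment_coefs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ASSIGNMENT)
    )
    effect_spec: TrueEffectSpec = field(default_factory=TrueEffectSpec)
    noise_sd: float = 1.0
    missing_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_RATES)
    )
    switch_rate: float = 0.05
    missing_mechanism: str = "mcar"  # or "mnar" (outcome-dependent)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError(f"n_patients must be positive, got {self.n_patients}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for col, rate in self.missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missing rate for {col!r} outside [0, 1]: {rate}")
        if not 0.0 <= self.switch_rate <= 1.0:
            raise ValueError("switch_rate outside [0, 1]")
        if self.missing_mechanism not in ("mcar", "mnar"):
            raise ValueError(f"unknown missing_mechanism {self.missing_mechanism!r}")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


def true_cate(covariates, spec: TrueEffectSpec):
    """Evaluate theta(x) for a mapping, Series or DataFrame of covariates.

    Returns a float for a single observation, a numpy array for a DataFrame.
    Raises ``KeyError`` if a covariate referenced by a modifier is absent.
    """
    if isinstance(covariates, pd.DataFrame):
        theta = np.full(len(covariates), float(spec.base_effect))
        for name, cut, inc in spec.modifiers:
            if name not in covariates.columns:
                raise KeyError(f"effect modifier {name!r} missing from covariates")
            col = covariates[name]
            if isinstance(cut, str):
                theta = theta + inc * (col == cut).to_numpy(dtype=float)
            else:
                theta = theta + inc * (col.to_numpy(dtype=float) > cut)
        return theta
    theta = float(spec.base_effect)
    for name, cut, inc in spec.modifiers:
        if name not in covariates:
            raise KeyError(f"effect modifier {name!r} missing from covariates")
        val = covariates[name]
        if isinstance(cut, str):
            theta += inc if val == cut else 0.0
        else:
            theta += inc if float(val) > cut else 0.0
    return theta


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _marginal_from_normal(z: np.ndarray, spec: tuple, name: str) -> np.ndarray:
    """Map standard normals through a marginal via the probability transform."""
    family = spec[0]
    u = stats.norm.cdf(z)
    if family == "normal":
        _, loc, scale = spec
        return loc + scale * z
    if family == "truncnorm":
        _, loc, scale, lo, hi = spec
        a, b = (lo - loc) / scale, (hi - loc) / scale
        return stats.truncnorm.ppf(u, a, b, loc=loc, scale=scale)
    if family == "lognormal":
        _, mean, sd = spec
        mu, sigma = _lognormal_params(mean, sd)
        return np.exp(mu + sigma * z)
    if family == "bernoulli":
        _, p = spec
        return (u < p).astype(float)
    if family == "categorical":
        _, levels, probs = spec
        edges = np.cumsum(probs)
        idx = np.searchsorted(edges, u, side="right").clip(0, len(levels) - 1)
        return np.asarray(levels, dtype=object)[idx]
    if family == "poisson":
        _, lam = spec
        return stats.poisson.ppf(np.clip(u, 1e-12, 1 - 1e-12), lam)
    if family == "zero_inflated_exp":
        _, p_zero, mean_pos = spec
        out = np.where(
            u < p_zero,
            0.0,
            stats.expon.ppf((u - p_zero).clip(0) / (1 - p_zero), scale=mean_pos),
        )
        return out
    raise ValueError(f"unknown covariate family {family!r} for {name!r}")


def _draw_covariates(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_patients
    names = list(config.covariate_specs)
    z = rng.standard_normal((n, len(names)))
    cols: dict[str, np.ndarray] = {}
    # Gaussian copula: correlate PsAID and BDI latents before the marginal map.
    if "psaid_baseline" in names and "bdi_baseline" in names:
        i, j = names.index("psaid_baseline"), names.index("bdi_baseline")
        r = PSAID_BDI_CORR
        z[:, j] = r * z[:, i] + np.sqrt(1 - r * r) * z[:, j]
    for k, name in enumerate(names):
        cols[name] = _marginal_from_normal(z[:, k], config.covariate_specs[name], name)
    return pd.DataFrame(cols)


def _propensity(cov: pd.DataFrame, coefs: Mapping[str, float]) -> np.ndarray:
    logit = np.full(len(cov), float(coefs.get("intercept", 0.0)))
    for name, b in coefs.items():
        if name == "intercept":
            continue
        if name not in cov.columns:
            raise KeyError(f"assignment coefficient references unknown covariate {name!r}")
        logit = logit + b * cov[name].to_numpy(dtype=float)
    return 1.0 / (1.0 + np.exp(-logit))


def _response(cov: pd.DataFrame) -> np.ndarray:
    """Prognostic PsAID reduction, independent of dose."""
    r = np.zeros(len(cov))
    for name, b in RESPONSE_COEFS.items():
        r = r + b * cov[name].to_numpy(dtype=float)
    return r


def simulate_cohort(config: SimConfig) -> pd.DataFrame:
    """Generate a long-format visit table (6 rows per patient).

    The Visit-3/4 PsAID equals ``baseline - (response(x) + theta(x) * T + noise)``
    clamped to the instrument range [0, 10].  The starting dose is held fixed
    unless ``switch_rate`` lets a patient change dose at an interim visit (such
    patients are meant to be removed by the dose-stability selection rule).
    Hidden ``_true_theta``/``_true_response``/``_true_propensity`` columns are
    attached for evaluation.  Identical configs (same seed) give identical
    tables.  Missingness is injected per ``config.missing_rates``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    cov = _draw_covariates(config, rng)
    e_true = _propensity(cov, config.assignment_coefs)
    t = (rng.random(n) < e_true).astype(int)
    theta = np.asarray(true_cate(cov, config.effect_spec), dtype=float)
    resp = _response(cov)

    # Treatment start relative to baseline; the selection window admits
    # starts no earlier than 4 weeks before baseline.
    offsets = rng.choice(
        np.array([-8, -6, -4, -2, 0]), size=n, p=[0.02, 0.03, 0.15, 0.30, 0.50]
    )
    switches = rng.random(n) < config.switch_rate
    switch_visit = rng.integers(2, 5, size=n)  # switch takes effect at visit 2-4

    psaid0 = cov["psaid_baseline"].to_numpy()
    eps = rng.normal(0.0, config.noise_sd, size=(n, 6))

    rows: list[pd.DataFrame] = []
    ramp = {1: 0.0, 2: 0.5, 3: 1.0, 4: 1.0, 5: 1.0, 6: 1.0}
    sec_noise = {"bdi": 2.0, "phga": 0.8, "pga": 0.9, "spi2": 2.5, "pasi": 2.0, "crp": 3.0}
    sec_improve = {"bdi": 0.12, "phga": 0.15, "pga": 0.12, "spi2": 0.05, "pasi": 0.35, "crp": 0.20}
    base_cols = {
        "bdi": "bdi_baseline",
        "phga": "phga_baseline",
        "pga": "pga_baseline",
        "spi2": "spi2_baseline",
        "pasi": "pasi_baseline",
        "crp": "crp_baseline",
    }
    sec_eps = {
        s: rng.normal(0.0, sec_noise[s], size=(n, 6)) for s in base_cols
    }

    for v, week in VISIT_WEEKS.items():
        dose_now = np.where(
            switches & (switch_visit <= v), np.where(t == 1, 150, 300), np.where(t == 1, 300, 150)
        )
        drop = ramp[v] * (resp + theta * t)
        noise = eps[:, v - 1] if v != 1 else 0.0
        psaid_v = psaid0 - drop - (noise if v != 1 else 0.0)
        psaid_v = np.clip(psaid_v, *SCORE_BOUNDS["psaid"])
        if v == 1:
            psaid_v = psaid0
        frame = {
            "patient_id": np.arange(n),
            "visit_index": v,
            "week": week,
            "treatment_start_offset_weeks": offsets,
            "dose": dose_now,
            "psaid": psaid_v,
        }
        for s, bcol in base_cols.items():
            base = cov[bcol].to_numpy(dtype=float)
            val = base * (1.0 - sec_improve[s] * ramp[v]) + (
                sec_eps[s][:, v - 1] if v != 1 else 0.0
            )
            lo, hi = SCORE_BOUNDS[s]
            frame[s] = base if v == 1 else np.clip(val, lo, hi)
        for c in ("age", "female", "bmi", "smoking", "plaque_psoriasis", "biologics_count", "tnfi_months"):
            frame[c] = cov[c].to_numpy()
        frame["_true_theta"] = theta
        frame["_true_response"] = resp
        frame["_true_propensity"] = e_true
        rows.append(pd.DataFrame(frame))

    table = pd.concat(rows, ignore_index=True).sort_values(
        ["patient_id", "visit_index"], kind="stable", ignore_index=True
    )
    if config.missing_rates:
        mask_seed = int(rng.integers(0, 2**31 - 1))
        table = inject_missingness(
            table,
            config.missing_rates,
            seed=mask_seed,
            mechanism=config.missing_mechanism,
        )
    return table


def inject_missingness(
    table: pd.DataFrame,
    missing_rates: Mapping[str, float],
    seed: int,
    mechanism: str = "mcar",
) -> pd.DataFrame:
    """Mask values to NaN, column by column, reproducibly under ``seed``.

    MCAR masks uniformly at random at each column's rate.  The "mnar" variant
    makes worse (higher) scores more likely to be missing while preserving the
    column-wise expected rate.  Identity and treatment columns are protected.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    for col in sorted(missing_rates):
        rate = missing_rates[col]
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missing rate for {col!r} outside [0, 1]: {rate}")
        if col in PROTECTED_COLUMNS:
            raise ValueError(f"refusing to mask protected column {col!r}")
        if col not in out.columns:
            warnings.warn(f"missing-rate column {col!r} not in table; skipped")
            continue
        if rate == 0.0:
            continue
        n = len(out)
        if mechanism == "mnar" and pd.api.types.is_numeric_dtype(out[col]):
            vals = out[col].to_numpy(dtype=float)
            ranks = pd.Series(vals).rank(pct=True, na_option="keep").to_numpy()
            # tilt the masking probability toward high scores, mean kept at rate
            p = np.clip(rate * (0.5 + ranks) , 0.0, 1.0)
            p = np.where(np.isnan(p), rate, p)
            mask = rng.random(n) < p
        else:
            mask = rng.random(n) < rate
        out.loc[mask, col] = np.nan
    return out
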