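"""Double machine learning: cross-fitted nuisances, linear CATE stage, IPTW.

Stage 1 fits the outcome regression m(x) = E[Y | X, W] and the propensity
e(x) = P(T=1 | X, W) with cross-fitting: each patient's nuisance predictions
come from models trained on the other folds, which removes own-observation
overfitting bias.  Stage 2 regresses the outcome residual Y - m̂ on the
treatment residual (T - ê) interacted with an effect-modifier basis phi(x):

    Y - m̂(x)  =  [ (T - ê(x)) * phi(x) ]' beta  +  error

so thetâ(x) = beta' phi(x) is the estimated conditional average treatment
effect and its mean is the (partially linear) ATE.  Inference uses
heteroskedasticity-robust (HC1) standard errors with normal p-values.

An inverse-probability-of-treatment (Hájek) estimator of the ATE is provided
as the classical reweighting benchmark: it uses the same clipped propensities
but no outcome model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from sklearn.ensemble import (
    HistGradientBoostingClassifier,
    HistGradientBoostingRegressor,
)
from sklearn.linear_model import LogisticRegression, Ridge

from .cohort import VariableRoles

__all__ = [
    "assign_folds",
    "NuisanceFit",
    "CATEModel",
    "fit_nuisances",
    "fit_linear_cate",
    "estimate_ate_iptw",
    "predict_cate",
    "coefficient_table",
    "prepare_features",
]

PROPENSITY_CLIP = (0.01, 0.99)


def assign_folds(t: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Treatment-stratified fold assignment; overall sizes differ by <= 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    t = np.asarray(t)
    n = len(t)
    rng = np.random.default_rng(seed)
    order = np.concatenate(
        [rng.permutation(np.flatnonzero(t == cls)) for cls in np.unique(t)]
    )
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % k
    return folds


def prepare_features(
    table: pd.DataFrame, roles: VariableRoles, dummy_reference: dict | None = None
) -> pd.DataFrame:
    """Numeric design frame from the X+W columns (dummy-coding categoricals).

    Categorical columns are one-hot encoded against a reference level
    (default: smoking dummy-coded with the active smoker as reference).
    Columns absent from the table are silently skipped so the same roles
    object can be used before and after missingness filtering.
    """
    ref = {"smoking": "active"}
    if dummy_reference:
        ref.update(dummy_reference)
    cols = [c for c in roles.features if c in table.columns]
    extra = [c for c in table.columns if c.endswith("_was_missing")]
    out = {}
    for c in cols:
        s = table[c]
        if pd.api.types.is_numeric_dtype(s):
            out[c] = s.astype(float)
        else:
            levels = sorted(x for x in s.dropna().unique())
            base = ref.get(c)
            for lev in levels:
                if lev == base:
                    continue
                out[f"{c}_{lev}"] = (s == lev).astype(float)
    for c in extra:
        out[c] = table[c].astype(float)
    return pd.DataFrame(out, index=table.index)


def _make_learners(learner: str, seed: int):
    if learner == "gbt":
        reg = HistGradientBoostingRegressor(
            max_depth=3, max_iter=150, learning_rate=0.08, random_state=seed
        )
        clf = HistGradientBoostingClassifier(
            max_depth=3, max_iter=150, learning_rate=0.08, random_state=seed
        )
    elif learner == "linear":
        reg = Ridge(alpha=1.0)
        clf = LogisticRegression(max_iter=2000)
    else:
        raise ValueError(f"unknown learner {learner!r} (use 'gbt' or 'linear')")
    return reg, clf


@dataclass
class NuisanceFit:
    """Out-of-fold nuisance predictions for every analysis row."""

    m_hat: np.ndarray
    e_hat: np.ndarray
    folds: np.ndarray
    k: int
    learner: str
    seed: int
    clip: tuple = PROPENSITY_CLIP


def fit_nuisances(
    table: pd.DataFrame,
    roles: VariableRoles,
    k: int = 5,
    learner: str = "gbt",
    seed: int = 0,
) -> NuisanceFit:
    """Cross-fit m̂ = E[Y|X,W] and the clipped propensity ê = P(T=1|X,W).

    Deterministic under a fixed seed.  Aborts if any training fold contains a
    single treatment class (the propensity model would be undefined).
    """
    y = table[roles.y].to_numpy(dtype=float)
    t = table[roles.t].to_numpy(dtype=int)
    if np.isnan(y).any():
        raise ValueError("Y contains missing values; select/impute first")
    feats = prepare_features(table, roles)
    if feats.isna().any().any():
        raise ValueError("features contain missing values; impute first")
    X = feats.to_numpy(dtype=float)
    folds = assign_folds(t, k, seed)
    m_hat = np.empty(len(y))
    e_hat = np.empty(len(y))
    for f in range(k):
        tr, te = folds != f, folds == f
        if len(np.unique(t[tr])) < 2:
            raise ValueError(f"training folds for fold {f} contain one treatment class")
        reg, clf = _make_learners(learner, seed + f)
        reg.fit(X[tr], y[tr])
        m_hat[te] = reg.predict(X[te])
        clf.fit(X[tr], t[tr])
        e_hat[te] = clf.predict_proba(X[te])[:, 1]
    e_hat = np.clip(e_hat, *PROPENSITY_CLIP)
    return NuisanceFit(m_hat=m_hat, e_hat=e_hat, folds=folds, k=k, learner=learner, seed=seed)


@dataclass
class CATEModel:
    """Stage-2 linear effect model thetâ(x) = beta' phi(x)."""

    feature_names: list
    beta: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    theta_hat: np.ndarray
    average_cate: float
    standardize: bool = False
    centers: np.ndarray | None = None
    scales: np.ndarray | None = None
    intercept_label: str = "start_dose"

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "pvalues": self.pvalues.tolist(),
            "average_cate": float(self.average_cate),
            "standardize": bool(self.standardize),
            "centers": None if self.centers is None else self.centers.tolist(),
            "scales": None if self.scales is None else self.scales.tolist(),
        }


def _basis(
    table: pd.DataFrame,
    effect_modifiers,
    standardize: bool,
    centers=None,
    scales=None,
):
    """Build phi(x) = [1, modifiers...]; optionally z-scored modifiers."""
    if effect_modifiers:
        phi = np.column_stack(
            [np.asarray(table[c], dtype=float) for c in effect_modifiers]
        )
    else:
        phi = np.empty((len(table), 0))
    if standardize and phi.shape[1]:
        if centers is None:
            centers = phi.mean(axis=0)
            scales = phi.std(axis=0)
            scales = np.where(scales == 0, 1.0, scales)
        phi = (phi - centers) / scales
    ones = np.ones((len(table), 1))
    return np.hstack([ones, phi]), centers, scales


def fit_linear_cate(
    table: pd.DataFrame,
    nuisances: NuisanceFit,
    effect_modifiers=(),
    roles: VariableRoles | None = None,
    standardize: bool = False,
) -> CATEModel:
    """Residual-on-residual least squares with HC1 robust inference.

    With an intercept-only basis this reduces to the partially linear ATE.
    Collinear basis columns are dropped with a warning.  Missing modifier
    values are an error.
    """
    roles = roles or VariableRoles()
    y = table[roles.y].to_numpy(dtype=float)
    t = table[roles.t].to_numpy(dtype=float)
    y_res = y - nuisances.m_hat
    t_res = t - nuisances.e_hat
    effect_modifiers = list(effect_modifiers)
    for c in effect_modifiers:
        if table[c].isna().any():
            raise ValueError(f"effect modifier {c!r} has missing values")
    phi, centers, scales = _basis(table, effect_modifiers, standardize)
    names = ["start_dose"] + [str(c) for c in effect_modifiers]
    design = t_res[:, None] * phi

    rank = np.linalg.matrix_rank(design)
    keep = list(range(design.shape[1]))
    if rank < design.shape[1]:
        keep = []
        for j in range(design.shape[1]):
            trial = design[:, keep + [j]]
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(j)
        dropped = [names[j] for j in range(design.shape[1]) if j not in keep]
        warnings.warn(f"dropping collinear effect-modifier columns: {dropped}")
        design = design[:, keep]
        phi = phi[:, keep]
        names = [names[j] for j in keep]

    res = sm.OLS(y_res, design).fit(cov_type="HC1")
    beta = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2.0 * (1.0 - stats.norm.cdf(np.abs(z)))
    theta_hat = phi @ beta
    return CATEModel(
        feature_names=names,
        beta=beta,
        se=se,
        pvalues=pvals,
        theta_hat=theta_hat,
        average_cate=float(np.mean(theta_hat)),
        standardize=standardize,
        centers=centers,
        scales=scales,
    )


def predict_cate(model: CATEModel, covariates) -> np.ndarray | float:
    """thetâ(x) = beta' phi(x) for new covariates (frame, Series or mapping)."""
    scalar = not isinstance(covariates, pd.DataFrame)
    if scalar:
        covariates = pd.DataFrame([dict(covariates)])
    modifiers = model.feature_names[1:]
    for c in modifiers:
        if c not in covariates.columns or covariates[c].isna().any():
            raise ValueError(f"missing effect-modifier value for {c!r}")
    phi, _, _ = _basis(
        covariates, modifiers, model.standardize, model.centers, model.scales
    )
    theta = phi @ model.beta
    return float(theta[0]) if scalar else theta


def estimate_ate_iptw(
    y: np.ndarray, t: np.ndarray, e_hat: np.ndarray
) -> tuple[float, float]:
    """Hájek (normalized-weight) IPTW ATE with a delta-method SE.

    Weighted mean of Y with weights 1/ê among treated minus weighted mean
    with weights 1/(1-ê) among controls.  Requires both arms non-empty.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t)
    e = np.asarray(e_hat, dtype=float)
    if not ((t == 1).any() and (t == 0).any()):
        raise ValueError("both treatment arms must be non-empty")

    def _arm(mask, w):
        w = w[mask]
        yv = y[mask]
        mu = np.sum(w * yv) / np.sum(w)
        var = np.sum((w * (yv - mu)) ** 2) / np.sum(w) ** 2
        return mu, var

    mu1, v1 = _arm(t == 1, 1.0 / e)
    mu0, v0 = _arm(t == 0, 1.0 / (1.0 - e))
    return float(mu1 - mu0), float(np.sqrt(v1 + v0))


def coefficient_table(model: CATEModel) -> pd.DataFrame:
    """Coefficients with 95% CIs, sorted by p-value ascending (forest-plot order)."""
    df = pd.DataFrame(
        {
            "name": model.feature_names,
            "coefficient": model.beta,
            "se": model.se,
            "ci_low": model.beta - 1.959963984540054 * model.se,
            "ci_high": model.beta + 1.959963984540054 * model.se,
            "p_value": model.pvalues,
        }
    )
    return df.sort_values("p_value", kind="stable", ignore_index=True)
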