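"""Random-intercept calibration of metabolic rate on physiological predictors.

The statistical core: linear mixed models with individual as a random
intercept, fit by maximum likelihood (so fits with different fixed-effect
structures are AICc-comparable), ranked by the small-sample Akaike
criterion, with Nakagawa–Schielzeth marginal/conditional R² and
likelihood-ratio tests for nested comparisons.  The response is a
continuous metabolic rate, so the "generalized" mixed model reduces to the
identity-link linear mixed model.

Model fitting is delegated to :class:`statsmodels` ``MixedLM``; everything
around it (information criteria, R², selection table, prediction) is
computed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "ModelFit",
    "fit_random_intercept",
    "aicc",
    "r2_nakagawa",
    "model_selection",
    "lr_test",
    "predict_expenditure",
    "PAPER_CALIBRATION",
    "DEFAULT_CANDIDATES",
]

# Published best-fit calibration: daily energy expenditure (kJ d^-1) on bpm
PAPER_CALIBRATION = {"intercept": 0.0527, "slope": 0.00106, "unit": "kJ/day"}

# which predictor (sets) compete by default: each single predictor, all
# pairs, and the heart-rate x temperature interactions
DEFAULT_CANDIDATES = (
    ("f_h",),
    ("t_b",),
    ("t_diff",),
    ("f_h", "t_b"),
    ("f_h", "t_diff"),
    ("t_b", "t_diff"),
    ("f_h", "t_b", "f_h:t_b"),
    ("f_h", "t_diff", "f_h:t_diff"),
)


@dataclass
class ModelFit:
    """One fitted random-intercept model."""

    predictors: tuple
    beta: dict  # fixed-effect coefficients incl. "intercept"
    sigma_u: float  # random-intercept s.d.
    sigma_e: float  # residual s.d.
    loglik: float
    n_obs: int
    n_groups: int
    k_params: int  # fixed effects + 2 variance components
    aicc: float
    r2m: float
    r2c: float
    fit_method: str = "ML"
    boundary: bool = False  # sigma_u estimated at (or near) zero
    converged: bool = True
    unit: str | None = None
    result: object = field(default=None, repr=False, compare=False)

    @property
    def formula(self) -> str:
        return " + ".join(self.predictors) if self.predictors else "1"


def _design(data: pd.DataFrame, predictors: tuple) -> pd.DataFrame:
    """Design matrix with intercept; 'a:b' terms are products."""
    X = pd.DataFrame({"intercept": np.ones(len(data))}, index=data.index)
    for p in predictors:
        if ":" in p:
            a, b = p.split(":")
            X[p] = data[a].to_numpy() * data[b].to_numpy()
        else:
            X[p] = data[p].to_numpy()
    return X


def _base_columns(predictors) -> set:
    cols = set()
    for p in predictors:
        cols.update(p.split(":"))
    return cols


def fit_random_intercept(
    data: pd.DataFrame,
    predictors: tuple = ("f_h",),
    response: str = "mr",
    group: str = "individual",
    method: str = "ML",
    unit: str | None = None,
) -> ModelFit:
    """ML fit of ``response ~ predictors + (1 | group)``.

    Rows with missing values in the used columns are dropped (listwise),
    with the resulting n recorded on the fit.  A fit whose random-intercept
    variance collapses to the boundary is returned with ``boundary=True``
    rather than raising.  Use ``method="REML"`` only for variance reporting,
    never for AICc comparison across fixed-effect structures.
    """
    cols = sorted(_base_columns(predictors) | {response, group})
    data = data.dropna(subset=[c for c in cols if c in data.columns])
    if data[group].nunique() < 2:
        raise ValueError("need at least 2 individuals for a mixed fit")
    y = data[response].to_numpy(dtype=float)
    X = _design(data, tuple(predictors))
    groups = data[group].to_numpy()

    boundary = False
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = MixedLM(y, X.to_numpy(), groups=groups)
            res = model.fit(reml=(method == "REML"))
            # the default optimizer occasionally diverges (non-finite
            # likelihood), notably on intercept-only fits; retry with
            # derivative-free optimizers and keep the best finite optimum
            if not np.isfinite(res.llf):
                best = None
                for opt in ("powell", "nm", "bfgs"):
                    try:
                        cand = model.fit(reml=(method == "REML"), method=opt)
                    except Exception:  # noqa: BLE001
                        continue
                    if np.isfinite(cand.llf) and (best is None or cand.llf > best.llf):
                        best = cand
                if best is None:
                    raise np.linalg.LinAlgError("mixed-model likelihood diverged")
                res = best
            params = dict(zip(X.columns, res.fe_params))
            sigma_u2 = float(np.squeeze(np.asarray(res.cov_re)))
            sigma_e2 = float(res.scale)
            llf = float(res.llf)
            converged = bool(res.converged)
        except np.linalg.LinAlgError:
            # degenerate (e.g. noise-free) data: ordinary least squares with
            # zero variance components
            beta_arr, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
            params = dict(zip(X.columns, beta_arr))
            resid = y - X.to_numpy() @ beta_arr
            sigma_u2, sigma_e2 = 0.0, float(np.var(resid))
            n = y.size
            llf = (
                -0.5 * n * np.log(2 * np.pi * max(sigma_e2, 1e-300))
                - 0.5 * n
                if sigma_e2 > 0
                else np.inf
            )
            res = None
            boundary = True
    # a convergence warning alone is not evidence of a boundary fit; the
    # variance estimate itself is
    if sigma_u2 <= 1e-8 * max(sigma_u2 + sigma_e2, 1e-12):
        boundary = True

    k = X.shape[1] + 2  # fixed effects + intercept variance + residual variance
    n_obs = y.size
    fit_aicc = aicc(llf, k, n_obs) if np.isfinite(llf) else -np.inf
    fitted_fixed = X.to_numpy() @ np.array([params[c] for c in X.columns])
    r2m, r2c = r2_nakagawa(
        var_f=float(np.var(fitted_fixed, ddof=1)) if len(predictors) else 0.0,
        var_u=sigma_u2,
        var_e=sigma_e2,
    )
    return ModelFit(
        predictors=tuple(predictors),
        beta=params,
        sigma_u=float(np.sqrt(max(sigma_u2, 0.0))),
        sigma_e=float(np.sqrt(max(sigma_e2, 0.0))),
        loglik=llf,
        n_obs=n_obs,
        n_groups=int(data[group].nunique()),
        k_params=k,
        aicc=fit_aicc,
        r2m=r2m,
        r2c=r2c,
        fit_method=method,
        boundary=boundary,
        converged=converged,
        unit=unit,
        result=res,
    )


def aicc(loglik: float, k_params: int, n_obs: int) -> float:
    """Small-sample Akaike criterion: −2ℓ + 2k + 2k(k+1)/(n − k − 1)."""
    if n_obs <= k_params + 1:
        raise ValueError("AICc undefined: n must exceed k + 1")
    return -2.0 * loglik + 2.0 * k_params + 2.0 * k_params * (k_params + 1) / (n_obs - k_params - 1)


def r2_nakagawa(
    fit: ModelFit | None = None,
    data: pd.DataFrame | None = None,
    *,
    var_f=None,
    var_u=None,
    var_e=None,
):
    """Marginal and conditional R² from variance components.

    R²m = σ²_f / (σ²_f + σ²_u + σ²_e); R²c = (σ²_f + σ²_u) / (same total),
    where σ²_f is the variance of the fixed-effect linear predictor over
    the data.  Pass either a fitted model plus the data it was fit to, or
    the three variance components directly.  Requires a positive total
    variance.
    """
    if fit is not None:
        if data is None:
            raise TypeError("recomputing R² from a fit requires the dataset")
        rows = data.dropna(subset=[c for c in _base_columns(fit.predictors) if c in data.columns])
        X = _design(rows, fit.predictors)
        pred = X.to_numpy() @ np.array([fit.beta[c] for c in X.columns])
        var_f = float(np.var(pred, ddof=1)) if fit.predictors else 0.0
        var_u = fit.sigma_u**2
        var_e = fit.sigma_e**2
    total = var_f + var_u + var_e
    if total <= 0:
        raise ValueError("zero total variance")
    return float(var_f / total), float((var_f + var_u) / total)


def model_selection(
    data: pd.DataFrame,
    candidate_sets=DEFAULT_CANDIDATES,
    response: str = "mr",
    group: str = "individual",
    unit: str | None = None,
):
    """Fit every candidate by ML on identical rows and rank by AICc.

    All candidates are fit to the listwise-complete rows over the union of
    candidate predictors, so their likelihoods are comparable.  Ties in
    AICc are broken by fewer parameters.  A failing candidate is recorded
    as failed and ranking proceeds.
    """
    candidate_sets = [tuple(c) for c in candidate_sets]
    if len(candidate_sets) < 2:
        raise ValueError("need at least 2 candidate models")
    all_cols = set().union(*(_base_columns(c) for c in candidate_sets))
    rows = data.dropna(subset=[c for c in all_cols | {response, group} if c in data.columns])

    fits, records = {}, []
    for cand in candidate_sets:
        try:
            fit = fit_random_intercept(rows, cand, response, group, "ML", unit)
            fits[cand] = fit
            records.append(
                {
                    "formula": fit.formula,
                    "k": fit.k_params,
                    "n": fit.n_obs,
                    "loglik": fit.loglik,
                    "aicc": fit.aicc,
                    "r2m": fit.r2m,
                    "r2c": fit.r2c,
                    "failed": False,
                }
            )
        except Exception as exc:  # noqa: BLE001 - candidate failure is data
            records.append(
                {"formula": " + ".join(cand), "k": np.nan, "n": np.nan,
                 "loglik": np.nan, "aicc": np.inf, "r2m": np.nan, "r2c": np.nan,
                 "failed": True, "error": str(exc)}
            )
    table = pd.DataFrame(records).sort_values(["aicc", "k"], kind="mergesort").reset_index(drop=True)
    finite = table.loc[~table["failed"], "aicc"]
    table["delta_aicc"] = table["aicc"] - (finite.min() if len(finite) else np.nan)
    return table, fits


def lr_test(nested_fit: ModelFit, full_fit: ModelFit):
    """Likelihood-ratio test of nested ML fits: χ² = 2Δℓ on Δk df.

    Both fits must be ML on the same rows and the nested predictors a
    subset of the full model's.  Note the test is conservative when the
    null lies on a variance boundary (e.g. testing sigma_u = 0), where the
    asymptotic distribution is a chi-bar-square mixture.
    """
    if not set(nested_fit.predictors) <= set(full_fit.predictors):
        raise ValueError("models are not nested")
    if nested_fit.n_obs != full_fit.n_obs:
        raise ValueError("fits use different rows; refit on identical data")
    if nested_fit.fit_method != "ML" or full_fit.fit_method != "ML":
        raise ValueError("likelihood-ratio tests require ML fits")
    chi2 = max(2.0 * (full_fit.loglik - nested_fit.loglik), 0.0)
    df = full_fit.k_params - nested_fit.k_params
    if df <= 0:
        raise ValueError("full model has no extra parameters")
    p = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), p


def predict_expenditure(
    f_h,
    fit=None,
    unit: str | None = None,
    individual: str | None = None,
):
    """Energy expenditure predicted from heart rate.

    ``fit`` may be a :class:`ModelFit` with an ``f_h`` coefficient, a
    ``(intercept, slope)`` pair, or ``None`` for the published calibration
    (kJ d^-1 = 0.00106·f_H + 0.0527).  Predictions are population-level
    (random intercept at zero) unless an individual with a fitted random
    effect is named.  Requesting a unit that contradicts the fit's unit tag
    raises — there is no silent 24x rescaling between daily and hourly
    energy units.
    """
    f_h = np.asarray(f_h, dtype=float)
    if np.any(f_h < 0):
        raise ValueError("heart rate must be non-negative")
    offset = 0.0
    if fit is None:
        b0, b1, fit_unit = (
            PAPER_CALIBRATION["intercept"],
            PAPER_CALIBRATION["slope"],
            PAPER_CALIBRATION["unit"],
        )
    elif isinstance(fit, ModelFit):
        if "f_h" not in fit.beta:
            raise ValueError("fit has no heart-rate coefficient")
        b0, b1, fit_unit = fit.beta["intercept"], fit.beta["f_h"], fit.unit
        if individual is not None and fit.result is not None:
            re = fit.result.random_effects
            if individual not in re:
                raise KeyError(f"no random effect for individual {individual!r}")
            offset = float(np.squeeze(np.asarray(re[individual])))
    else:
        b0, b1 = fit
        fit_unit = unit
    if unit is not None and fit_unit is not None and unit != fit_unit:
        raise ValueError(f"unit mismatch: fit is in {fit_unit!r}, requested {unit!r}")
    return b0 + b1 * f_h + offset
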