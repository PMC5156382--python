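"""Baseline regression fitting and AICc bookkeeping.

The window search compares, for every candidate window, a user-defined
baseline model (no climate term) against the same model with climate terms
appended.  Fits go through statsmodels (OLS for gaussian, GLM otherwise);
formulas are parsed with patsy.  AICc is the small-sample corrected AIC

    AICc = -2 logL + 2 rho + 2 rho (rho + 1) / (N - rho - 1)

with natural logs; for gaussian models rho counts the residual-variance
parameter, so an intercept-only gaussian fit has rho = 2.  The comparison
metric is

    dAICc = AICc(climate model) - AICc(baseline)

so negative values mean the climate window improves on the baseline and
the best window has the smallest (most negative) dAICc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm

__all__ = [
    "BaselineSpec",
    "FittedModel",
    "fit_baseline",
    "attach_climate",
    "aicc",
    "delta_aicc",
    "gaussian_loglik",
    "CLIMATE_FUNCS",
]

FAMILIES = ("gaussian", "poisson", "binomial")
CLIMATE_FUNCS = ("lin", "quad", "cub", "log", "inv")


class FitError(RuntimeError):
    """The requested model could not be fitted (rank deficiency, bad data)."""


@dataclass
class BaselineSpec:
    """A climate-free baseline model: formula + family + data.

    The formula uses the conventional ``response ~ term + term`` notation
    (``response ~ 1`` for intercept-only) and must not reference a column
    named ``climate`` — that name is reserved for the appended terms.
    """

    formula: str
    data: pd.DataFrame
    family: str = "gaussian"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if "climate" in self.formula.replace(" ", "").split("~")[-1].split("+"):
            raise ValueError("baseline formula must not contain a term named 'climate'")


@dataclass
class FittedModel:
    """A fitted model reduced to what model selection needs."""

    params: pd.Series
    bse: pd.Series
    llf: float
    n_params: int                  # rho: estimated parameters incl. dispersion
    nobs: int
    fittedvalues: np.ndarray
    family: str
    # internals used for refitting with climate terms appended
    _y: np.ndarray = field(repr=False, default=None)
    _X: np.ndarray = field(repr=False, default=None)
    _xnames: list = field(repr=False, default_factory=list)

    @property
    def rsquared(self) -> float:
        """Proportion of response variance explained (gaussian only)."""
        if self.family != "gaussian":
            raise ValueError("rsquared is defined here for gaussian fits only")
        resid = self._y - self.fittedvalues
        tss = ((self._y - self._y.mean()) ** 2).sum()
        return 1.0 - (resid ** 2).sum() / tss


def gaussian_loglik(rss: float, n: int) -> float:
    """Maximum gaussian log-likelihood given the residual sum of squares."""
    return -0.5 * n * (np.log(2 * np.pi) + np.log(rss / n) + 1.0)


def _fit_design(y: np.ndarray, X: np.ndarray, xnames: list, family: str) -> FittedModel:
    if np.any(~np.isfinite(y)) or np.any(~np.isfinite(X)):
        raise FitError("non-finite values in response or design")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise FitError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} columns); "
            "collinear or inestimable terms"
        )
    n, p = X.shape
    if family == "gaussian":
        res = sm.OLS(y, X).fit()
        rho = p + 1  # residual variance is an estimated parameter
        llf = res.llf
    else:
        fam = sm.families.Poisson() if family == "poisson" else sm.families.Binomial()
        try:
            res = sm.GLM(y, X, family=fam).fit()
        except Exception as exc:  # perfect separation etc.
            raise FitError(f"GLM fit failed: {exc}") from exc
        rho = p
        llf = res.llf
    return FittedModel(
        params=pd.Series(np.asarray(res.params), index=xnames),
        bse=pd.Series(np.asarray(res.bse), index=xnames),
        llf=float(llf),
        n_params=rho,
        nobs=n,
        fittedvalues=np.asarray(res.fittedvalues),
        family=family,
        _y=y,
        _X=X,
        _xnames=list(xnames),
    )


def fit_baseline(spec: BaselineSpec) -> FittedModel:
    """Fit the climate-free baseline by maximum likelihood (OLS for gaussian)."""
    try:
        y_dm, X_dm = patsy.dmatrices(spec.formula, spec.data, return_type="dataframe")
    except Exception as exc:
        raise FitError(f"could not build design from formula {spec.formula!r}: {exc}") from exc
    y = y_dm.to_numpy(dtype=float).ravel()
    X = X_dm.to_numpy(dtype=float)
    if X.shape[0] <= X.shape[1]:
        raise FitError(f"too few rows ({X.shape[0]}) for {X.shape[1]} design columns")
    return _fit_design(y, X, list(X_dm.columns), spec.family)


def climate_columns(climate: np.ndarray, func: str = "lin",
                    centred: tuple[np.ndarray, np.ndarray] | None = None
                    ) -> tuple[np.ndarray, list[str]]:
    """Expand an aggregate climate vector into model columns for ``func``.

    ``centred`` replaces the single (linear) climate term by two columns:
    the within-group deviation and the group mean.
    """
    x = np.asarray(climate, dtype=float)
    if centred is not None:
        if func != "lin":
            raise ValueError("within-group centring is defined for the linear climate term")
        dev, mean = (np.asarray(a, dtype=float) for a in centred)
        return np.column_stack([dev, mean]), ["climate_dev", "climate_mean"]
    if func == "lin":
        return x[:, None], ["climate"]
    if func == "quad":
        return np.column_stack([x, x ** 2]), ["climate", "climate^2"]
    if func == "cub":
        return np.column_stack([x, x ** 2, x ** 3]), ["climate", "climate^2", "climate^3"]
    if func == "log":
        if np.any(x <= 0):
            raise ValueError("func='log' requires strictly positive climate values")
        return np.log(x)[:, None], ["log(climate)"]
    if func == "inv":
        if np.any(x == 0):
            raise ValueError("func='inv' requires non-zero climate values")
        return (1.0 / x)[:, None], ["1/climate"]
    raise ValueError(f"func must be one of {CLIMATE_FUNCS}, got {func!r}")


def attach_climate(base: FittedModel, climate, func: str = "lin",
                   centred: tuple | None = None) -> FittedModel:
    """Refit the baseline with climate terms appended, on identical rows."""
    cols, names = climate_columns(climate, func=func, centred=centred)
    if cols.shape[0] != base.nobs:
        raise ValueError(f"climate vector length {cols.shape[0]} != N = {base.nobs}")
    X = np.column_stack([base._X, cols])
    return _fit_design(base._y, X, base._xnames + names, base.family)


def aicc(model: FittedModel) -> float:
    """Sample-size corrected AIC of a fitted model."""
    rho, n = model.n_params, model.nobs
    if n - rho - 1 <= 0:
        raise ValueError(f"AICc undefined: N = {n} <= rho + 1 = {rho + 1}")
    return -2.0 * model.llf + 2.0 * rho + 2.0 * rho * (rho + 1) / (n - rho - 1)


def delta_aicc(model: FittedModel, baseline: FittedModel) -> float:
    """AICc(model) - AICc(baseline); negative means climate improves the fit."""
    if model.nobs != baseline.nobs:
        raise ValueError("model and baseline must be fitted on identical rows")
    return aicc(model) - aicc(baseline)
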