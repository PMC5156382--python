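"""Parametric weighted-window analysis.

Instead of a uniform weight over a hard-edged window, a Weibull or
generalized extreme value (GEV) density over the climate history defines a
weighted climate mean, and (shape, scale, location) are optimized to
minimize dAICc by bounded quasi-Newton search (L-BFGS-B).  The density is
evaluated on normalized time t in [0, 1] across the offset range (at the
midpoint of each day's interval) and renormalized to sum to one, so the
weights are exactly a discrete distribution; small t = recent climate.

The uniform special case recovers the sliding search: a weight vector
uniform over [end, start] and zero elsewhere gives precisely the mean-stat
aggregate of that window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import models as _m
from .timeframe import (
    BiologicalTable,
    ClimateMatrix,
    ClimateSeries,
    apply_reference,
    build_climate_matrix,
)

__all__ = ["WeightParams", "WeightedResult", "weight_curve", "weighted_climate",
           "weightwin", "explore", "DEFAULT_BOUNDS"]

# bounds on (shape, scale, location) in normalized time, user-overridable
DEFAULT_BOUNDS = {
    "weibull": ((1e-2, 20.0), (1e-2, 5.0), (-5.0, 5.0)),
    "gev": ((-5.0, 5.0), (1e-2, 5.0), (-5.0, 5.0)),
}
_PENALTY = 1e10


class DegenerateWeightsError(ValueError):
    """The density is (numerically) zero everywhere on the offset grid."""


@dataclass(frozen=True)
class WeightParams:
    """Weight-function parameters on the normalized time axis.

    family 'weibull' needs shape > 0 and scale > 0; 'gev' needs scale > 0
    and uses the standard GEV shape xi (the Gumbel limit is taken for
    |shape| < 1e-6, where the density is continuous in xi).
    """

    family: str
    shape: float
    scale: float
    location: float = 0.0
    range: tuple[int, int] = (365, 0)

    def __post_init__(self):
        if self.family not in ("weibull", "gev"):
            raise ValueError(f"family must be 'weibull' or 'gev', got {self.family!r}")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.family == "weibull" and self.shape <= 0:
            raise ValueError("weibull shape must be positive")


@dataclass
class WeightedResult:
    """Optimized weighted-window fit and its optimizer report."""

    params: WeightParams
    delta_aicc: float
    beta: float
    se: float
    weights: np.ndarray
    offsets: np.ndarray
    converged: bool
    n_iter: int
    n_eval: int
    message: str
    trace: list = field(repr=False, default_factory=list)
    model: _m.FittedModel | None = field(repr=False, default=None)
    baseline_aicc: float = np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "delta_aicc": self.delta_aicc, "shape": self.params.shape,
            "scale": self.params.scale, "location": self.params.location,
            "beta": self.beta, "se": self.se, "converged": self.converged,
        }])


def _density(family: str, t: np.ndarray, shape: float, scale: float, location: float) -> np.ndarray:
    if family == "weibull":
        return stats.weibull_min.pdf(t, c=shape, loc=location, scale=scale)
    # scipy's genextreme uses c = -xi relative to the standard GEV shape
    xi = 0.0 if abs(shape) < 1e-6 else shape
    return stats.genextreme.pdf(t, c=-xi, loc=location, scale=scale)


def weight_curve(params: WeightParams) -> np.ndarray:
    """Discrete weights over offsets range_min..range_max, summing to one.

    Offset j maps to normalized time t = (j - range_min + 1/2) / m with
    m = range_max - range_min + 1; the density at the day midpoints is
    normalized by its sum.  An all-zero density raises
    :class:`DegenerateWeightsError`.
    """
    rmax, rmin = params.range
    m = rmax - rmin + 1
    t = (np.arange(m) + 0.5) / m
    dens = _density(params.family, t, params.shape, params.scale, params.location)
    total = dens.sum()
    if not np.isfinite(total) or total <= 0:
        raise DegenerateWeightsError(
            f"weight density is zero/non-finite over the whole range for {params}"
        )
    return dens / total


def weighted_climate(matrix: ClimateMatrix, weights: np.ndarray) -> np.ndarray:
    """Per-record weighted climate mean (row-wise dot product)."""
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != matrix.values.shape[1]:
        raise ValueError(
            f"weight length {weights.shape[0]} != matrix columns {matrix.values.shape[1]}"
        )
    return matrix.values @ weights


def explore(params: WeightParams) -> pd.DataFrame:
    """Tabulate a weight curve as (offset, weight) pairs for plotting.

    Used to pick sensible starting parameters before optimization.
    """
    w = weight_curve(params)
    rmax, rmin = params.range
    return pd.DataFrame({"offset": np.arange(rmin, rmax + 1), "weight": w})


def weightwin(baseline: _m.BaselineSpec, series: ClimateSeries, biol: BiologicalTable,
              family: str = "weibull", par0: tuple[float, float, float] = (3.0, 0.2, 0.0),
              range: tuple[int, int] = (365, 0), window_type: str = "relative",
              refday: tuple[int, int] | None = None, func: str = "lin",
              method: str = "L-BFGS-B", bounds=None,
              options: dict | None = None) -> WeightedResult:
    """Optimize (shape, scale, location) to minimize dAICc.

    The objective composes weight_curve -> weighted_climate ->
    attach_climate -> delta_aicc; parameter sets with invalid or degenerate
    densities return a large penalty so the bounded search steps back.
    Deterministic for fixed (par0, method, bounds).  Non-convergence is
    reported on the result, with the best parameters seen so far.
    """
    rmax, rmin = range
    adjusted = apply_reference(biol.dates, window_type, refday)
    matrix = build_climate_matrix(series, adjusted, rmax, rmin)
    base = _m.fit_baseline(baseline)
    if bounds is None:
        bounds = DEFAULT_BOUNDS[family]

    trace: list[tuple] = []
    best = {"obj": np.inf, "params": None}

    def objective(theta) -> float:
        shape, scale, location = map(float, theta)
        try:
            p = WeightParams(family, shape, scale, location, range=(rmax, rmin))
            w = weight_curve(p)
            agg = weighted_climate(matrix, w)
            fitted = _m.attach_climate(base, agg, func=func)
            obj = _m.delta_aicc(fitted, base)
        except (ValueError, _m.FitError):
            return _PENALTY
        trace.append((shape, scale, location, obj))
        if obj < best["obj"]:
            best["obj"] = obj
            best["params"] = p
        return obj

    x0 = np.asarray(par0, dtype=float)
    if not all(lo <= v <= hi for v, (lo, hi) in zip(x0, bounds)):
        raise ValueError(f"par0 {tuple(x0)} outside bounds {bounds}")
    res = optimize.minimize(objective, x0, method=method, bounds=bounds,
                            options=options or {})

    params = best["params"]
    if params is None:
        raise DegenerateWeightsError("objective was never finite; check par0/bounds")
    w = weight_curve(params)
    agg = weighted_climate(matrix, w)
    fitted = _m.attach_climate(base, agg, func=func)
    d = _m.delta_aicc(fitted, base)
    p0 = base._X.shape[1]
    return WeightedResult(
        params=params, delta_aicc=d,
        beta=float(fitted.params.iloc[p0]), se=float(fitted.bse.iloc[p0]),
        weights=w, offsets=np.arange(rmin, rmax + 1),
        converged=bool(res.success), n_iter=int(getattr(res, "nit", 0)),
        n_eval=int(res.nfev), message=str(res.message), trace=trace,
        model=fitted, baseline_aicc=_m.aicc(base),
    )
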