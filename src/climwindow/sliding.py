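"""Exhaustive sliding-window search ranked by dAICc.

For a range (range_max, range_min) every closed window [end, start] with
range_min <= end <= start <= range_max is a candidate: the climate inside
it is aggregated per record, appended to the baseline model, and the refit
is scored by dAICc against the baseline.  The number of candidates is
m(m+1)/2 with m = range_max - range_min + 1, so a one-year daily search
(range 365..0) fits 67,161 models.

Gaussian/linear searches take a closed-form OLS path vectorized across all
windows (algebraically identical to refitting each window with statsmodels,
which the generic path does and the tests cross-check).  Optional k-fold
cross-validation replaces each window's dAICc by an out-of-sample version
based on test-fold mean squared error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import models as _m
from .timeframe import (
    BiologicalTable,
    ClimateMatrix,
    ClimateSeries,
    WindowSpec,
    aggregate_window,
    apply_reference,
    block_matrix,
    build_climate_matrix,
    centre_split,
)

logger = logging.getLogger(__name__)

__all__ = ["SlidingConfig", "CandidateRecord", "ModelSet", "enumerate_windows", "slidingwin",
           "crossvalidate_window"]


@dataclass
class SlidingConfig:
    """Settings for one sliding-window run.

    range is (range_max, range_min) in cinterval units (days by default);
    k = 0 disables cross-validation; seed feeds fold assignment and is
    recorded so runs are reproducible byte for byte.
    """

    range: tuple[int, int] = (365, 0)
    stat: str = "mean"
    func: str = "lin"
    window_type: str = "relative"
    refday: tuple[int, int] | None = None
    k: int = 0
    centre: bool = False
    cinterval: str = "day"
    seed: int | None = None

    def __post_init__(self):
        rmax, rmin = self.range
        if rmin < 0 or rmax < rmin:
            raise ValueError(f"need range_max >= range_min >= 0, got {self.range}")
        if self.k < 0 or self.k == 1:
            raise ValueError("k must be 0 (off) or >= 2")


@dataclass(frozen=True)
class CandidateRecord:
    """One tested window and its fit summary."""

    window_start: int
    window_end: int
    delta_aicc: float
    betas: tuple
    ses: tuple
    akaike_weight: float | None = None
    ok: bool = True
    note: str = ""


@dataclass
class ModelSet:
    """All candidates from one run, sorted ascending by dAICc (best first)."""

    frame: pd.DataFrame
    config: SlidingConfig
    baseline_aicc: float
    baseline_model: _m.FittedModel
    best_model: _m.FittedModel | None
    best_climate: np.ndarray | None
    matrix: ClimateMatrix = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def best(self) -> pd.Series:
        return self.frame.iloc[0]

    def records(self) -> list[CandidateRecord]:
        beta_cols = [c for c in self.frame.columns if c.startswith("beta")]
        se_cols = [c for c in self.frame.columns if c.startswith("se")]
        out = []
        for _, row in self.frame.iterrows():
            out.append(CandidateRecord(
                int(row.window_start), int(row.window_end), float(row.delta_aicc),
                tuple(row[c] for c in beta_cols), tuple(row[c] for c in se_cols),
                akaike_weight=float(row.mod_weight) if "mod_weight" in row else None,
                ok=bool(row.ok), note=str(row.get("note", "")),
            ))
        return out


def enumerate_windows(range_max: int, range_min: int = 0) -> list[WindowSpec]:
    """All candidate windows, start descending then end descending."""
    if range_min < 0:
        raise ValueError("offsets must be non-negative")
    if range_max < range_min:
        raise ValueError("range_max must be >= range_min")
    return [WindowSpec(start=s, end=e)
            for s in range(range_max, range_min - 1, -1)
            for e in range(s, range_min - 1, -1)]


def _window_aggregates(matrix: ClimateMatrix, windows, stat: str) -> np.ndarray:
    """Aggregate matrix A with A[w] = per-record aggregate of window w."""
    vals = matrix.values
    n, c = vals.shape
    A = np.empty((len(windows), n))
    if stat in ("mean", "sum"):
        cs = np.concatenate([np.zeros((n, 1)), np.cumsum(vals, axis=1)], axis=1)
        for i, w in enumerate(windows):
            j0, j1 = w.end - matrix.range_min, w.start - matrix.range_min
            s = cs[:, j1 + 1] - cs[:, j0]
            A[i] = s / (j1 - j0 + 1) if stat == "mean" else s
    else:
        for i, w in enumerate(windows):
            A[i] = aggregate_window(matrix, w, stat)
    return A


def _sort_modelset(frame: pd.DataFrame) -> pd.DataFrame:
    """Ascending dAICc; ties broken by shorter window, then later (smaller) end."""
    key = frame.assign(
        _d=frame.delta_aicc.fillna(np.inf),
        _len=frame.window_start - frame.window_end,
    ).sort_values(["_d", "_len", "window_end"], kind="mergesort")
    return frame.loc[key.index].reset_index(drop=True)


def _fold_indices(n: int, k: int, seed) -> list[np.ndarray]:
    if not (2 <= k <= n):
        raise ValueError(f"need 2 <= k <= N, got k={k}, N={n}")
    rng = np.random.default_rng(seed)
    return [np.sort(f) for f in np.array_split(rng.permutation(n), k)]


def _mse_aicc(mse: float, rho: int, n: int) -> float:
    """Out-of-sample AICc from a test-set MSE (N is the total sample size)."""
    if n - rho - 1 <= 0:
        raise ValueError("AICc undefined: N <= rho + 1")
    return n * np.log(mse) + 2.0 * rho + 2.0 * rho * (rho + 1) / (n - rho - 1)


def crossvalidate_window(y: np.ndarray, X0: np.ndarray, climate_cols: np.ndarray,
                         k: int, seed, folds: list[np.ndarray] | None = None) -> float:
    """Cross-validated dAICc of one window model against the baseline.

    Per fold: fit both models on training rows, score each by test-row MSE
    converted to AICc with N = total sample size, difference the two, and
    average the k fold differences.  Gaussian responses only (the score is
    MSE-based).
    """
    n = len(y)
    p0 = X0.shape[1]
    Xw = np.column_stack([X0, climate_cols])
    p1 = Xw.shape[1]
    if folds is None:
        folds = _fold_indices(n, k, seed)
    deltas = []
    for test in folds:
        if len(test) == 0:
            raise ValueError("empty cross-validation fold")
        train = np.setdiff1d(np.arange(n), test)
        b0, *_ = np.linalg.lstsq(X0[train], y[train], rcond=None)
        bw, *_ = np.linalg.lstsq(Xw[train], y[train], rcond=None)
        mse0 = float(np.mean((y[test] - X0[test] @ b0) ** 2))
        msew = float(np.mean((y[test] - Xw[test] @ bw) ** 2))
        deltas.append(_mse_aicc(msew, p1 + 1, n) - _mse_aicc(mse0, p0 + 1, n))
    return float(np.mean(deltas))


def _fast_ols_scan(y: np.ndarray, X0: np.ndarray, A: np.ndarray, rho0: int):
    """Closed-form OLS of y ~ X0 + climate for every row of A at once.

    Returns (delta_aicc, beta, se, ok) arrays.  Uses the standard
    residual-regression identity: after projecting out the baseline design,
    the climate slope, its variance and the full-model RSS follow from the
    residualized cross-products.
    """
    n, p0 = X0.shape
    G = X0.T @ X0
    GinvXT = np.linalg.solve(G, X0.T)
    y_r = y - X0 @ (GinvXT @ y)
    rss0 = float(y_r @ y_r)
    Z = A.T                                   # N x n_windows
    Z_r = Z - X0 @ (GinvXT @ Z)
    szz = np.einsum("ij,ij->j", Z_r, Z_r)
    szy = Z_r.T @ y_r
    ok = szz > 1e-10 * max(np.abs(Z).max() ** 2, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(ok, szy / np.where(ok, szz, 1.0), np.nan)
        rss = np.where(ok, rss0 - beta * szy, np.nan)
        rss = np.maximum(rss, 1e-300)
        sigma2 = rss / (n - p0 - 1)
        se = np.sqrt(sigma2 / np.where(ok, szz, np.nan))
        llf = -0.5 * n * (np.log(2 * np.pi) + np.log(rss / n) + 1.0)
    rho1 = rho0 + 1
    aicc1 = -2.0 * llf + 2.0 * rho1 + 2.0 * rho1 * (rho1 + 1) / (n - rho1 - 1)
    llf0 = _m.gaussian_loglik(rss0, n)
    aicc0 = -2.0 * llf0 + 2.0 * rho0 + 2.0 * rho0 * (rho0 + 1) / (n - rho0 - 1)
    return aicc1 - aicc0, beta, se, ok


def _fast_ols_cv(y: np.ndarray, X0: np.ndarray, A: np.ndarray, folds) -> np.ndarray:
    """Vectorized cross-validated dAICc for the gaussian/linear scan."""
    n, p0 = X0.shape
    nw = A.shape[0]
    Z = A.T
    deltas = np.zeros(nw)
    rho0, rho1 = p0 + 1, p0 + 2
    for test in folds:
        train = np.setdiff1d(np.arange(n), test)
        X0t, yt = X0[train], y[train]
        G = X0t.T @ X0t
        GinvXT = np.linalg.solve(G, X0t.T)
        a0 = GinvXT @ yt                      # baseline coefs on train
        C = GinvXT @ Z[train]                 # p0 x nw
        y_r = yt - X0t @ a0
        Z_r = Z[train] - X0t @ C
        szz = np.einsum("ij,ij->j", Z_r, Z_r)
        szy = Z_r.T @ y_r
        with np.errstate(divide="ignore", invalid="ignore"):
            b = szy / szz                     # climate slope per window
        gamma = a0[:, None] - C * b[None, :]  # baseline coefs in full model
        pred = X0[test] @ gamma + Z[test] * b[None, :]
        msew = np.mean((y[test, None] - pred) ** 2, axis=0)
        mse0 = float(np.mean((y[test] - X0[test] @ a0) ** 2))
        deltas += (n * np.log(msew) + 2 * rho1 + 2 * rho1 * (rho1 + 1) / (n - rho1 - 1)) \
            - (n * np.log(mse0) + 2 * rho0 + 2 * rho0 * (rho0 + 1) / (n - rho0 - 1))
    return deltas / len(folds)


def slidingwin(baseline: _m.BaselineSpec, series: ClimateSeries, biol: BiologicalTable,
               config: SlidingConfig) -> ModelSet:
    """Run the exhaustive window search and return the ranked model set.

    Windows whose model cannot be fitted (undefined aggregate transform,
    collinearity) are retained as flagged records with missing dAICc so the
    set always has m(m+1)/2 rows.
    """
    if config.k and baseline.family != "gaussian":
        raise ValueError("k-fold cross-validation is MSE-based and requires a gaussian response")
    adjusted = apply_reference(biol.dates, config.window_type, config.refday)
    rmax, rmin = config.range
    if config.cinterval == "day":
        matrix = build_climate_matrix(series, adjusted, rmax, rmin)
    else:
        span = 7 * (rmax + 1) if config.cinterval == "week" else 31 * (rmax + 1) + 7
        daily = build_climate_matrix(series, adjusted, span - 1, 0)
        matrix = block_matrix(daily, config.cinterval)
        if matrix.range_max < rmax:
            raise ValueError("climate span too short for the requested block range")
        matrix = ClimateMatrix(matrix.values[:, rmin:rmax + 1], matrix.adjusted_dates,
                               range_max=rmax, range_min=rmin, cinterval=config.cinterval)

    base = _m.fit_baseline(baseline)
    windows = enumerate_windows(rmax, rmin)
    A = _window_aggregates(matrix, windows, config.stat)
    n = base.nobs
    if A.shape[1] != n:
        raise ValueError("biological table and baseline data have different row counts")

    folds = _fold_indices(n, config.k, config.seed) if config.k else None
    fast = (baseline.family == "gaussian" and config.func == "lin"
            and not config.centre and np.all(np.isfinite(A)))

    starts = np.array([w.start for w in windows])
    ends = np.array([w.end for w in windows])
    if fast:
        delta, beta, se, ok = _fast_ols_scan(base._y, base._X, A, base.n_params)
        if config.k:
            cv_delta = np.full(len(windows), np.nan)
            cv_delta[ok] = _fast_ols_cv(base._y, base._X, A[ok], folds)
            delta = cv_delta
        frame = pd.DataFrame({
            "window_start": starts, "window_end": ends, "delta_aicc": delta,
            "beta": beta, "se": se, "ok": ok,
            "note": np.where(ok, "", "degenerate climate term"),
        })
    else:
        rows = []
        for i, w in enumerate(windows):
            agg = A[i]
            try:
                if not np.all(np.isfinite(agg)):
                    raise ValueError("aggregate not finite")
                centred = centre_split(agg, biol.group) if config.centre else None
                fitted = _m.attach_climate(base, agg, func=config.func, centred=centred)
                if config.k:
                    cols, _ = _m.climate_columns(agg, func=config.func, centred=centred)
                    d = crossvalidate_window(base._y, base._X, cols, config.k,
                                             config.seed, folds=folds)
                else:
                    d = _m.delta_aicc(fitted, base)
                cb = fitted.params.iloc[base._X.shape[1]:]
                cs = fitted.bse.iloc[base._X.shape[1]:]
                rows.append((w.start, w.end, d, tuple(cb), tuple(cs), True, ""))
            except (ValueError, _m.FitError) as exc:
                logger.warning("window (%d, %d) not fitted: %s", w.start, w.end, exc)
                rows.append((w.start, w.end, np.nan, (), (), False, str(exc)))
        n_terms = max((len(r[3]) for r in rows), default=1) or 1
        bnames = ["beta"] if n_terms == 1 else [f"beta{i+1}" for i in range(n_terms)]
        snames = ["se"] if n_terms == 1 else [f"se{i+1}" for i in range(n_terms)]
        frame = pd.DataFrame([
            {"window_start": s, "window_end": e, "delta_aicc": d,
             **{bn: (b[i] if i < len(b) else np.nan) for i, bn in enumerate(bnames)},
             **{sn: (v[i] if i < len(v) else np.nan) for i, sn in enumerate(snames)},
             "ok": okf, "note": note}
            for (s, e, d, b, v, okf, note) in rows
        ])

    frame = _sort_modelset(frame)
    from .inference import akaike_weights  # deferred: inference builds on ModelSet
    w = np.full(len(frame), np.nan)
    finite = frame.delta_aicc.notna().to_numpy()
    if finite.any():
        w[finite] = akaike_weights(frame.delta_aicc.to_numpy()[finite])
    frame["mod_weight"] = w

    best_model = None
    best_climate = None
    if finite.any():
        brow = frame.iloc[0]
        bw = WindowSpec(int(brow.window_start), int(brow.window_end))
        best_climate = aggregate_window(matrix, bw, config.stat)
        try:
            centred = centre_split(best_climate, biol.group) if config.centre else None
            best_model = _m.attach_climate(base, best_climate, func=config.func, centred=centred)
        except (_m.FitError, ValueError):  # pragma: no cover - best window fitted above
            best_model = None

    return ModelSet(frame=frame, config=replace(config), baseline_aicc=_m.aicc(base),
                    baseline_model=base, best_model=best_model,
                    best_climate=best_climate, matrix=matrix)
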