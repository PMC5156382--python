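"""Synthetic datasets with a known climate window.

Emulates the simulation design behind the method-performance results: a
daily AR(1) gaussian climate series over N years, and one biological
record per year whose response is a linear function of mean climate inside
a known true window plus gaussian noise scaled to a target R-squared.
Everything is reproducible from (spec, seed), and the generator is the
offline stand-in for real field data in tests and examples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date

import numpy as np
import pandas as pd

from .timeframe import BiologicalTable, ClimateSeries, WindowSpec, aggregate_window, build_climate_matrix

__all__ = ["SyntheticSpec", "gen_climate", "gen_dataset", "performance_study"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    One record per year on a fixed measurement day; the true signal is
    beta * mean(climate over true_window days before measurement).  Noise
    variance solves R2 = Var(signal) / (Var(signal) + Var(eps)) on the
    realized windowed means, so target_r2 is a property of each generated
    series; target_r2 = 0 forces beta = 0 (a pure-null dataset with unit
    response noise around the intercept).  noise_sd, when set, overrides
    the R2 calculation (noise_sd = 0 gives the noiseless boundary case
    used internally by tests).
    """

    n_records: int = 47
    start_year: int = 1966
    true_window: tuple[int, int] = (30, 10)     # (start, end) offsets, days
    beta: float = -3.0
    target_r2: float = 0.4
    climate_autocorr: float = 0.5
    intercept: float = 100.0
    measurement_day: tuple[int, int] = (20, 5)  # (day, month), fixed each year
    lead_in: int = 400                          # climate days before first record
    noise_sd: float | None = None
    family: str = "gaussian"
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd is None:
            if not (0.0 <= self.target_r2 < 1.0):
                raise ValueError("target_r2 must be in [0, 1)")
            if (self.target_r2 == 0.0) != (self.beta == 0.0):
                raise ValueError("target_r2 = 0 if and only if beta = 0")
        if not (0.0 <= self.climate_autocorr < 1.0):
            raise ValueError("climate_autocorr must be in [0, 1)")
        s, e = self.true_window
        if not (0 <= e <= s):
            raise ValueError("true_window must satisfy 0 <= end <= start")
        if s > self.lead_in:
            raise ValueError("true_window extends beyond the climate lead-in")
        if self.n_records < 3:
            raise ValueError("need at least 3 records")


def measurement_dates(spec: SyntheticSpec) -> np.ndarray:
    d, m = spec.measurement_day
    return np.array([date(spec.start_year + i, m, d).toordinal()
                     for i in range(spec.n_records)], dtype=np.int64)


def gen_climate(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> ClimateSeries:
    """Daily AR(1) climate with unit marginal variance and mean zero.

    x[t] = phi * x[t-1] + sqrt(1 - phi^2) * eps[t], initialized from the
    stationary distribution, spanning lead_in days before the first record
    through the last measurement date.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    dates_b = measurement_dates(spec)
    first, last = int(dates_b[0]) - spec.lead_in, int(dates_b[-1])
    n = last - first + 1
    phi = spec.climate_autocorr
    eps = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = eps[0]
    innov_sd = np.sqrt(1.0 - phi ** 2)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + innov_sd * eps[t]
    return ClimateSeries(np.arange(first, last + 1, dtype=np.int64), x, name="climate")


def gen_dataset(spec: SyntheticSpec) -> tuple[ClimateSeries, BiologicalTable]:
    """One (climate, biology) pair with the spec's embedded signal."""
    rng = np.random.default_rng(spec.seed)
    series = gen_climate(spec, rng)
    dates_b = measurement_dates(spec)
    s, e = spec.true_window
    matrix = build_climate_matrix(series, dates_b, s, 0)
    signal_x = aggregate_window(matrix, WindowSpec(s, e), "mean")
    if spec.noise_sd is not None:
        sd = spec.noise_sd
        beta = spec.beta
    elif spec.target_r2 == 0.0:
        sd, beta = 1.0, 0.0
    else:
        var_signal = float(np.var(spec.beta * signal_x))
        sd = np.sqrt(var_signal * (1.0 - spec.target_r2) / spec.target_r2)
        beta = spec.beta
    response = spec.intercept + beta * signal_x + sd * rng.standard_normal(spec.n_records)
    biol = BiologicalTable(dates_b, response, response_name="response")
    return series, biol


def _jaccard(w1: tuple[int, int], w2: tuple[int, int]) -> float:
    a = set(range(w1[1], w1[0] + 1))
    b = set(range(w2[1], w2[0] + 1))
    return len(a & b) / len(a | b)


def performance_study(n_grid=(10, 47), r2_grid=(0.0, 0.2, 0.8), reps: int = 25,
                      *, search_range: tuple[int, int] = (40, 0), k: int = 0,
                      rand_repeats: int = 5, threshold: float = 0.5,
                      base_spec: SyntheticSpec | None = None, seed: int = 0,
                      ) -> pd.DataFrame:
    """Misclassification and R2-bias table over a (sample size, R2) grid.

    Per grid cell, reps datasets are generated; each gets a sliding-window
    search (optionally k-fold cross-validated) plus a small randomization
    run, and is classified as 'signal' when the reported-orientation P_C
    (small = credible) falls below the threshold.  Reported per cell:
    false-positive rate (null cells), false-negative rate (signal cells),
    median estimated R2 of the best window, and the median realized dAICc.
    """
    from .inference import c_statistic, p_c, randwin
    from .models import BaselineSpec
    from .sliding import SlidingConfig, slidingwin

    if base_spec is None:
        base_spec = SyntheticSpec()
    rows = []
    rng = np.random.default_rng(seed)
    for n in n_grid:
        for r2 in r2_grid:
            null_cell = (r2 == 0.0)
            miss = 0
            r2_hats = []
            deltas = []
            jaccards = []
            for _ in range(reps):
                spec = replace(base_spec, n_records=n, target_r2=r2,
                               beta=0.0 if null_cell else base_spec.beta,
                               seed=int(rng.integers(2 ** 31 - 1)))
                series, biol = gen_dataset(spec)
                baseline = BaselineSpec("response ~ 1", biol.to_frame())
                config = SlidingConfig(range=search_range, stat="mean", func="lin",
                                       window_type="relative", k=k,
                                       seed=int(rng.integers(2 ** 31 - 1)))
                ms = slidingwin(baseline, series, biol, config)
                rand = randwin(rand_repeats, baseline, series, biol,
                               window="sliding", config=config,
                               seed=int(rng.integers(2 ** 31 - 1)))
                report = p_c(c_statistic(ms, percent=False), rand, n=n,
                             cv=bool(k), orientation="reported")
                detected = report.value < threshold
                if null_cell and detected:
                    miss += 1
                if not null_cell and not detected:
                    miss += 1
                best = ms.best
                deltas.append(float(best.delta_aicc))
                if ms.best_model is not None:
                    r2_hats.append(ms.best_model.rsquared)
                if not null_cell:
                    jaccards.append(_jaccard(
                        (int(best.window_start), int(best.window_end)),
                        spec.true_window))
            rows.append({
                "n": n, "true_r2": r2, "cv": bool(k), "reps": reps,
                "misclassification_rate": miss / reps,
                "rate_kind": "false_positive" if null_cell else "false_negative",
                "median_r2_hat": float(np.median(r2_hats)) if r2_hats else np.nan,
                "median_delta_aicc": float(np.median(deltas)),
                "mean_jaccard": float(np.mean(jaccards)) if jaccards else np.nan,
            })
    return pd.DataFrame(rows)
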