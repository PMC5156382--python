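"""Weighted-window analysis of a fading-memory climate signal.

The response is driven by an exponentially decaying weighting of past
climate (recent days matter most) - exactly the situation a hard-edged
uniform window cannot represent.  A Weibull weight curve over normalized
time is optimized by bounded quasi-Newton search to minimize dAICc, and
beats the best uniform window.
"""

import numpy as np

import climwindow as cw
from climwindow import weighted as wt

# climate series and annual records
spec = cw.SyntheticSpec(n_records=47, true_window=(60, 0), beta=0.0,
                        target_r2=0.0, seed=31)
series, _ = cw.gen_dataset(spec)
dates = np.array([series.dates[-1] - 365 * i for i in range(47)])[::-1]
matrix = cw.build_climate_matrix(series, dates, 60)

# response = exponentially weighted mean climate + noise (true R^2 = 0.8)
true_curve = wt.weight_curve(wt.WeightParams("weibull", 1.0, 0.15, 0.0, range=(60, 0)))
signal = wt.weighted_climate(matrix, true_curve)
rng = np.random.default_rng(5)
resp = 50 + 2.0 * signal + np.sqrt(np.var(2.0 * signal) * 0.25) * rng.standard_normal(47)
biol = cw.BiologicalTable(dates, resp)

# inspect a candidate starting curve, then optimize
start = cw.explore(wt.WeightParams("weibull", 2.0, 0.3, 0.0, range=(60, 0)))
print(f"starting curve: mode at offset {start.loc[start.weight.idxmax(), 'offset']} days,"
      f" weights sum {start.weight.sum():.3f}")

baseline = cw.BaselineSpec("response ~ 1", biol.to_frame())
result = cw.weightwin(baseline, series, biol, family="weibull",
                      par0=(2.0, 0.3, 0.0), range=(60, 0))
sliding = cw.slidingwin(baseline, series, biol, cw.SlidingConfig(range=(60, 0)))

print(f"optimized: shape {result.params.shape:.2f}, scale {result.params.scale:.2f}, "
      f"location {result.params.location:.2f} (converged={result.converged}, "
      f"{result.n_eval} evaluations)")
print(f"weighted-window dAICc: {result.delta_aicc:.2f}, slope {result.beta:.2f}")
print(f"best uniform window:   dAICc {sliding.best.delta_aicc:.2f} "
      f"({int(sliding.best.window_start)}-{int(sliding.best.window_end)} days)")
print(f"L1 distance of fitted curve from the generating curve: "
      f"{np.abs(result.weights - true_curve).sum():.3f}")
print()
print("The fitted curve decays from offset 0 like the generating exponential, and")
print("its dAICc advantage over the best uniform window is the gain from letting")
print("weights fade gradually instead of cutting off at window edges.")
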