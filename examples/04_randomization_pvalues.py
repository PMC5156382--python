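"""Randomization-based error metrics: P_dAICc and P_C.

An exhaustive search over hundreds of autocorrelated windows will always
find some 'best' window, so the observed dAICc must be compared with what
the same search finds on date-permuted (signal-free) data.  P_dAICc is the
permutation rank of the observed dAICc (needs many repeats); P_C is a
logistic calibration of the confidence-set shift dC usable with as few as
5 repeats.
"""

import numpy as np

import climwindow as cw

spec = cw.SyntheticSpec(n_records=47, true_window=(30, 10), target_r2=0.4, seed=7)
series, biol = cw.gen_dataset(spec)
baseline = cw.BaselineSpec("response ~ 1", biol.to_frame())
config = cw.SlidingConfig(range=(40, 0))
modelset = cw.slidingwin(baseline, series, biol, config)
observed = float(modelset.best.delta_aicc)
c_obs = cw.c_statistic(modelset, percent=False)

rand = cw.randwin(99, baseline, series, biol, window="sliding", config=config, seed=11)
p_d = cw.p_delta_aicc(observed, rand)
p_c_reported = cw.p_c(c_obs, rand, n=47, orientation="reported")
p_c_verbatim = cw.p_c(c_obs, rand, n=47, orientation="verbatim")

print(f"observed best dAICc: {observed:.2f}; randomized median: "
      f"{np.median(rand.delta_aicc):.2f}; shift dD = {cw.delta_d(observed, rand):.2f}")
print(f"P_dAICc = {p_d.text}  ({rand.repeats} permutations)")
print(f"C observed = {100 * c_obs:.1f}%, randomized median = "
      f"{100 * p_c_reported.inputs['c_rand_median']:.1f}% "
      f"(dC = {p_c_reported.inputs['delta_c']:.2f})")
print(f"P_C (reported orientation, small = credible signal): {p_c_reported.text}")
print(f"P_C (verbatim calibrated form, its complement):      {p_c_verbatim.text}")
print()
print("P_dAICc below 1/(repeats+1) means no permutation matched the observed fit.")
print("The reported-orientation P_C is the scale on which 'P_C < 0.5' flags a")
print("signal; the verbatim form of the calibration is its complement.")
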