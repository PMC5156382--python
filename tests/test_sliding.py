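"""Window enumeration, the exhaustive search and cross-validation."""

import numpy as np
import pandas as pd
import pytest

import climwindow as cw
from climwindow import models as m
from climwindow import sliding as sl


class TestEnumerateWindows:
    def test_counts(self):
        assert len(sl.enumerate_windows(0, 0)) == 1
        assert [(w.start, w.end) for w in sl.enumerate_windows(1, 0)] == [(1, 1), (1, 0), (0, 0)]
        m_ = 366
        assert len(sl.enumerate_windows(365, 0)) == m_ * (m_ + 1) // 2 == 67_161

    def test_count_formula_with_offset_min(self):
        for rmax, rmin in [(10, 0), (10, 4), (7, 7)]:
            m_ = rmax - rmin + 1
            assert len(sl.enumerate_windows(rmax, rmin)) == m_ * (m_ + 1) // 2

    def test_negative_offsets_rejected(self):
        with pytest.raises(ValueError):
            sl.enumerate_windows(5, -1)


def _brute_force(baseline_spec, series, biol, config):
    """Naive per-window refit straight from the raw series (oracle)."""
    adjusted = cw.apply_reference(biol.dates, config.window_type, config.refday)
    base = m.fit_baseline(baseline_spec)
    out = {}
    for w in sl.enumerate_windows(*config.range):
        agg = np.empty(len(biol))
        for r, d in enumerate(adjusted):
            i0 = np.searchsorted(series.dates, d - w.start)
            i1 = np.searchsorted(series.dates, d - w.end)
            chunk = series.values[i0:i1 + 1]
            agg[r] = {"mean": chunk.mean(), "sum": chunk.sum(), "max": chunk.max(),
                      "min": chunk.min()}[config.stat]
        fit = m.attach_climate(base, agg, func=config.func)
        out[(w.start, w.end)] = m.delta_aicc(fit, base)
    return out


class TestSlidingwin:
    def test_noiseless_signal_recovered_exactly(self):
        spec = cw.SyntheticSpec(n_records=25, true_window=(40, 20), beta=2.0,
                                noise_sd=0.0, seed=5)
        series, biol = cw.gen_dataset(spec)
        base = cw.BaselineSpec("response ~ 1", biol.to_frame())
        ms = cw.slidingwin(base, series, biol, cw.SlidingConfig(range=(50, 0)))
        assert (int(ms.best.window_start), int(ms.best.window_end)) == (40, 20)
        assert ms.best.beta == pytest.approx(2.0, abs=1e-8)

    @pytest.mark.parametrize("stat,func,family", [
        ("mean", "lin", "gaussian"),   # vectorized fast path
        ("sum", "lin", "gaussian"),
        ("max", "quad", "gaussian"),   # generic path
    ])
    def test_matches_brute_force_oracle(self, signal_dataset, stat, func, family):
        _, series, biol = signal_dataset
        base = cw.BaselineSpec("response ~ 1", biol.to_frame(), family=family)
        config = cw.SlidingConfig(range=(12, 0), stat=stat, func=func)
        ms = cw.slidingwin(base, series, biol, config)
        oracle = _brute_force(base, series, biol, config)
        assert len(ms) == len(oracle)
        for _, row in ms.frame.iterrows():
            assert row.delta_aicc == pytest.approx(
                oracle[(int(row.window_start), int(row.window_end))], abs=1e-8)
        best = min(oracle, key=oracle.get)
        assert (int(ms.best.window_start), int(ms.best.window_end)) == best

    def test_fast_path_agrees_with_generic_covariate_baseline(self, rng):
        spec = cw.SyntheticSpec(n_records=25, true_window=(15, 5), target_r2=0.5, seed=21)
        series, biol = cw.gen_dataset(spec)
        frame = biol.to_frame()
        frame["z"] = rng.normal(size=len(frame))
        base = cw.BaselineSpec("response ~ z", frame)
        config = cw.SlidingConfig(range=(10, 0))
        ms = cw.slidingwin(base, series, biol, config)
        fit0 = m.fit_baseline(base)
        for _, row in ms.frame.head(5).iterrows():
            agg = cw.aggregate_window(ms.matrix,
                                      cw.WindowSpec(int(row.window_start), int(row.window_end)),
                                      "mean")
            refit = m.attach_climate(fit0, agg)
            assert row.delta_aicc == pytest.approx(m.delta_aicc(refit, fit0), abs=1e-8)
            assert row.beta == pytest.approx(float(refit.params.iloc[-1]), abs=1e-8)
            assert row.se == pytest.approx(float(refit.bse.iloc[-1]), abs=1e-8)

    def test_modelset_sorted_and_sized(self, signal_dataset):
        _, series, biol = signal_dataset
        base = cw.BaselineSpec("response ~ 1", biol.to_frame())
        ms = cw.slidingwin(base, series, biol, cw.SlidingConfig(range=(14, 3)))
        m_ = 12
        assert len(ms) == m_ * (m_ + 1) // 2
        d = ms.frame.delta_aicc.to_numpy()
        assert np.all(np.diff(d[~np.isnan(d)]) >= -1e-12)

    def test_failed_windows_flagged_not_dropped(self, signal_dataset):
        _, series, biol = signal_dataset
        base = cw.BaselineSpec("response ~ 1", biol.to_frame())
        # log of a zero-mean gaussian climate is undefined for most windows
        config = cw.SlidingConfig(range=(6, 0), func="log")
        ms = cw.slidingwin(base, series, biol, config)
        assert len(ms) == 28
        assert (~ms.frame.ok).any()
        assert ms.frame.loc[~ms.frame.ok, "delta_aicc"].isna().all()

    def test_determinism(self, signal_dataset):
        _, series, biol = signal_dataset
        base = cw.BaselineSpec("response ~ 1", biol.to_frame())
        config = cw.SlidingConfig(range=(10, 0), k=5, seed=77)
        a = cw.slidingwin(base, series, biol, config)
        b = cw.slidingwin(base, series, biol, config)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_pure_noise_best_delta_matches_randomization_null(self):
        # under no signal, the observed best dAICc and the date-permuted best
        # dAICc are draws from the same distribution
        from scipy.stats import ks_2samp
        rng = np.random.default_rng(7)
        deltas = []
        config = cw.SlidingConfig(range=(12, 0))
        for _ in range(120):
            spec = cw.SyntheticSpec(n_records=15, true_window=(10, 5), target_r2=0.0,
                                    beta=0.0, seed=int(rng.integers(2 ** 31 - 1)))
            series, biol = cw.gen_dataset(spec)
            base = cw.BaselineSpec("response ~ 1", biol.to_frame())
            deltas.append(float(cw.slidingwin(base, series, biol, config).best.delta_aicc))
        spec = cw.SyntheticSpec(n_records=15, true_window=(10, 5), target_r2=0.0,
                                beta=0.0, seed=3)
        series, biol = cw.gen_dataset(spec)
        base = cw.BaselineSpec("response ~ 1", biol.to_frame())
        rand = cw.randwin(120, base, series, biol, window="sliding", config=config, seed=11)
        assert ks_2samp(deltas, rand.delta_aicc).pvalue > 0.01


class TestCoarserIntervals:
    def test_weekly_search_matches_blocked_matrix(self, signal_dataset):
        _, series, biol = signal_dataset
        base = cw.BaselineSpec("response ~ 1", biol.to_frame())
        config = cw.SlidingConfig(range=(4, 0), cinterval="week")
        ms = cw.slidingwin(base, series, biol, config)
        assert len(ms) == 15
        assert ms.matrix.cinterval == "week"
        # block 0 of the matrix is the mean of the 7 days ending on the record date
        daily = cw.build_climate_matrix(series, biol.dates, 34)
        assert np.allclose(ms.matrix.values[:, 0], daily.values[:, :7].mean(axis=1))
        fit0 = m.fit_baseline(base)
        agg = cw.aggregate_window(ms.matrix,
                                  cw.WindowSpec(int(ms.best.window_start),
                                                int(ms.best.window_end), cinterval="week"),
                                  "mean")
        assert float(ms.best.delta_aicc) == pytest.approx(
            m.delta_aicc(m.attach_climate(fit0, agg), fit0), abs=1e-8)


class TestWithinGroupCentring:
    def test_centred_search_reports_two_climate_terms(self, rng):
        spec = cw.SyntheticSpec(n_records=40, true_window=(15, 5), target_r2=0.5, seed=33)
        series, biol = cw.gen_dataset(spec)
        biol = cw.BiologicalTable(biol.dates, biol.response,
                                  group=np.repeat(["a", "b", "c", "d"], 10))
        base = cw.BaselineSpec("response ~ 1", biol.to_frame().drop(columns="group"))
        ms = cw.slidingwin(base, series, biol,
                           cw.SlidingConfig(range=(10, 0), centre=True))
        assert {"beta1", "beta2", "se1", "se2"} <= set(ms.frame.columns)
        # deviation + mean coefficients come from the same refit statsmodels does
        fit0 = m.fit_baseline(base)
        row = ms.frame.iloc[0]
        agg = cw.aggregate_window(ms.matrix,
                                  cw.WindowSpec(int(row.window_start), int(row.window_end)),
                                  "mean")
        refit = m.attach_climate(fit0, agg, centred=cw.centre_split(agg, biol.group))
        assert row.beta1 == pytest.approx(float(refit.params["climate_dev"]), abs=1e-8)
        assert row.beta2 == pytest.approx(float(refit.params["climate_mean"]), abs=1e-8)


class TestCrossValidation:
    def test_mse_aicc_formula(self):
        assert sl._mse_aicc(1.0, 2, 20) == pytest.approx(4.0 + 12 / 17)

    def test_leave_one_out_runs(self):
        spec = cw.SyntheticSpec(n_records=10, true_window=(8, 4), target_r2=0.5, seed=8)
        series, biol = cw.gen_dataset(spec)
        base = cw.BaselineSpec("response ~ 1", biol.to_frame())
        ms = cw.slidingwin(base, series, biol, cw.SlidingConfig(range=(6, 0), k=10, seed=1))
        assert np.isfinite(ms.best.delta_aicc)

    def test_k_exceeding_n_errors(self, signal_dataset):
        _, series, biol = signal_dataset
        base = cw.BaselineSpec("response ~ 1", biol.to_frame())
        with pytest.raises(ValueError, match="k"):
            cw.slidingwin(base, series, biol,
                          cw.SlidingConfig(range=(5, 0), k=len(biol) + 1, seed=0))

    def test_cv_requires_gaussian(self, signal_dataset):
        _, series, biol = signal_dataset
        frame = biol.to_frame()
        frame["response"] = (frame["response"] > frame["response"].median()).astype(float)
        base = cw.BaselineSpec("response ~ 1", frame, family="binomial")
        with pytest.raises(ValueError, match="gaussian"):
            cw.slidingwin(base, series, biol, cw.SlidingConfig(range=(5, 0), k=5, seed=0))

    def test_vectorized_cv_matches_scalar_crossvalidate(self, signal_dataset):
        _, series, biol = signal_dataset
        base = cw.BaselineSpec("response ~ 1", biol.to_frame())
        config = cw.SlidingConfig(range=(8, 0), k=5, seed=13)
        ms = cw.slidingwin(base, series, biol, config)
        fit0 = m.fit_baseline(base)
        folds = sl._fold_indices(len(biol), 5, 13)
        for _, row in ms.frame.head(4).iterrows():
            agg = cw.aggregate_window(ms.matrix,
                                      cw.WindowSpec(int(row.window_start), int(row.window_end)),
                                      "mean")
            d = sl.crossvalidate_window(fit0._y, fit0._X, agg[:, None], 5, 13, folds=folds)
            assert row.delta_aicc == pytest.approx(d, abs=1e-8)

    def test_cv_more_conservative_for_true_window(self):
        # for a fixed window with a real signal the out-of-sample dAICc is
        # typically less negative than the in-sample dAICc: cross-validation
        # removes the optimism of scoring a model on the data that fitted it
        rng = np.random.default_rng(17)
        diffs = []
        for _ in range(120):
            spec = cw.SyntheticSpec(n_records=47, true_window=(30, 10), target_r2=0.2,
                                    seed=int(rng.integers(2 ** 31 - 1)))
            series, biol = cw.gen_dataset(spec)
            base = cw.BaselineSpec("response ~ 1", biol.to_frame())
            fit0 = m.fit_baseline(base)
            mat = cw.build_climate_matrix(series, biol.dates, 40)
            agg = cw.aggregate_window(mat, cw.WindowSpec(30, 10), "mean")
            d_plain = m.delta_aicc(m.attach_climate(fit0, agg), fit0)
            d_cv = sl.crossvalidate_window(fit0._y, fit0._X, agg[:, None], 10,
                                           int(rng.integers(2 ** 31 - 1)))
            diffs.append(d_cv - d_plain)
        assert np.median(diffs) > 0
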