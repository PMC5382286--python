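import numpy as np
import pytest
import statsmodels.api as sm

from seizurewaves.coherence import CoherogramSet
from seizurewaves.recordings import AnalysisWindow, ElectrodeLayout, micro_layout
from seizurewaves.waves import (
    DelayEstimate,
    DelayMap,
    build_delay_map,
    coherence_vs_distance,
    direction_consistency,
    direction_difference,
    fit_plane,
    group_delay,
    group_test,
    summarize_intervals,
)

WINDOW = AnalysisWindow(start=0.0, normalized_time=0.5)


def synthetic_coherogram(delay_s=0.02, sig=(1.0, 13.0), df=0.1, fmax=25.0):
    """Coherogram with phase = 2*pi*f*delay and a significant band."""
    f = np.arange(0.0, fmax + df / 2, df)
    phase = 2 * np.pi * f * delay_s
    mask = (f >= sig[0]) & (f <= sig[1])
    return CoherogramSet(
        pair=("a", "b"),
        magnitude=np.ones((1, len(f))),
        phase=((phase + np.pi) % (2 * np.pi) - np.pi)[None, :],
        sig_mask=mask[None, :],
        freq_axis=f,
        windows=[WINDOW],
    )


class TestGroupDelay:
    def test_linear_phase_recovers_delay(self):
        est = group_delay(synthetic_coherogram(0.02), 0)
        assert est.defined
        assert est.value == pytest.approx(0.020, rel=1e-6)

    def test_phase_wrap_handled(self):
        # 60 ms delay wraps the raw phase several times across 1-13 Hz
        est = group_delay(synthetic_coherogram(0.06), 0)
        assert est.defined
        assert est.value == pytest.approx(0.06, rel=1e-6)

    def test_negative_delay(self):
        est = group_delay(synthetic_coherogram(-0.015), 0)
        assert est.value == pytest.approx(-0.015, rel=1e-6)

    def test_no_wide_band_undefined(self):
        cg = synthetic_coherogram(0.02, sig=(5.0, 7.0))  # only 2 Hz wide
        est = group_delay(cg, 0, min_band=3.0)
        assert not est.defined and np.isnan(est.value)

    def test_constant_phase_not_significant(self):
        cg = synthetic_coherogram(0.0)
        rng = np.random.default_rng(0)
        cg.phase = 0.3 + 0.01 * rng.standard_normal(cg.phase.shape)
        est = group_delay(cg, 0)
        assert not est.defined

    def test_longest_run_chosen_ties_to_lowest(self):
        f = np.arange(0.0, 25.05, 0.1)
        mask = np.zeros(len(f), bool)
        mask[(f >= 1) & (f <= 5)] = True     # 4 Hz run
        mask[(f >= 8) & (f <= 12)] = True    # 4 Hz run (tie)
        cg = synthetic_coherogram(0.01)
        cg.sig_mask = mask[None, :]
        est = group_delay(cg, 0)
        assert est.band_used[0] == pytest.approx(1.0)

    def test_broadband_shift_recovered(self):
        # delayed broadband pair through the full coherence pipeline
        from seizurewaves.coherence import CoherenceEngine
        from seizurewaves.recordings import make_windows
        from conftest import make_recording

        rng = np.random.default_rng(1)
        n = int(40.0 * 500)
        x = rng.standard_normal(n + 20)
        a, b = x[20:][:n], x[:-20][:n]  # b lags a by 40 ms
        rec = make_recording(np.column_stack([a, b]), onset=10.0)
        wins = make_windows(rec, pre_duration=10.0)
        eng = CoherenceEngine(rec, wins)
        fwd = [group_delay(eng.coherogram("c0", "c1"), w)
               for w in range(len(wins))]
        vals = [e.value for e in fwd if e.defined]
        assert len(vals) >= 0.9 * len(wins)
        assert np.median(vals) == pytest.approx(0.040, rel=0.10)
        # antisymmetry: swapping the channels negates the delay
        rev = group_delay(eng.coherogram("c1", "c0"), 0)
        assert rev.value == pytest.approx(-fwd[0].value, rel=1e-6)


class TestDelayMap:
    def test_micro_map_includes_reference_at_zero(self):
        pairs = {("r", f"e{i}"): DelayEstimate(0.005, True) for i in range(4)}
        dmap = build_delay_map(pairs, WINDOW, "micro", "r")
        assert dmap.delays["r"].value == 0.0
        assert all(dmap.delays[f"e{i}"].value == 0.005 for i in range(4))

    def test_macro_mean_over_defined(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0.0, 0.010, 96)
        pairs = {(f"m{i}", "M0"): DelayEstimate(v, True)
                 for i, v in enumerate(vals)}
        pairs[("m96", "M1")] = DelayEstimate(np.nan, False)
        dmap = build_delay_map(pairs, WINDOW, "macro", "MEA")
        assert dmap.delays["M0"].value == pytest.approx(vals.mean())
        assert not dmap.delays["M1"].defined

    def test_macro_mean_skips_undefined_constituents(self):
        pairs = {
            ("m0", "M0"): DelayEstimate(0.004, True),
            ("m1", "M0"): DelayEstimate(np.nan, False),
            ("m2", "M0"): DelayEstimate(0.008, True),
        }
        dmap = build_delay_map(pairs, WINDOW, "macro", "MEA")
        assert dmap.delays["M0"].value == pytest.approx(0.006)


def _map_from_values(layout, values):
    delays = {
        i: DelayEstimate(v, np.isfinite(v))
        for i, v in zip(layout.ids, values)
    }
    for i, v in zip(layout.ids, values):
        if not np.isfinite(v):
            delays[i] = DelayEstimate(np.nan, False)
    return DelayMap(window=WINDOW, reference=layout.ids[0], delays=delays)


class TestPlaneFit:
    def setup_method(self):
        self.layout = micro_layout(n_side=5, pitch_mm=0.4)

    def test_pure_x_gradient(self):
        vals = 0.001 * self.layout.positions[:, 0]
        fit = fit_plane(_map_from_values(self.layout, vals), self.layout)
        assert fit.valid
        assert fit.speed == pytest.approx(1000.0, rel=1e-6)
        assert fit.source_direction == pytest.approx(0.0, abs=1e-9)

    def test_diagonal_gradient(self):
        vals = 0.0005 * self.layout.positions.sum(axis=1)
        fit = fit_plane(_map_from_values(self.layout, vals), self.layout)
        assert fit.speed == pytest.approx(1414.2, rel=1e-3)
        assert fit.source_direction == pytest.approx(np.pi / 4, abs=1e-9)

    def test_constant_delays_invalid(self):
        rng = np.random.default_rng(3)
        vals = 0.005 + 1e-6 * rng.standard_normal(len(self.layout))
        fit = fit_plane(_map_from_values(self.layout, vals), self.layout)
        assert not fit.valid
        assert np.isnan(fit.speed)

    def test_under_half_defined_invalid(self):
        lay = micro_layout(n_side=10, pitch_mm=0.4)
        vals = 0.001 * lay.positions[:, 0]
        vals[40:] = np.nan  # 40 of 100 defined
        fit = fit_plane(_map_from_values(lay, vals), lay)
        assert fit.n_defined == 40
        assert not fit.valid

    def test_too_few_points_invalid(self):
        lay = micro_layout(n_side=3)
        vals = np.full(9, np.nan)
        vals[0], vals[1] = 0.0, 0.001
        fit = fit_plane(_map_from_values(lay, vals), lay)
        assert not fit.valid

    def test_matches_ols_oracle_on_noisy_small_instance(self):
        # <= 9 electrodes, robust weights disabled: must equal exhaustive OLS
        lay = micro_layout(n_side=3, pitch_mm=0.4)
        rng = np.random.default_rng(4)
        vals = (0.002 * lay.positions[:, 0]
                - 0.001 * lay.positions[:, 1]
                + 0.0005 * rng.standard_normal(9))
        fit = fit_plane(_map_from_values(lay, vals), lay, robust=False)
        X = sm.add_constant(lay.positions)
        oracle = sm.OLS(vals, X).fit()
        assert fit.b0 == pytest.approx(oracle.params[0], rel=1e-8, abs=1e-12)
        assert fit.b1 == pytest.approx(oracle.params[1], rel=1e-8)
        assert fit.b2 == pytest.approx(oracle.params[2], rel=1e-8)
        assert fit.fit_p == pytest.approx(oracle.f_pvalue, rel=1e-6)

    def test_robust_downweights_outlier(self):
        lay = micro_layout(n_side=5, pitch_mm=0.4)
        vals = 0.001 * lay.positions[:, 0]
        vals = vals + 1e-5 * np.sin(np.arange(25.0))  # small non-outlier noise
        vals[7] += 0.05  # gross outlier
        robust = fit_plane(_map_from_values(lay, vals), lay, robust=True)
        plain = fit_plane(_map_from_values(lay, vals), lay, robust=False)
        assert abs(robust.b1 - 0.001) < abs(plain.b1 - 0.001)


class TestCircularStats:
    def test_identical_angles_plv_one(self):
        assert direction_consistency(np.full(17, 1.23)) == pytest.approx(1.0)

    def test_antipodal_pair_cancels(self):
        assert direction_consistency(np.array([0.0, np.pi])) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_uniform_angles_near_zero(self):
        rng = np.random.default_rng(5)
        plv = direction_consistency(rng.uniform(-np.pi, np.pi, 1000))
        # E[plv] ~ sqrt(pi)/(2*sqrt(N)) ~ 0.028
        assert plv < 0.1

    def test_rotation_invariance(self):
        rng = np.random.default_rng(6)
        ang = rng.uniform(-np.pi, np.pi, 50)
        a = direction_consistency(ang)
        b = direction_consistency(ang + 2.0)
        assert a == pytest.approx(b, rel=1e-12)

    def test_empty_warns_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(direction_consistency(np.array([])))

    @pytest.mark.parametrize("a,b,expected", [
        (0.1, 0.1, 0.0),
        (np.pi / 2, 0.0, np.pi / 2),
        (-3.0, 3.0, 2 * np.pi - 6.0),
        (3.0, -3.0, -(2 * np.pi - 6.0)),
    ])
    def test_direction_difference_wraps(self, a, b, expected):
        assert direction_difference(a, b) == pytest.approx(expected)

    def test_difference_range(self):
        rng = np.random.default_rng(7)
        for a, b in rng.uniform(-np.pi, np.pi, (200, 2)):
            d = direction_difference(a, b)
            assert -np.pi < d <= np.pi


class TestDistanceRegression:
    def test_exact_line(self):
        d = np.linspace(5, 150, 30)
        c = 0.8 - 0.002 * d
        reg = coherence_vs_distance(d, c)
        assert reg.slope == pytest.approx(-0.002, rel=1e-9)
        assert reg.left_intercept == pytest.approx(0.79, rel=1e-9)
        assert reg.right_intercept == pytest.approx(0.5, rel=1e-9)

    def test_constant_coherence(self):
        d = np.linspace(5, 150, 30)
        reg = coherence_vs_distance(d, np.full(30, 0.3))
        assert reg.slope == pytest.approx(0.0, abs=1e-12)
        assert reg.left_intercept == pytest.approx(0.3)
        assert reg.right_intercept == pytest.approx(0.3)

    def test_intercept_identity(self):
        rng = np.random.default_rng(8)
        d = rng.uniform(5, 150, 100)
        c = 0.7 - 0.001 * d + 0.05 * rng.standard_normal(100)
        reg = coherence_vs_distance(d, c)
        assert reg.right_intercept == pytest.approx(
            reg.left_intercept + reg.slope * (reg.d_max - reg.d_min)
        )

    def test_noisy_slope_within_standard_error(self):
        rng = np.random.default_rng(9)
        d = rng.uniform(5, 150, 200)
        c = 0.7 - 0.001 * d + 0.02 * rng.standard_normal(200)
        reg = coherence_vs_distance(d, c)
        X = sm.add_constant(d)
        res = sm.OLS(c, X).fit()
        assert abs(reg.slope - (-0.001)) < 3 * res.bse[1]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            coherence_vs_distance(np.array([1.0, 2.0]), np.array([0.1, 0.2]))
        with pytest.raises(ValueError):
            coherence_vs_distance(np.full(5, 3.0), np.linspace(0, 1, 5))


def _fit(nt, direction=np.pi / 4, speed=300.0, valid=True):
    from seizurewaves.waves import PlaneWaveFit
    return PlaneWaveFit(
        valid=valid, speed=speed, source_direction=direction,
        n_defined=9, n_total=9,
        window=AnalysisWindow(start=0.0, normalized_time=nt),
    )


class TestIntervalSummaries:
    def test_shared_direction_full_consistency(self):
        fits = [_fit(nt) for nt in np.linspace(-0.4, 1.0, 30)]
        summ = summarize_intervals(fits, n_boot=100, rng=0)
        for s in summ.values():
            assert s.direction_consistency == pytest.approx(1.0)
            assert not s.empty

    def test_interval_with_no_valid_fits_is_empty(self):
        fits = [_fit(0.9)]  # late only
        summ = summarize_intervals(fits, n_boot=50, rng=0)
        assert summ["Pre"].empty and summ["Pre"].n_waves == 0
        assert not summ["Late"].empty

    def test_invalid_fits_excluded(self):
        fits = [_fit(0.6), _fit(0.6, valid=False)]
        summ = summarize_intervals(fits, n_boot=50, rng=0)
        assert summ["Late"].n_waves == 1

    def test_bootstrap_ci_covers_truth(self):
        # synthetic speeds with known mean: the 95% CI should cover the
        # truth in roughly 95% of repetitions
        rng = np.random.default_rng(10)
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            speeds = 300.0 + 50.0 * rng.standard_normal(40)
            fits = [
                _fit(0.8, speed=s, direction=0.5) for s in speeds
            ]
            summ = summarize_intervals(fits, n_boot=200, rng=rep)["Late"]
            lo, hi = summ.ci_speed
            hits += lo <= 300.0 <= hi
        assert 85 <= hits <= 100

    def test_mean_speed_matches_direct_average(self):
        speeds = [100.0, 200.0, 300.0]
        fits = [_fit(0.8, speed=s) for s in speeds]
        summ = summarize_intervals(fits, n_boot=50, rng=0)
        assert summ["Late"].mean_speed == pytest.approx(200.0)


class TestGroupTest:
    def test_identical_groups_p_one(self):
        a = np.array([1.0, 2.0, 3.0])
        assert group_test(a, a) == pytest.approx(1.0)

    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(11)
        a = rng.standard_normal(10)
        b = 5.0 + rng.standard_normal(10)
        assert group_test(a, b) < 1e-6

    def test_null_calibration_uniform_p(self):
        # 7 vs 21 with no true difference: p should be ~Uniform(0,1)
        rng = np.random.default_rng(12)
        ps = [
            group_test(rng.standard_normal(7), rng.standard_normal(21))
            for _ in range(400)
        ]
        from scipy import stats
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_variance(self):
        with pytest.warns(UserWarning):
            assert np.isnan(group_test(np.zeros(3), np.ones(3)))

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            group_test(np.array([1.0]), np.array([1.0, 2.0]))
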