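import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcaredox import (
    KineticParams,
    ObservationParams,
    apply_observation_model,
    calibrate_fluorescence,
    condition,
    exclude_quench_window,
    find_first_valid,
    fit_all,
    fit_initial_rate,
    scan_window_r2,
    simulate_assay,
)
from pcaredox.errors import InsufficientDataError, NoValidDataError
from pcaredox.rates import INDETERMINATE, OXIDATION, REDUCTION, InitialRateModel
from pcaredox.series import ConcentrationSeries

from conftest import make_series, ols_normal_equations


class TestCalibration:
    def test_blank_subtraction_gives_zero(self):
        t = np.arange(5.0)
        s = calibrate_fluorescence(np.full(5, 120.0), t, gain=3.0, blank=120.0)
        np.testing.assert_array_equal(s.values, 0.0)
        assert s.valid.all()

    def test_round_trip_with_noise_free_observation(self):
        t = np.linspace(0, 10, 41)
        true = np.clip(200.0 - 25.0 * t, 0, None)
        raw = apply_observation_model(true, t, gain=80.0, blank=55.0,
                                      noise_sd=0.0)
        s = calibrate_fluorescence(raw, t, gain=80.0, blank=55.0)
        np.testing.assert_allclose(s.values, true, atol=1e-10)

    def test_below_blank_clipped_and_flagged(self):
        t = np.arange(3.0)
        s = calibrate_fluorescence(np.array([90.0, 110.0, 100.0]), t,
                                   gain=2.0, blank=100.0)
        assert s.values[0] == 0.0
        assert not s.valid[0]
        assert s.valid[1]

    def test_nonpositive_gain_rejected(self):
        with pytest.raises(ValueError, match="gain"):
            calibrate_fluorescence(np.zeros(3), np.arange(3.0), gain=0.0,
                                   blank=0.0)


class TestFirstValid:
    def test_series_above_threshold_at_start(self):
        s = make_series([0, 1, 2], [10, 9, 8])
        assert find_first_valid(s, 5.0) == 0.0

    def test_quench_flagged_points_skipped(self):
        t = np.arange(0, 3, 0.25)
        s = make_series(t, np.full(t.size, 50.0),
                        condition=condition("abiotic", "nitrite", "reduced"))
        s = exclude_quench_window(s)
        assert find_first_valid(s, 5.0) == 1.5

    def test_all_below_threshold_signals_no_valid_data(self):
        s = make_series([0, 1, 2], [0.0, 0.0, 0.0])
        with pytest.raises(NoValidDataError):
            find_first_valid(s, 5.0)


class TestQuenchExclusion:
    def test_quarter_hour_grid_flags_first_six_points(self):
        # grid points strictly below 1.5 h: 0, .25, .5, .75, 1.0, 1.25
        t = np.arange(0, 24.0, 0.25)
        s = make_series(t, np.full(t.size, 50.0))
        out = exclude_quench_window(
            s, condition("abiotic", "nitrite", "reduced")
        )
        assert (~out.valid).sum() == 6
        assert out.valid[t >= 1.5].all()

    def test_nitrate_condition_is_identity(self):
        t = np.arange(0, 5.0, 0.25)
        s = make_series(t, np.full(t.size, 50.0))
        out = exclude_quench_window(
            s, condition("C. portucalensis MBL", "nitrate", "reduced")
        )
        assert out.valid.all()
        assert out is s

    def test_no_early_points_is_identity(self):
        s = make_series([2.0, 3.0, 4.0], [1, 2, 3])
        out = exclude_quench_window(
            s, condition("abiotic", "nitrite", "reduced")
        )
        assert out is s


class TestInitialRateFit:
    def test_exact_line_recovered_exactly(self):
        t = np.arange(0, 5.01, 0.25)
        s = make_series(t, 200.0 - 25.23 * t)
        est = fit_initial_rate(s, 5.0)
        assert est.rate == pytest.approx(-25.23, abs=1e-12)
        assert est.se == pytest.approx(0.0, abs=1e-10)
        assert est.r2 == pytest.approx(1.0, abs=1e-12)
        assert est.interpretation == OXIDATION
        assert est.ci95_half == pytest.approx(1.96 * est.se)

    def test_constant_series_indeterminate(self):
        t = np.arange(0, 5.01, 0.5)
        est = fit_initial_rate(make_series(t, np.full(t.size, 80.0)), 5.0)
        assert est.rate == 0.0
        assert est.interpretation == INDETERMINATE

    def test_window_anchored_at_first_valid_measurement(self):
        """The 5-h window starts at first detection, not at assay start."""
        t = np.arange(0, 12.01, 0.5)
        values = np.where(t < 2.0, 0.0, (t - 2.0) * 10.0)
        est = fit_initial_rate(make_series(t, values), 5.0,
                               detection_threshold=5.0)
        assert est.window[0] == 2.5  # first point >= 5 uM
        assert est.window[1] == 7.5
        assert est.rate == pytest.approx(10.0)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        n=st.integers(3, 200),
        slope=st.floats(-30, 30),
        noise=st.floats(0.1, 10),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_matches_normal_equations_oracle(self, n, slope, noise, seed):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 5, n))
        t += np.arange(n) * 1e-6  # ensure strict monotonicity
        y = 100.0 + slope * t + rng.normal(0, noise, n)
        y -= y.min() - 1.0  # keep concentrations positive
        est = fit_initial_rate(make_series(t, y), window_length=10.0)
        o_slope, o_se, o_r2 = ols_normal_equations(t, y)
        assert est.rate == pytest.approx(o_slope, rel=1e-10)
        assert est.se == pytest.approx(o_se, rel=1e-10)
        assert est.r2 == pytest.approx(o_r2, rel=1e-10)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_sign_flip_swaps_interpretation(self, seed):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 5, 21)
        y = 100.0 + 5.0 * t + rng.normal(0, 1.0, t.size)
        up = fit_initial_rate(make_series(t, y), 5.0)
        down = fit_initial_rate(make_series(t, 300.0 - y), 5.0)
        assert down.rate == pytest.approx(-up.rate, rel=1e-12)
        assert {up.interpretation, down.interpretation} == {
            OXIDATION, REDUCTION,
        }

    def test_insufficient_points_rejected(self):
        s = make_series([0.0, 0.3, 6.0, 7.0], [10, 11, 12, 13])
        with pytest.raises(InsufficientDataError):
            fit_initial_rate(s, window_length=1.0)

    def test_conf_int_widths(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 5, 20)
        y = 100 + 3 * t + rng.normal(0, 2, 20)
        est = InitialRateModel(make_series(t, y), 5.0).fit()
        lo_n, hi_n = est.conf_int(use_t=False)
        lo_t, hi_t = est.conf_int(use_t=True)
        assert hi_t - lo_t > hi_n - lo_n  # t interval wider at small n
        assert (lo_n, hi_n) == pytest.approx(
            (est.rate - est.ci95_half, est.rate + est.ci95_half), rel=1e-6
        )


class TestWindowScan:
    def test_perfect_line_r2_one_everywhere(self):
        t = np.arange(0, 15.01, 0.25)
        scan = scan_window_r2(make_series(t, 500.0 - 3.0 * t), 15.0, 1.0)
        np.testing.assert_allclose(scan.r2_values, 1.0)
        assert scan.chosen_window == 5.0

    def test_r2_declines_past_exhaustion_changepoint(self):
        """Once the window crosses substrate exhaustion the line misfits."""
        a = simulate_assay(
            condition("C. portucalensis MBL", "nitrate", "reduced"),
            KineticParams(k_biox=25.0, k_abio=0.0),
            seed=0,
        )
        scan = scan_window_r2(a.true_series["PCA_red"], 20.0, 1.0)
        # exhaustion at 200/25 = 8 h; r2 non-increasing from there on
        past = scan.r2_values[scan.window_lengths >= 8.0]
        assert np.all(np.diff(past) <= 1e-9)
        assert past[-1] < 0.9 < scan.r2_values[0]

    def test_step_validation(self):
        s = make_series([0, 1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            scan_window_r2(s, max_length=1.0, step=2.0)


def _plate_frames(specs, seed=0, obs=None):
    import pcaredox.io as pio
    from pcaredox.sim import params_for_strain

    obs = obs or ObservationParams()
    assays = [
        simulate_assay(c, params_for_strain(c.strain), seed=seed, obs=obs)
        for c in specs
    ]
    import tempfile
    from pathlib import Path

    with tempfile.TemporaryDirectory() as d:
        pio.write_plate_csvs(assays, Path(d) / "p.csv", Path(d) / "l.csv")
        return pd.read_csv(Path(d) / "p.csv"), pd.read_csv(Path(d) / "l.csv")


class TestFitAll:
    def test_full_design_yields_one_row_per_condition(self):
        from pcaredox.conditions import default_condition_matrix

        plate, layout = _plate_frames(default_condition_matrix())
        rates = fit_all(plate, layout, gain=100.0, blank=100.0)
        assert len(rates) == 36  # 6 strains x 3 TEAs x 2 PCA states
        assert rates["n_replicates"].eq(3).all()

    def test_abiotic_no_tea_indeterminate(self):
        from pcaredox.conditions import make_condition_matrix

        specs = make_condition_matrix(["abiotic"], ["none"], ["reduced"], 3)
        noise_free = ObservationParams(noise_sd_uM=0.0, od_noise_sd=0.0,
                                       ic_noise_sd=0.0)
        plate, layout = _plate_frames(specs, seed=1, obs=noise_free)
        rates = fit_all(plate, layout, gain=100.0, blank=100.0)
        assert rates["interpretation"].iloc[0] == INDETERMINATE
        assert rates["rate_uM_per_h"].iloc[0] == 0.0

    def test_single_replicate_equals_replicate_estimate(self):
        from pcaredox.conditions import make_condition_matrix

        specs = make_condition_matrix(
            ["C. portucalensis MBL"], ["nitrate"], ["reduced"], 1
        )
        plate, layout = _plate_frames(specs, seed=2)
        rates = fit_all(plate, layout, gain=100.0, blank=100.0)
        row = rates.iloc[0]
        assert float(row["replicate_rates"]) == pytest.approx(
            row["rate_uM_per_h"], abs=0.005  # table rounds to 2 decimals
        )

    def test_wells_missing_from_layout_rejected(self):
        plate = pd.DataFrame(
            {"well": ["W1", "W2"], "time_h": [0.0, 0.0],
             "fluorescence": [1.0, 1.0], "od600": [0.1, 0.1]}
        )
        layout = pd.DataFrame(
            {"well": ["W1"], "strain": ["abiotic"], "tea": ["none"],
             "pca_state": ["reduced"], "replicate": [1]}
        )
        with pytest.raises(ValueError, match="W2"):
            fit_all(plate, layout, gain=1.0, blank=0.0)

    def test_excluded_quench_points_cannot_influence_fit(self):
        """Perturbing pre-1.5-h readings of nitrite wells changes nothing."""
        from pcaredox.conditions import make_condition_matrix

        specs = make_condition_matrix(["abiotic"], ["nitrite"], ["reduced"], 3)
        plate, layout = _plate_frames(specs, seed=3)
        baseline = fit_all(plate, layout, gain=100.0, blank=100.0)
        perturbed = plate.copy()
        early = perturbed["time_h"] < 1.5
        perturbed.loc[early, "fluorescence"] += 1e4
        after = fit_all(perturbed, layout, gain=100.0, blank=100.0)
        pd.testing.assert_frame_equal(baseline, after)
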