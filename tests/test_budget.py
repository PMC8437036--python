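import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcaredox import (
    KineticParams,
    RateEstimate,
    check_stoichiometry,
    compare_rates,
    condition,
    electron_budget,
    estimate_initial_n_rate,
    simulate_assay,
    thermodynamic_feasibility,
)
from pcaredox.errors import InsufficientDataError

from conftest import make_series


def _est(value, ci, species="no3"):
    return RateEstimate.from_value_ci(value, ci, species=species)


class TestInitialNitrogenRate:
    def test_flat_series_zero_rate(self):
        s = make_series([0.0, 4.0, 8.0], [10000.0, 10000.0, 10000.0],
                        species="no3")
        assert estimate_initial_n_rate(s).rate == 0.0

    def test_two_point_consumption_slope(self):
        # oracle: (10000 - 8952) / 8 = 131 uM/h consumption
        s = make_series([0.0, 8.0], [10000.0, 8952.0], species="no3")
        est = estimate_initial_n_rate(s)
        assert est.rate == pytest.approx(131.0)
        assert "consumption" in est.note

    def test_production_sign_for_nitrite(self):
        s = make_series([0.0, 8.0], [0.0, 1048.0], species="no2")
        est = estimate_initial_n_rate(s)
        assert est.rate == pytest.approx(131.0)
        assert "production" in est.note

    def test_replicate_dispersion_propagates_to_se(self):
        # oracle: sem_i = sd_i/sqrt(3); se = sqrt(sem0^2+sem1^2)/dt
        reps = [
            make_series([0.0, 4.0], [10000.0 + d0, 9500.0 + d1], species="no3")
            for d0, d1 in [(-90.0, 60.0), (0.0, -30.0), (90.0, -30.0)]
        ]
        est = estimate_initial_n_rate(reps)
        sem0 = np.std([-90, 0, 90], ddof=1) / math.sqrt(3)
        sem1 = np.std([60, -30, -30], ddof=1) / math.sqrt(3)
        assert est.se == pytest.approx(math.hypot(sem0, sem1) / 4.0)
        assert est.ci95_half == pytest.approx(1.96 * est.se)

    def test_two_point_mode_equals_window_mode_on_two_timepoints(self):
        reps = [
            make_series([0.0, 4.0], [10000.0 - 50 * i, 9000.0 + 40 * i],
                        species="no3")
            for i in range(3)
        ]
        two = estimate_initial_n_rate(reps, mode="first_two_points")
        win = estimate_initial_n_rate(reps, mode="window", window_h=4.0)
        assert two.rate == pytest.approx(win.rate)

    def test_too_few_points_rejected(self):
        s = make_series([0.0], [10000.0], species="no3")
        with pytest.raises(InsufficientDataError):
            estimate_initial_n_rate(s)


class TestStoichiometry:
    def test_matched_conversion_balanced(self):
        no3 = make_series([0, 8], [10000.0, 9500.0], species="no3")
        no2 = make_series([0, 8], [0.0, 500.0], species="no2")
        rep = check_stoichiometry(no3, no2, tol=50.0)
        assert rep.balanced
        assert rep.imbalance == 0.0

    def test_unbalanced_conversion_flagged(self):
        no3 = make_series([0, 8], [10000.0, 9500.0], species="no3")
        no2 = make_series([0, 8], [0.0, 300.0], species="no2")
        rep = check_stoichiometry(no3, no2, tol=50.0)
        assert not rep.balanced
        assert rep.imbalance == pytest.approx(-200.0)

    def test_mismatched_grids_rejected(self):
        no3 = make_series([0, 8], [10000.0, 9500.0], species="no3")
        no2 = make_series([0, 4], [0.0, 300.0], species="no2")
        with pytest.raises(ValueError, match="time grid"):
            check_stoichiometry(no3, no2)

    @pytest.mark.parametrize("pca_start", ["reduced", "oxidized", "none"])
    def test_simulator_truth_is_stoichiometric(self, pca_start):
        a = simulate_assay(
            condition("C. portucalensis MBL", "nitrate", pca_start), seed=0
        )
        rep = check_stoichiometry(a.true_series["no3"], a.true_series["no2"],
                                  tol=1e-5)
        assert rep.balanced


class TestCompareRates:
    def test_nitrate_excess_example(self):
        cmp = compare_rates(_est(131, 49), _est(35, 35))
        assert cmp.diff == pytest.approx(96.0)
        assert cmp.ci95_half_combined == pytest.approx(60.0, abs=0.5)
        assert cmp.lower_bound == pytest.approx(36.0, abs=0.5)
        assert cmp.excludes_zero

    def test_nitrite_excess_example(self):
        cmp = compare_rates(_est(147, 44), _est(58, 2))
        assert cmp.diff == pytest.approx(89.0)
        assert cmp.ci95_half_combined == pytest.approx(44.0, abs=0.1)

    def test_identical_rates_do_not_exclude_zero(self):
        cmp = compare_rates(_est(50, 10), _est(50, 10))
        assert cmp.diff == 0.0
        assert not cmp.excludes_zero

    def test_geometric_mean_variant(self):
        # literal geometric-mean interval: sqrt(49*35) ~ 41.4, narrower than
        # quadrature and unable to reproduce the +/-60 contrast width
        cmp = compare_rates(_est(131, 49), _est(35, 35),
                            method="geometric_mean")
        assert cmp.ci95_half_combined == pytest.approx(math.sqrt(49 * 35))

    def test_species_mismatch_rejected(self):
        with pytest.raises(ValueError, match="species"):
            compare_rates(_est(131, 49, "no3"), _est(147, 44, "no2"))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        ra=st.floats(-200, 200), rb=st.floats(-200, 200),
        ha=st.floats(0, 100), hb=st.floats(0, 100),
    )
    def test_antisymmetry_and_width_bounds(self, ra, rb, ha, hb):
        a, b = _est(ra, ha), _est(rb, hb)
        fwd = compare_rates(a, b)
        rev = compare_rates(b, a)
        assert fwd.diff == pytest.approx(-rev.diff)
        assert fwd.lower_bound == pytest.approx(-rev.upper_bound)
        assert max(ha, hb) <= fwd.ci95_half_combined + 1e-12
        assert fwd.ci95_half_combined <= ha + hb + 1e-12


class TestElectronBudget:
    def test_two_electron_cap(self):
        b = electron_budget(_est(-25, 0.84 * 1.96), _est(131, 49),
                            _est(35, 35))
        assert b.stoich_cap == pytest.approx(25.0)

    def test_measured_scale_excess_infers_cycling(self):
        b = electron_budget(_est(-25, 1.6), _est(131, 49), _est(35, 35))
        assert b.observed_excess.lower_bound > b.stoich_cap
        assert b.cycling_inferred

    def test_zero_pca_rate_degenerate_cap(self):
        b = electron_budget(_est(0, 0), _est(60, 20), _est(10, 20))
        assert b.stoich_cap == 0.0
        assert b.cycling_inferred == b.observed_excess.excludes_zero

    def test_reduction_rate_rejected(self):
        with pytest.raises(ValueError, match="reduction"):
            electron_budget(_est(8.0, 1.0), _est(131, 49), _est(35, 35))

    def test_unequal_electron_counts_scale_cap(self):
        b = electron_budget(_est(-25, 0), _est(131, 49), _est(35, 35),
                            e_pca=2, e_no3=1)
        assert b.stoich_cap == pytest.approx(50.0)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        ref=st.floats(0, 100), bump=st.floats(0, 100),
    )
    def test_raising_reference_never_creates_cycling(self, ref, bump):
        """Inference is monotone: a faster reference only weakens the case."""
        pca = _est(-25, 2)
        with_pca = _est(131, 49)
        low = electron_budget(pca, with_pca, _est(ref, 35))
        high = electron_budget(pca, with_pca, _est(ref + bump, 35))
        assert not (high.cycling_inferred and not low.cycling_inferred)


class TestThermodynamics:
    @pytest.mark.parametrize(
        "donor, acceptor, delta",
        [("PCA", "NO3-/NO2-", 549.0), ("PCA", "NO2-/NO", 466.0)],
    )
    def test_pca_donation_is_downhill(self, donor, acceptor, delta):
        d, feasible = thermodynamic_feasibility(donor, acceptor)
        assert d == pytest.approx(delta)
        assert feasible

    def test_couple_against_itself_not_feasible(self):
        d, feasible = thermodynamic_feasibility("PCA", "PCA")
        assert d == 0.0
        assert not feasible

    def test_unknown_couple_rejected(self):
        with pytest.raises(KeyError):
            thermodynamic_feasibility("PCA", "O2/H2O")
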