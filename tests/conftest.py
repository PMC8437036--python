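import numpy as np
import pytest

from pcaredox import (
    ObservationParams,
    calibrate_fluorescence,
    condition,
    exclude_quench_window,
    fit_initial_rate,
    mean_of_replicates,
    params_for_strain,
    simulate_assay,
)
from pcaredox.rates import DEFAULT_DETECTION_THRESHOLD_UM
from pcaredox.series import ConcentrationSeries


@pytest.fixture
def cport_nitrate():
    return condition("C. portucalensis MBL", "nitrate", "reduced")


@pytest.fixture
def abiotic_nitrite():
    return condition("abiotic", "nitrite", "reduced")


def make_series(times, values, **kw):
    return ConcentrationSeries(np.asarray(times, float),
                               np.asarray(values, float), **kw)


def ols_normal_equations(t, y):
    """Independent closed-form OLS oracle: slope, slope SE, R^2.

    Straight normal equations with textbook variance formulas; shares no
    code with the fitting path under test.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    n = t.size
    tbar, ybar = t.mean(), y.mean()
    sxx = np.sum((t - tbar) ** 2)
    sxy = np.sum((t - tbar) * (y - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * tbar
    resid = y - (intercept + slope * t)
    ss_res = np.sum(resid**2)
    ss_tot = np.sum((y - ybar) ** 2)
    sigma2 = ss_res / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    r2 = 1.0 - ss_res / ss_tot
    return slope, se, r2


def fit_observed_condition(cond, seed, params=None, replicates=3,
                           window_h=5.0,
                           threshold=DEFAULT_DETECTION_THRESHOLD_UM,
                           obs=None):
    """Simulate replicates of one condition and fit the replicate-mean trace.

    The full observation path: fluorescence with noise -> calibration ->
    quench exclusion -> mean of replicates -> windowed OLS.
    """
    obs = obs or ObservationParams()
    params = params or params_for_strain(cond.strain)
    reps = []
    for r in range(1, replicates + 1):
        c = condition(cond.strain, cond.tea, cond.pca_start, replicate=r,
                      pca_total=cond.pca_total, tea_conc=cond.tea_conc)
        assay = simulate_assay(c, params, seed=seed, obs=obs)
        ser = calibrate_fluorescence(
            assay.observed_fluorescence, assay.grid,
            gain=obs.gain, blank=obs.blank, condition=c, replicate=r,
        )
        reps.append(exclude_quench_window(ser, c))
    return fit_initial_rate(mean_of_replicates(reps), window_h, threshold)
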