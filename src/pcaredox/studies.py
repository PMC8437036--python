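"""Seeded simulation studies: recovery, calibration and conservation sweeps.

These run the full observation-and-inference path on synthetic assays many
times to measure frequentist operating characteristics: how accurately the
windowed OLS recovers a known oxidation rate, whether the slope's
confidence interval covers at its nominal level, and how often the
electron-budget test infers redox cycling when it should (and should not).
"""

from __future__ import annotations

import numpy as np

from .budget import electron_budget, estimate_initial_n_rate
from .conditions import ConditionSpec, condition, default_condition_matrix
from .rates import (
    DEFAULT_DETECTION_THRESHOLD_UM,
    InitialRateModel,
    RateEstimate,
    calibrate_fluorescence,
)
from .series import ConcentrationSeries, mean_of_replicates
from .sim import (
    KineticParams,
    ObservationParams,
    apply_observation_model,
    conservation_residuals,
    simulate_assay,
)


def _trial_rngs(seed: int, n_trials: int, stream: int) -> list:
    ss = np.random.SeedSequence(entropy=int(seed) % (2**31),
                                spawn_key=(stream,))
    return [np.random.default_rng(child) for child in ss.spawn(n_trials)]


def parameter_recovery_study(
    n_trials: int = 500,
    seed: int = 0,
    k_biox: float = 25.0,
    noise_sd_uM: float = 2.0,
    replicates: int = 3,
    window_h: float = 5.0,
) -> dict:
    """Recover a known PCA oxidation rate from noisy plate observations.

    Simulates the nitrate-stimulated fast-oxidizer condition once (the
    kinetics are deterministic), then per trial draws fresh replicate
    fluorescence noise, calibrates, averages replicates and fits the
    windowed OLS.  Reports the fitted rates and the fraction of trials
    whose rate lies within 3 uM/h of ``-k_biox``.

    Note the recovered slope also carries the slow abiotic contribution
    from cell-produced nitrite (~ -k_abio), so the expected value sits
    slightly below ``-k_biox``.
    """
    obs = ObservationParams(noise_sd_uM=noise_sd_uM)
    cond = condition("C. portucalensis MBL", "nitrate", "reduced")
    assay = simulate_assay(cond, KineticParams(k_biox=k_biox), seed=seed,
                           obs=obs)
    truth = assay.true_series["PCA_red"].values
    rates = np.empty(n_trials)
    for i, rng in enumerate(_trial_rngs(seed, n_trials, stream=1)):
        reps = []
        for _ in range(replicates):
            raw = apply_observation_model(
                truth, assay.grid, gain=obs.gain, blank=obs.blank,
                noise_sd=obs.noise_sd, rng=rng,
            )
            reps.append(
                calibrate_fluorescence(raw, assay.grid, gain=obs.gain,
                                       blank=obs.blank)
            )
        mean = mean_of_replicates(reps)
        est = InitialRateModel(mean, window_h,
                               DEFAULT_DETECTION_THRESHOLD_UM).fit()
        rates[i] = est.rate
    within = np.abs(rates - (-k_biox)) <= 3.0
    return {
        "rates": rates,
        "fraction_within_3": float(within.mean()),
        "mean_rate": float(rates.mean()),
    }


def ci_coverage_study(
    n_trials: int = 1000,
    seed: int = 0,
    n_points: int = 20,
    slope: float = -25.0,
    intercept: float = 200.0,
    noise_sd: float = 2.0,
    alpha: float = 0.05,
) -> dict:
    """Empirical coverage of the slope's t-based confidence interval.

    Draws Gaussian-noise lines, fits each with the package's OLS path and
    checks whether ``conf_int(use_t=True)`` contains the true slope.
    Under the homoscedastic Gaussian model the t interval is exact, so
    coverage should sit at ``1 - alpha`` up to binomial error.
    """
    t = np.linspace(0, 5, n_points)
    hits = 0
    for rng in _trial_rngs(seed, n_trials, stream=2):
        y = intercept + slope * t + rng.normal(0, noise_sd, n_points)
        y = y - min(y.min(), 0.0)  # keep the container's values >= 0
        est = InitialRateModel(
            ConcentrationSeries(t, y), window_h=t[-1] + 1.0
        ).fit()
        lo, hi = est.conf_int(alpha=alpha, use_t=True)
        hits += lo <= slope <= hi
    return {"coverage": hits / n_trials, "n_trials": n_trials}


def cycling_calibration_study(
    n_trials: int = 500,
    seed: int = 0,
    r_no3_stim: float = 0.0,
    k_biox: float = 25.0,
    replicates: int = 3,
    ic_noise_sd: float = 120.0,
    ic_times=(0.0, 4.0, 8.0),
) -> dict:
    """Operating characteristics of the redox-cycling inference.

    Simulates the ion-chromatography experiment (nitrate tubes with
    reduced PCA versus a no-PCA reference) with the requested stimulated
    rate, then per trial draws fresh IC measurement noise, estimates the
    first-two-points nitrate rates with replicate-propagated intervals,
    and runs the electron budget against the known oxidation-rate cap.

    With ``r_no3_stim = 0`` the true excess equals the direct-donation cap
    exactly, so inferring cycling is a false positive; with a large
    stimulated rate the inference should almost always fire.
    """
    ic_times = np.asarray(ic_times, dtype=float)
    grid = np.arange(0.0, ic_times[-1] + 1e-9, 0.25)
    params = KineticParams(k_biox=k_biox, r_no3_stim=r_no3_stim)
    truth = {}
    for label, pca_state in (("with_pca_red", "reduced"), ("reference", "none")):
        assay = simulate_assay(
            condition("C. portucalensis MBL", "nitrate", pca_state),
            params, grid=grid, seed=seed,
        )
        idx = np.searchsorted(grid, ic_times)
        truth[label] = assay.true_series["no3"].values[idx]

    pca_cap_rate = RateEstimate.from_value_ci(-k_biox, 0.0, species="no3")
    inferred = np.zeros(n_trials, dtype=bool)
    for i, rng in enumerate(_trial_rngs(seed, n_trials, stream=3)):
        ests = {}
        for label in ("with_pca_red", "reference"):
            reps = [
                ConcentrationSeries(
                    ic_times,
                    np.clip(truth[label]
                            + rng.normal(0, ic_noise_sd, ic_times.size),
                            0, None),
                    species="no3",
                )
                for _ in range(replicates)
            ]
            ests[label] = estimate_initial_n_rate(reps)
        budget = electron_budget(pca_cap_rate, ests["with_pca_red"],
                                 ests["reference"])
        inferred[i] = budget.cycling_inferred
    return {
        "fraction_inferred": float(inferred.mean()),
        "n_trials": n_trials,
        "stoich_cap": k_biox,
    }


def conservation_sweep(replicates: int = 3, seed: int = 0) -> dict:
    """Max conservation residuals over the full default condition design."""
    worst_pca = 0.0
    worst_n = 0.0
    for cond in default_condition_matrix(replicates):
        assay = simulate_assay(cond, seed=seed)
        pca_resid, n_resid = conservation_residuals(assay)
        worst_pca = max(worst_pca, pca_resid)
        worst_n = max(worst_n, n_resid)
    return {"max_pca_residual": worst_pca, "max_n_residual": worst_n,
            "n_conditions": len(default_condition_matrix(replicates))}


__all__ = [
    "parameter_recovery_study",
    "ci_coverage_study",
    "cycling_calibration_study",
    "conservation_sweep",
]
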