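"""Initial-rate estimation from plate-reader kinetics.

The workflow mirrors the standard microplate analysis: calibrate raw
fluorescence to PCA_red concentration, flag the early quench artifact in
supplied-nitrite wells, anchor at the first detectable measurement, fit an
ordinary-least-squares line over a fixed window (default 5 h), and report
the slope with its standard error and 95% confidence interval.

Sign convention: PCA_ox reduction is a positive rate, PCA_red oxidation a
negative rate.  A rate is called "oxidation" or "reduction" only when its
magnitude exceeds the 1.96 x SE half-interval; otherwise "indeterminate".

The central objects follow the Model/Results pattern:
``InitialRateModel(series, window_h=5).fit()`` returns a ``RateEstimate``
results object carrying the estimates, uncertainties and diagnostics, with
a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .conditions import ConditionSpec
from .errors import DegenerateFitError, InsufficientDataError, NoValidDataError
from .series import ConcentrationSeries, mean_of_replicates

QUENCH_CUTOFF_H = 1.5
DEFAULT_WINDOW_H = 5.0
#: First-detectable threshold: blank-equivalent (0 after calibration) plus
#: three times the default concentration-equivalent noise sd of 2 uM.
DEFAULT_DETECTION_THRESHOLD_UM = 6.0

OXIDATION = "oxidation"
REDUCTION = "reduction"
INDETERMINATE = "indeterminate"


def _interpret(rate: float, ci95_half: float) -> str:
    if rate < 0 and abs(rate) > ci95_half:
        return OXIDATION
    if rate > 0 and rate > ci95_half:
        return REDUCTION
    return INDETERMINATE


@dataclass
class RateEstimate:
    """Results of an initial-rate fit.

    Attributes
    ----------
    rate : float
        OLS slope in uM/h (signed; see the module sign convention).
    se : float
        Standard error of the slope.
    ci95_half : float
        Half-width of the 95% interval, ``1.96 * se``.
    window : tuple of float
        (t_start, t_end) of the fitted window in hours.
    r2 : float
        Coefficient of determination; NaN for windows of <= 2 points.
    n_points : int
        Number of valid points used.
    interpretation : str
        "oxidation", "reduction" or "indeterminate".
    """

    rate: float
    se: float
    ci95_half: float = None  # type: ignore[assignment]
    window: tuple = (np.nan, np.nan)
    r2: float = np.nan
    n_points: int = 0
    interpretation: str = None  # type: ignore[assignment]
    species: str = "PCA_red"
    df_resid: int = 0
    note: str = ""

    def __post_init__(self) -> None:
        if self.ci95_half is None:
            self.ci95_half = 1.96 * self.se
        if self.interpretation is None:
            self.interpretation = _interpret(self.rate, self.ci95_half)

    @classmethod
    def from_value_ci(cls, rate: float, ci95_half: float, **kw) -> "RateEstimate":
        """Build from a reported ``value +/- ci95`` pair (SE backed out)."""
        return cls(rate=rate, se=ci95_half / 1.96, ci95_half=ci95_half, **kw)

    def conf_int(self, alpha: float = 0.05, use_t: bool = False) -> tuple:
        """(lower, upper) confidence bounds for the slope.

        ``use_t=False`` uses the normal 1.96-style quantile (the reporting
        convention); ``use_t=True`` uses the Student-t quantile on the fit's
        residual degrees of freedom, which is calibrated at small n.
        """
        if use_t and self.df_resid > 0:
            q = stats.t.ppf(1 - alpha / 2, self.df_resid)
        elif alpha == 0.05:
            q = 1.96  # the reporting convention, consistent with ci95_half
        else:
            q = stats.norm.ppf(1 - alpha / 2)
        return (self.rate - q * self.se, self.rate + q * self.se)

    def summary(self) -> str:
        lines = [
            "Initial-rate fit",
            "----------------",
            f"species          : {self.species}",
            f"rate             : {self.rate:.2f} uM/h ({self.interpretation})",
            f"std err          : {self.se:.3f} uM/h",
            f"95% CI           : [{self.rate - self.ci95_half:.2f}, "
            f"{self.rate + self.ci95_half:.2f}] uM/h",
            f"window           : {self.window[0]:.2f} - {self.window[1]:.2f} h",
            f"R^2              : {self.r2:.4f}" if np.isfinite(self.r2)
            else "R^2              : n/a",
            f"n points         : {self.n_points}",
        ]
        if self.note:
            lines.append(f"note             : {self.note}")
        return "\n".join(lines)


def calibrate_fluorescence(
    raw: np.ndarray,
    times: np.ndarray,
    gain: float,
    blank: float,
    *,
    species: str = "PCA_red",
    condition: Optional[ConditionSpec] = None,
    replicate: Optional[int] = None,
) -> ConcentrationSeries:
    """Convert fluorescence to concentration: ``(raw - blank) / gain``.

    Readings below blank would map to negative concentrations; those points
    are clipped to 0 and flagged invalid rather than reported negative.
    """
    if gain <= 0:
        raise ValueError("gain must be > 0")
    raw = np.asarray(raw, dtype=float)
    conc = (raw - blank) / gain
    valid = conc >= 0
    return ConcentrationSeries(
        times=np.asarray(times, dtype=float),
        values=np.where(valid, conc, 0.0),
        species=species,
        condition=condition,
        replicate=replicate,
        valid=valid,
    )


def exclude_quench_window(
    series: ConcentrationSeries,
    cond: Optional[ConditionSpec] = None,
    cutoff_h: float = QUENCH_CUTOFF_H,
) -> ConcentrationSeries:
    """Flag points before ``cutoff_h`` invalid in supplied-nitrite conditions.

    Conditions without supplied nitrite pass through unchanged, as do
    nitrite series with no points before the cutoff.
    """
    cond = cond if cond is not None else series.condition
    if cond is None or cond.tea != "nitrite":
        return series
    early = series.times < cutoff_h
    if not early.any():
        return series
    return series.with_flags(early)


def find_first_valid(series: ConcentrationSeries, threshold: float = 0.0) -> float:
    """Earliest time with an unflagged value >= threshold.

    Raises :class:`NoValidDataError` when no point qualifies.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    mask = series.valid & (series.values >= threshold)
    if not mask.any():
        raise NoValidDataError(
            f"no valid measurement >= {threshold} uM in {series.species} series"
        )
    return float(series.times[np.argmax(mask)])


class InitialRateModel:
    """OLS line through the first ``window_h`` hours of detectable signal.

    Parameters
    ----------
    series : ConcentrationSeries
        Calibrated concentrations with validity flags already applied
        (quench exclusion etc.).
    window_h : float
        Window length in hours, anchored at the first valid measurement
        (not at assay start).
    detection_threshold : float
        Minimum concentration counting as "detectable" for the anchor.
    """

    def __init__(
        self,
        series: ConcentrationSeries,
        window_h: float = DEFAULT_WINDOW_H,
        detection_threshold: float = 0.0,
    ) -> None:
        if window_h <= 0:
            raise ValueError("window_h must be > 0")
        self.series = series
        self.window_h = float(window_h)
        self.detection_threshold = float(detection_threshold)

    def _window_points(self) -> tuple[np.ndarray, np.ndarray, float]:
        t0 = find_first_valid(self.series, self.detection_threshold)
        in_win = (
            self.series.valid
            & (self.series.times >= t0 - 1e-12)
            & (self.series.times <= t0 + self.window_h + 1e-9)
        )
        return self.series.times[in_win], self.series.values[in_win], t0

    def fit(self) -> RateEstimate:
        """Fit and return the results object.

        Raises :class:`InsufficientDataError` for < 3 valid points in the
        window and :class:`DegenerateFitError` for zero time variance.
        """
        t, y, t0 = self._window_points()
        n = t.size
        if n < 3:
            raise InsufficientDataError(
                f"{n} valid points in [{t0}, {t0 + self.window_h}] h; need >= 3"
            )
        if np.ptp(t) == 0:
            raise DegenerateFitError("zero variance in time within the window")
        if np.ptp(y) == 0:
            # Exactly flat series: slope 0 with no residual scatter.  A
            # horizontal line fits perfectly, so R^2 is reported as 1.
            slope, se, r2 = 0.0, 0.0, 1.0
        else:
            res = sm.OLS(y, sm.add_constant(t)).fit()
            slope = float(res.params[1])
            se = float(res.bse[1])
            r2 = float(res.rsquared)
        return RateEstimate(
            rate=slope,
            se=se,
            window=(t0, float(t[-1])),
            r2=r2,
            n_points=int(n),
            species=self.series.species,
            df_resid=int(n - 2),
        )


def fit_initial_rate(
    series: ConcentrationSeries,
    window_length: float = DEFAULT_WINDOW_H,
    detection_threshold: float = 0.0,
) -> RateEstimate:
    """Functional wrapper over :class:`InitialRateModel`."""
    return InitialRateModel(series, window_length, detection_threshold).fit()


@dataclass
class WindowScan:
    """R^2 of the initial-rate fit as a function of window length."""

    window_lengths: np.ndarray  # h
    r2_values: np.ndarray  # NaN where no fit was possible
    chosen_window: float = DEFAULT_WINDOW_H

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"window_h": self.window_lengths, "r2": self.r2_values,
             "chosen": self.window_lengths == self.chosen_window}
        )


def scan_window_r2(
    series: ConcentrationSeries,
    max_length: float = 15.0,
    step: float = 0.5,
    detection_threshold: float = 0.0,
    chosen_window: float = DEFAULT_WINDOW_H,
) -> WindowScan:
    """Fit over increasing window lengths and track R^2.

    Used to pick a fitting window that stays inside the linear regime: R^2
    drops once the window crosses into substrate exhaustion.  Lengths where
    no fit is possible (too few valid points) record NaN.
    """
    if not (max_length >= step > 0):
        raise ValueError("require max_length >= step > 0")
    lengths = np.arange(step, max_length + 1e-9, step)
    r2 = np.full(lengths.size, np.nan)
    for i, length in enumerate(lengths):
        try:
            est = fit_initial_rate(series, length, detection_threshold)
        except (InsufficientDataError, NoValidDataError, DegenerateFitError):
            continue
        r2[i] = est.r2
    return WindowScan(lengths, r2, chosen_window=chosen_window)


@dataclass
class ConditionRates:
    """Per-condition fit on the replicate mean, plus per-replicate fits."""

    strain: str
    tea: str
    pca_state: str
    estimate: Optional[RateEstimate]
    replicate_estimates: list


def fit_all(
    plate: pd.DataFrame,
    layout: pd.DataFrame,
    *,
    gain: float,
    blank: float,
    window_h: float = DEFAULT_WINDOW_H,
    quench_cutoff_h: float = QUENCH_CUTOFF_H,
    detection_threshold: float = DEFAULT_DETECTION_THRESHOLD_UM,
) -> pd.DataFrame:
    """Fit every condition in a plate and return a tidy rates table.

    ``plate`` has columns well, time_h, fluorescence, od600 (long format);
    ``layout`` maps well -> strain, tea, pca_state, replicate and must cover
    every well in the plate.  The condition-level rate is fitted on the mean
    of the replicates at shared time points; per-replicate rates are
    reported alongside as a dispersion check, never averaged into the
    condition slope.

    Conditions whose signal never reaches the detection threshold (e.g.
    abiotic wells started with oxidized PCA) are reported with NaN rate and
    "indeterminate" interpretation.
    """
    _require_columns(plate, ["well", "time_h", "fluorescence"], "plate")
    _require_columns(layout, ["well", "strain", "tea", "pca_state", "replicate"],
                     "layout")
    missing = sorted(set(plate["well"]) - set(layout["well"]))
    if missing:
        raise ValueError(f"wells missing from layout: {missing}")

    from .conditions import condition as make_condition

    lay = layout.set_index("well")
    rows = []
    grouped = plate.sort_values("time_h").groupby("well", sort=True)
    by_condition: dict[tuple, list[ConcentrationSeries]] = {}
    for well, g in grouped:
        meta = lay.loc[well]
        cond = make_condition(
            str(meta["strain"]), str(meta["tea"]), str(meta["pca_state"]),
            replicate=int(meta["replicate"]),
        )
        ser = calibrate_fluorescence(
            g["fluorescence"].to_numpy(), g["time_h"].to_numpy(),
            gain=gain, blank=blank, condition=cond, replicate=cond.replicate,
        )
        ser = exclude_quench_window(ser, cond, quench_cutoff_h)
        key = (cond.strain, cond.tea, cond.pca_start)
        by_condition.setdefault(key, []).append(ser)

    for (strain, tea, pca_state), reps in sorted(by_condition.items()):
        mean_series = mean_of_replicates(reps)
        est = _try_fit(mean_series, window_h, detection_threshold)
        rep_rates = [
            e.rate if (e := _try_fit(r, window_h, detection_threshold)) else np.nan
            for r in reps
        ]
        rows.append(
            {
                "strain": strain,
                "tea": tea,
                "pca_state": pca_state,
                "rate_uM_per_h": round(est.rate, 2) if est else np.nan,
                "se": est.se if est else np.nan,
                "ci95": est.ci95_half if est else np.nan,
                "r2": est.r2 if est else np.nan,
                "window_h": window_h,
                "n_points": est.n_points if est else 0,
                "interpretation": est.interpretation if est else INDETERMINATE,
                "n_replicates": len(reps),
                "replicate_rates": ";".join(
                    "" if not np.isfinite(r) else f"{r:.4f}" for r in rep_rates
                ),
            }
        )
    return pd.DataFrame(rows)


def _try_fit(series, window_h, threshold):
    try:
        return fit_initial_rate(series, window_h, threshold)
    except (NoValidDataError, InsufficientDataError, DegenerateFitError):
        return None


def _require_columns(df: pd.DataFrame, cols: Sequence[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table missing columns: {missing}")


__all__ = [
    "RateEstimate",
    "WindowScan",
    "InitialRateModel",
    "ConditionRates",
    "calibrate_fluorescence",
    "exclude_quench_window",
    "find_first_valid",
    "fit_initial_rate",
    "scan_window_r2",
    "fit_all",
    "OXIDATION",
    "REDUCTION",
    "INDETERMINATE",
    "DEFAULT_WINDOW_H",
    "QUENCH_CUTOFF_H",
    "DEFAULT_DETECTION_THRESHOLD_UM",
]
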