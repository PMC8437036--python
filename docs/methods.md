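# Methods

## The kinetic model

The simulator integrates four concentration pools — PCA_red, PCA_ox,
NO₃⁻, NO₂⁻ (all µM) — with an explicit adaptive Runge–Kutta method
(scipy `RK45`, rtol 1e−8, atol 1e−10). The reaction network:

| flux | rate law | gate |
| --- | --- | --- |
| biotic PCA_red oxidation | gross `s_tea·(k_biox·s(PCA_red) + v_bred)` | supplied TEA ∈ strain's `can_oxidize_with` |
| biotic PCA_ox reduction | `k_bred·s(PCA_ox)` | `can_reduce_pca`; under a stimulating TEA only in `cycling` mode |
| abiotic nitrite oxidation of PCA_red | `k_abio·s(PCA_red)·s(NO2)` | always (purely chemical) |
| cellular NO₃⁻ reduction | `(r_no3_base + r_no3_stim·s(PCA_red))·s(NO3)` | biotic, nitrate present; the stimulated term only while net PCA oxidation proceeds |
| direct donation | positive part of net biotic PCA flux, ×`e_pca/e_no3` | stimulating TEA is nitrate |

Observed traces are near-linear until a pool empties, so all rates are
zero-order with a smooth switch-off `s(x) = 1 − exp(−ln2·x/K)`,
half-saturation `K = 5 µM`. This form is exactly ½ at `K`, indistinguishable
from 1 at the working concentrations (200 µM PCA, 10 mM TEA), and keeps
the system smooth and non-stiff near zero; a Monod form `x/(x+K)` would
shave ~2.5 % off every configured rate at 200 µM, which is why the
exponential switch was chosen.

Two modeling commitments deserve emphasis:

* **`k_biox` is the net observable oxidation rate.** In the default
  `cycling` suppression mode, capable strains keep reducing PCA_ox at
  `k_bred` even when a stimulating TEA is present; the gross oxidation
  flux reoxidizes that product and additionally removes PCA_red at
  `k_biox`. Net reduction under nitrate is therefore exactly zero (the
  observed "nondetectable" reduction), while a plate assay started from
  PCA_red sees −`k_biox`. `suppression="hard"` instead switches reduction
  off entirely; the two modes produce identical net traces and differ only
  in gross turnover.
* **Electron accounting.** Total nitrate reduction = direct donation
  (net PCA oxidation routed into NO₃⁻ when nitrate is the stimulating TEA)
  + cellular paths (`r_no3_base`, plus `r_no3_stim` while oxidation runs).
  The cycle's extra throughput is carried by `r_no3_stim` — an effective
  rate, deliberately agnostic about mechanism, because whether PCA_red
  electrons enter cellular metabolism is an open experimental question.
  The ledger `2·(net PCA oxidized) + 2·(cellular) = 2·(total NO₃⁻
  reduced)` closes identically along every trajectory and is audited in
  the tests by independent trapezoidal integration of the flux terms.
* **The nitrite pool is a reservoir for the abiotic back-reaction.** Its
  reduction product (NO) is outside the modeled pools, and at ~1.5 µM/h
  against 10 mM the depletion is negligible; treating it this way keeps
  NO₃⁻+NO₂⁻ conservation exact. Conservation of both pool sums is asserted
  post hoc at 10× solver tolerance rather than enforced by projection.

## Default parameters

| parameter | default | unit | rationale |
| --- | --- | --- | --- |
| `pca_total` | 200 | µM | assay target concentration |
| `tea_conc` | 10 000 | µM | 10 mM supplied nitrate/nitrite |
| `k_biox` (*C. portucalensis*) | 25 | µM/h | the measured fast oxidizer |
| `k_biox` (*P. aureofaciens* / *P. chlororaphis*, nitrite) | 2.75 / 3.10 | µM/h | measured nitrite-stimulated rates |
| `k_biox` (*E. coli* / *P. aeruginosa*) | 12 / 8 | µM/h | unreported; representative intermediate scales |
| `k_bred` | 8 | µM/h | unreported; representative no-TEA reduction scale |
| `k_abio` | 1.48 | µM/h | measured abiotic nitrite reaction |
| `r_no3_base` | 22 | µM/h | no-PCA nitrite-production rate (the no-PCA nitrate-consumption reading is noise-dominated) |
| `r_no3_stim` | 84 | µM/h | so base + stimulation + donation ≈ 131 µM/h, the measured PCA_red-condition rate |
| `half_sat` | 5 | µM | switch-off scale; traces stay linear to near-exhaustion |
| fluorescence gain / blank | 100 / 100 | AFU/µM, AFU | arbitrary but invertible calibration |
| fluorescence noise | 2 µM equivalent | — | plate-reader-scale scatter |
| IC noise sd | 120 | µM | chosen so the replicate-propagated 95 % CI of a first-two-points rate (n = 3, Δt = 4 h) is ≈ ±48 µM/h, the scale of the measured intervals |
| plate grid | 0–24 h, 0.25 h | — | read interval unreported; a typical kinetic-read cadence |
| IC sampling | {0,4,…,24} h | — | sparse tube sampling |
| quench artifact | ×0.85→1.0 over 0–1.5 h | — | shape invented; only its confinement to <1.5 h is empirical |

Per-replicate noise streams are derived from the root seed plus a CRC32 of
the condition label and the replicate index, so any subset of a design can
be regenerated independently and bit-identically.

## Rate estimation

Calibration inverts the observation model, `c = (F − blank)/gain`;
readings below blank are clipped to zero and flagged invalid rather than
reported negative. Supplied-nitrite conditions flag all points before
1.5 h (the quench artifact); flagged points can never influence a fit.
The fit window (default 5 h, from the R² window scan) is anchored at the
first *detectable* measurement — the first unflagged reading at or above
blank-equivalent + 3× noise sd (6 µM by default) — not at assay start.

The slope, its standard error and R² come from statsmodels OLS. The
condition-level rate is fitted on the pointwise mean of the replicates (a
time point must be valid in every replicate to enter the mean);
per-replicate slopes are reported alongside as a dispersion check but are
never averaged into the estimate, avoiding the slope-of-means vs
mean-of-slopes ambiguity. Pooling replicate points into a single fit is
also supported for the nitrogen series (`mode="window"`).

Reported intervals are `±1.96·SE` — the field's reporting convention, kept
for comparability. At small n this normal quantile under-covers (~93.5 %
at n = 20), so `RateEstimate.conf_int(use_t=True)` exposes the Student-t
interval, which is exact under the Gaussian noise model; the coverage
study uses it. Degenerate cases: an exactly flat window reports slope 0,
SE 0 and R² = 1 (a horizontal line is a perfect fit); windows with ≤ 2
points report R² as missing; fewer than 3 valid points is an error, not a
NaN row, except in the batch `fit_all`, which records such conditions as
indeterminate with no rate.

Two-point nitrogen rates carry an SE propagated from replicate scatter:
`SE = sqrt(sem(t₁)² + sem(t₂)²)/(t₂−t₁)`. The authors' interval
construction for these rates is unreported, so this is a documented
package choice; a single tube yields SE 0.

## Rate contrasts and the electron budget

Contrasts combine intervals in quadrature, `sqrt(h_a² + h_b²)` — the exact
propagation for independent estimates, and the only rule that reproduces
the measured ±60 and ±44 contrast widths. A literal geometric mean of the
two intervals (`sqrt(h_a·h_b)`) is available behind
`method="geometric_mean"` for comparison; it is not a valid propagation
and shrinks the interval whenever the inputs are unequal.

The budget sets the stoichiometric cap `|R_PCA|·e_PCA/e_NO3` (both
two-electron by default) and infers cycling when the excess's 95 % lower
bound exceeds the cap. Because whether the comparison should be against
the cap or against zero is scientifically arguable, the weaker
excludes-zero result is always reported alongside. The endpoint
stoichiometry check (`ΔNO₂ ≈ −ΔNO₃`) uses a tolerance of 5 % of consumed
nitrate, floored at the propagated endpoint measurement noise when applied
to noisy IC data.

Thermodynamic feasibility is a midpoint-potential comparison at pH 7
(PCA −116 mV, NO₃⁻/NO₂⁻ +433 mV, NO₂⁻/NO +350 mV vs NHE); no Nernst
correction for non-standard concentrations is attempted.

## What the synthetic data do and do not show

The generator reproduces the statistical structure the analysis assumes:
near-linear initial segments, TEA-gated gating patterns across a
6-strain × 3-TEA × 2-PCA-state × 3-replicate design, stoichiometric
NO₃⁻→NO₂⁻ conversion, flat OD600 (no growth, by construction), Gaussian
homoscedastic measurement noise, and the early-nitrite quench artifact.
It does not emulate: well-to-well calibration drift, heteroscedastic or
correlated noise, evaporation or edge effects, pH or thermodynamic rate
coupling, enzyme saturation kinetics, downstream denitrification beyond
nitrite, or any growth dynamics. Passing tests therefore demonstrate that
the estimators are correct and calibrated *under the stated noise model*,
not that real plates are free of systematic error.

Study sizes (500 recovery trials, 1000 coverage trials, 500 seeds per
cycling scenario, the 108-well conservation sweep) were chosen so binomial
uncertainty on the measured fractions is well below the margins being
asserted, while the whole suite runs in seconds.

## Numerical choices and limitations

* Window-edge membership uses a 1e−9 h tolerance; pooled replicate series
  use a 1e−12 h jitter to satisfy the strictly-increasing-time contract
  without affecting window membership or OLS results.
* The cycling-power scenario sets the stimulated rate (210 µM/h) to put
  the true excess ≥ 3 combined 95 % half-widths above the cap
  (3 × ≈ 68 µM/h at IC noise 120 µM, n = 3, Δt = 4 h).
* The false-positive scenario (no stimulation, donation only) has a true
  excess exactly at the cap, so the nominal false-inference rate is the
  one-sided 2.5 %; the test allows 5 %.
* The recovered nitrate-condition rate sits ~1.5 µM/h below −`k_biox`
  because cell-produced nitrite drives the abiotic back-reaction inside
  the fit window; this is a property of the coupled system, not estimator
  bias, and the ±3 µM/h recovery margin accommodates it.
* Strain capabilities are a small registry; unregistered strains behave
  abiotically unless a full `ConditionSpec` is supplied. The inference
  layer is frequentist throughout; no hierarchical pooling across strains
  or conditions is attempted.
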