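# pcaredox

Analysis and simulation toolkit for **terminal-electron-acceptor-dependent
oxidation of phenazine-1-carboxylic acid (PCA)** by bacteria, and for the
stoichiometric electron budget that links PCA redox cycling to enhanced
nitrate reduction.

PCA is a secreted, redox-active metabolite that shuttles between a reduced,
fluorescent form (PCA_red) and an oxidized, non-fluorescent form (PCA_ox)
by two-electron transfer. Soil bacteria such as *Citrobacter portucalensis*
MBL oxidize PCA_red anaerobically — but only when a suitable terminal
electron acceptor (TEA) such as nitrate is available — and reduce PCA_ox
when it is not. The package is aimed at microbial-physiology and
biogeochemistry groups who run plate-reader redox assays and
ion-chromatography time courses and want the full inference chain, from raw
fluorescence to the redox-cycling verdict, as tested, scriptable code.

## What it computes

**Initial rates.** For a calibrated concentration series $c(t)$, the
initial rate is the OLS slope $\hat\beta$ of $c$ on $t$ over a fixed window
(default 5 h) anchored at the first detectable measurement, reported as
$\hat\beta \pm 1.96\,\mathrm{SE}(\hat\beta)$ with $R^2$ and an automatic
sign-convention call: oxidation ($\hat\beta<0$), reduction
($\hat\beta>0$), or indeterminate when the interval covers zero. The fit
window is chosen by scanning $R^2$ over increasing window lengths and
stopping before substrate exhaustion bends the trace. Supplied-nitrite
wells exclude the first 1.5 h, where a fluorescence-quench artifact
suppresses the PCA_red signal.

**Rate contrasts.** Two rates $a \pm h_a$, $b \pm h_b$ are contrasted as
$a-b \pm \sqrt{h_a^2+h_b^2}$ (quadrature, the exact propagation for
independent estimates).

**Electron budget.** PCA redox and the nitrate→nitrite step are both
two-electron processes, so oxidizing PCA_red at $R$ µM/h can directly
account for at most $R \cdot e_\mathrm{PCA}/e_{\mathrm{NO_3}} = R$ µM/h of
nitrate reduction. If the 95% lower bound of the measured excess of nitrate
reduction (PCA_red condition minus reference) exceeds that cap, one-pass
electron donation cannot explain it — evidence that the cells are running a
PCA redox **cycle**.

**Simulator.** A four-pool ODE model (PCA_red, PCA_ox, NO₃⁻, NO₂⁻) with
TEA-gated zero-order kinetics, an abiotic nitrite→PCA_red back-reaction,
and a plate-reader/ion-chromatography observation model (gain, blank,
Gaussian noise, quench artifact, flat OD600) generates synthetic assays
with known ground truth for every analysis stage.

## Worked example

The headline inference, from the tabulated first-8-h nitrogen rates
(nitrate reduction 131 ± 49 µM/h with PCA_red vs 35 ± 35 with PCA_ox;
PCA oxidation 25 µM/h):

```python
>>> from pcaredox import worked_example
>>> print(worked_example()["budget"].summary())
Two-electron budget
-------------------
PCA oxidation rate      : 25 uM/h
stoichiometric cap      : 25 uM/h (x2/2 e-)
observed excess         : 96 +/- 60 uM/h
excess 95% lower bound  : 36 uM/h
excess excludes zero    : True
verdict                 : REDOX CYCLING INFERRED
```

The excess nitrate reduction is 96 ± 60 µM/h; even its lower bound
(36 µM/h) exceeds the 25 µM/h that direct two-electron donation could
supply, so the stimulation must run through something other than
one-to-one electron transfer — a catalyzed PCA redox cycle.

Simulating an assay and fitting its initial rate:

```python
>>> from pcaredox import condition, simulate_assay, fit_initial_rate
>>> assay = simulate_assay(condition("C. portucalensis MBL", "nitrate", "reduced"), seed=1)
>>> print(fit_initial_rate(assay.true_series["PCA_red"], 5.0).summary())
Initial-rate fit
----------------
species          : PCA_red
rate             : -26.48 uM/h (oxidation)
std err          : 0.002 uM/h
95% CI           : [-26.48, -26.47] uM/h
window           : 0.00 - 5.00 h
R^2              : 1.0000
n points         : 21
```

The fitted −26.5 µM/h is the configured 25 µM/h biotic rate plus the slow
abiotic oxidation by the nitrite the cells themselves produce.
Thermodynamic sanity check: `thermodynamic_feasibility("PCA", "NO3-/NO2-")`
returns `(549.0, True)` — a +549 mV downhill transfer.

The same pipeline is available from the shell:

```bash
pcaredox reproduce --seed 1 --out runs/demo     # simulate → fit → budget
pcaredox fit --plate plate.csv --layout layout.csv --window 5 --out rates.csv
pcaredox validate --plate plate.csv --layout layout.csv
```

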