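# Methods

This note documents the models implemented in `residuechain`, the
assumptions behind them, the defaults of the synthetic-study generator, and
the numerical and design choices that were genuinely open.

## Response-surface model of the residue ratio

The residue ratio over a storage stage (C1/C0 for wheat, C3/C2 for flour)
is modelled as a full second-order polynomial in storage time *t* (days),
temperature *T* (°C) and relative humidity *RH* (percentage points; 50
means 50 %):

    ratio = b0 + b_t t + b_T T + b_RH RH + b_tt t² + b_TT T² + b_RHRH RH²
            + b_tT tT + b_tRH tRH + b_TRH TRH

No unit conversions are attempted: coefficients are meaningful only in
day/°C/%RH units, matching the experimental levels the published models
were fitted on (t ≤ 90 d wheat / 60 d flour, T ∈ [20, 50] °C,
RH ∈ [50, 80] %). Outside that box the polynomials extrapolate freely and
can leave the physical range — several flour models have intercepts above 1
and dip below 0 mid-schedule at high humidity. The package deliberately
does not "correct" the published coefficients; instead `evaluate_clamped`
clips ratios into [0, 1] and emits a warning record for every clip, and the
supply-chain predictor surfaces those events in its output.

**Registry fidelity.** The ten published models are stored as printed
strings and parsed once, so the registry can be proofread digit-for-digit.
Two anomalies in the published carbendazim/wheat row are preserved rather
than repaired: (a) its three cross terms are printed with inconsistent
subscripts (two apparent T·RH terms, no t·RH term); they are assigned, in
printed order, to the canonical (t·T, t·RH, T·RH) slots used by every other
row, and the discrepancy is recorded in the model's `notes`; (b) its linear
time coefficient (−0.00246/day) is two orders of magnitude smaller than
every other row's, so the positive t² term dominates after roughly a day
and that polynomial is *not* monotone decreasing in storage time — the
monotonicity property holds for the other four wheat models across
t ∈ [0, 55] days.

**Fitting.** `QuadraticSurfaceRegressor` solves ordinary least squares by
SVD (`numpy.linalg.lstsq`), never by inverted normal equations: raw
monomial columns over day/degree ranges differ by four orders of magnitude
and are ill-conditioned. Columns are norm-scaled internally and
coefficients (and standard errors) mapped back to the raw parameterization
for reporting, so results match a naive OLS to machine precision on
well-conditioned data while remaining stable otherwise. Standard errors
come from σ²(XᵀX)⁻¹ via the same SVD; p-values are two-sided t tests with
n − 10 degrees of freedom. Rank-deficient designs raise an error listing
the aliased columns (greedy rank scan in canonical column order). The full
ten-term model is always fitted — no stepwise selection — and responses are
left on the linear ratio scale, matching the published models. No
multiple-testing correction is applied across pesticides.

## First-order kinetics

Each time course is summarised by log-linear OLS: k = −slope of ln C on t,
t½ = ln 2/k, plus the R² of the log fit. The dissipation literature
standardly derives half-lives this way, though the source study never
states its method; the published half-lives are therefore treated as
*calibration anchors* for simulation, not as reproducible fit outputs.
(They are in fact not reconcilable with the published 90-day percent
decreases under any single first-order model, which supports treating them
as anchors only.) Non-positive concentrations are excluded with a warning;
censored points are excluded from kinetic fits but retained (at their
substituted value) in AUC, consistent with the generator's substitution
rule. A non-positive fitted k yields an infinite half-life with a warning
rather than an error.

`percent_decrease` uses linear interpolation when the horizon falls between
sampling days (schedules are user-defined) and refuses to extrapolate
beyond the observed span. AUC is the trapezoidal rule over observed days
only; it is computed on concentrations by default with a `ratio=True`
switch, since the source analysis does not state which scale it used.

## AUC effect analysis

Temperature and humidity effects on per-condition AUC are tested by
two-factor ANOVA. The original "response surface analysis" performed in
Minitab is unspecified in detail, so significance is *defined* here as:
with replicates, the balanced two-way ANOVA with interaction; with one
observation per cell, the additive two-way ANOVA with Tukey's
one-degree-of-freedom test of nonadditivity as the interaction test. The
sums of squares are computed in closed form (the design is required to be
complete and balanced; unbalanced tables raise), which keeps the
1000-replicate Monte-Carlo calibration of the type-I error rate at ~2 s;
statsmodels' `anova_lm` serves as an independent oracle in the test suite.
A zero-variance table returns F = 0 and p = 1 for every term.

## Synthetic-study generator

The generator emulates factorial storage trials: first-order decay with a
log-linear rate model

    k(T, RH) = k_ref · exp(a_T (T − T_ref) + a_RH (RH − RH_ref)),  a_T, a_RH ≥ 0

(the simplest monotone form consistent with rates that increase in both
factors; over a 30 °C span it is numerically close to an Arrhenius law),
multiplicative lognormal noise with median 1 parameterised by a CV, and
substitution censoring: values below the LOD are stored at LOD/2 and
flagged. Defaults, chosen once to mirror the study conditions the analysis
targets:

| parameter | default | rationale |
|---|---|---|
| temperatures | 20, 30, 40, 50 °C | the published factorial levels |
| humidities | 50, 60, 70, 80 % | the published factorial levels |
| schedule | 0, 1, 3, 5, 7, 14, 21, 30, 45, 60 (+75, 90 wheat) d | typical residue-trial schedule; the source lists none |
| noise CV | 0.05 | mid published assay-precision range (2.88–6.76 %) |
| LOD | 0.002 mg/kg | smallest published LOQ |
| c0 | 1.0 mg/kg | spiking levels are MRL multiples but unprinted |
| replicates | 1 | per-condition curves, as in the source figures |

Multiplicative (not additive) noise was chosen because concentrations span
orders of magnitude within one course; median-1 (not mean-1) noise makes
the noiseless curve the median curve, which the tests verify by Monte
Carlo. A single design seed drives everything, with per-time-course
substreams derived from a CRC of (pesticide, condition, replicate), so any
subset of a study is reproducible independently of generation order.

`calibrate_to_half_lives` converts anchors (T, RH, t½) to log-rates and
fits (log k_ref, a_T, a_RH) by least squares about the anchor centroid;
with ≤ 3 anchors at suitable conditions the minimum-norm solution
interpolates exactly. A negative fitted slope is clipped to zero with a
warning, since the rate model requires monotone rates. `default_params`
calibrates from the published per-condition half-lives; because the source
never states the humidity held during its temperature series (nor the
temperature held during its humidity series), the assumed held levels are
explicit arguments, defaulting to mid-range 60 % RH and 30 °C.

**What the generator does not emulate:** extraction/cleanup chemistry and
chromatographic signal (noise is applied directly at the concentration
level), within-day autocorrelation, replicate-batch effects, biphasic
decay, and any lack of fit of the first-order law itself. Passing tests
therefore demonstrate that the estimators invert the generator's data
model correctly and are calibrated under it — not that real storage data
obey first-order kinetics.

## Supply-chain predictor

c1 = c0 · clamp(wheat ratio), c2 = PF · c1, c3 = c2 · clamp(flour ratio).
PF is a required user input (default 1.0, no milling effect): the source
defines the processing factor but reports no numeric values, so estimating
it is out of scope. Milling is treated as zero-duration — degradation
during processing is folded into PF. Clamping before chaining keeps the
concentrations physical (0 ≤ c1 ≤ c0, 0 ≤ c3 ≤ c2) even where the
polynomials misbehave, and every clamp appears in `clamp_events`. PF > 1
(milling concentrating residue) is allowed but warned about.

## Problem sizes and tolerances

Acceptance-style checks run at: 160-point designs (4×4 conditions × 10
days) for surface refits; 200 replications for ±3 SE coverage at 5 % noise;
1000 null / 400 alternative simulations for ANOVA calibration (3 replicates
per cell, rejection at α = 0.05); 50 randomized draws for the kinetics
oracle (k ∈ [0.01, 0.5]/day). Noiseless round-trips are asserted at 1e−6
relative (coefficients), 1e−9 (rates, R² deviation from 1) and 1e−6 days
(half-life anchors); the trapezoid AUC is asserted within its analytic
error bound (t_span · max|c″|/12 · h²). These sizes give Monte-Carlo
standard errors comfortably inside the asserted bands (e.g. ±0.7 % on the
type-I rate at n = 1000).

## Known limitations

- The published R², half-lives and ANOVA p-values of the source study
  cannot be reproduced: the raw time courses exist only as figures. All
  simulation-based results are conditional on the generator's data model.
- The registry polynomials are trusted as printed, including the anomalous
  carbendazim/wheat row; clamping is the only guard applied.
- The effect ANOVA requires complete balanced factorials.
- No multi-compartment or biphasic kinetics; no packaging/transport stages
  beyond the three modelled critical points.
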