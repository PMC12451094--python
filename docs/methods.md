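# Methods

`pigmentox` models two coupled degradation processes observed when an
anthocyanin-rich plant extract (e.g. black carrot) is stored in an
oxidatively unstable oil-in-water emulsion: first-order loss of the pigment
and sigmoidal build-up of lipid-oxidation products. Around those kinetic
cores it provides spectral colorimetry, external calibration, replicate
statistics, and a seeded generator of study-like data.

## Kinetic models

**Pigment decay.** Concentration follows C(t) = C₀·e^(−kt), with C₀ in µM,
k in day⁻¹ and t in days. The half-life is t½ = ln2/k; the identity
t½·k = ln2 holds exactly by construction in every fit result. Fitting is
bounded nonlinear least squares (scipy trust-region reflective) on the
original concentration scale, so observations of exactly zero — common once
the pigment is gone — are admissible. A log-linear regression on the
strictly positive observations supplies starting values only. k is bounded
below by 0; an estimate pinned at the bound is flagged and reported with
t½ = ∞ (a constant series is a legitimate no-decay limit, not an error).

**Oxidation build-up.** Product concentration follows the logistic form
c(t) = cmax / (1 + A·e^(−kt)) with A = (cmax − c0)/c0, where c0 is the
fitted initial product level, cmax the plateau and k the propagation rate.
Derived statistics come from closed forms that the test suite verifies
against an independent high-precision numeric construction (second-derivative
sign-change bisection plus tangent root, 40-digit arithmetic):

* inflection (fastest propagation): t\* = ln A / k, where c = cmax/2 and
  dc/dt = k·cmax/4;
* induction period: the x-intercept of the tangent at the inflection,
  t_ind = t\* − 2/k = (ln A − 2)/k.

When t_ind ≤ 0 no induction phase can be constructed — typical when the
day-0 product level is already a sizeable fraction of the plateau, as for
hydroperoxides at the most acidic pH — and it is reported as `None`,
rendered "—" in tables.

The logistic RSS surface has flat valleys in k whenever the sampling grid
misses the propagation phase, so the fit is multi-started over
k ∈ {0.05, 0.2, 0.8, 3.2, 12.8} day⁻¹ and the best-RSS solution wins; RSS
ties (relative 1e-10) break toward the smallest k, preferring the slower,
more conservative kinetics. Bounds: cmax ∈ [0.8, 3]·max(observation);
c0 ∈ [1e-6, 2·max(smallest positive observation, mean at the first
timepoint)]. The first-timepoint mean enters the c0 bound because
measurement noise truncated at zero can push a single early observation far
below the true initial level; bounding by the minimum alone then clips c0
against the bound. The 1e-6 µM floor keeps A finite. Series whose range is
below twice a robust noise floor (1.4826·median|Δc|/√2) are returned
flagged non-converged with derived statistics `None` rather than fitted.

**Replicate aggregation.** The study design is duplicate preparations ×
duplicate measurements; fitting is per replicate, then parameters are
averaged (mean ± SD). Because 1/k is convex, the mean of per-replicate
half-lives exceeds ln2/mean(k) whenever replicate rates differ (Jensen's
inequality); reports therefore carry both `t_half_mean` and
`t_half_of_mean_k`. A pooled fit (all replicates in one regression) is
available through the model classes and the CLI's `--pooled` flag.

## Colorimetry

Absorbance spectra A(λ) on 380–780 nm are converted to transmittance
T = 10^(−A), resampled linearly to a 5 nm grid, and integrated
(rectangular rule) against the CIE 1931 2° colour-matching functions
weighted by standard illuminant C — the viewing conditions stated for the
study's measurements; both tables ship as packaged CSVs and reproduce
illuminant C's chromaticity (x, y) = (0.31006, 0.31616) exactly.
Tristimulus values are normalised so a perfect transmitter maps to the
white point, then converted to CIELAB with the standard piecewise
cube-root (ε = 216/24389, κ = 24389/27). Chroma and hue angle are derived;
the achromatic point has undefined hue, reported as 0° with a flag.

Colour differences use the full CIEDE2000 formula (G chroma rescaling,
primed hue-difference and hue-averaging rules, S_L/S_C/S_H weighting, T
term, R_T blue-region rotation) with k_L = k_C = k_H = 1. The
implementation matches the published 34-pair verification dataset to
≤ 1e-4 and an independent implementation (scikit-image) to the same
tolerance on random pairs.

Scalar spectral operations: turbidity correction A(522) − A(750) for the
concentration channel (the 750 nm reading estimates residual scattering; a
negative result is returned with a warning, flagging a scattering
artifact); the correction is not applied to the full-spectrum Lab route,
which consumes clarified spectra. Peak location `lambda_max` refines the
grid argmax with a least-squares parabola over ±10 nm — on broad bands the
top is flatter than realistic noise, so a three-point parabola would
jitter by several nm, while the windowed fit is stable and exact for
symmetric bands. Peak shifts are classified bathochromic/hypsochromic by
sign; relative intensity changes are reported with the **larger** peak
absorbance as denominator (1.0 → 1.25 is +20%), symmetrically in both
directions.

## Calibration and conversions

External calibration is an OLS line signal = a + b·conc (statsmodels),
optionally through the origin; inverse prediction (signal − a)/b flags
extrapolation outside the calibrated span and returns negative
concentrations as computed. Conversions are exact stoichiometry:
% w/w → mM via grams-per-litre and molar mass (0.1% w/w at
288.38 g mol⁻¹ → 3.47 mM), and stock-dose dilution assuming extract
density 1 g mL⁻¹ (0.79 mM stock dosed at 0.73 g L⁻¹ → 0.58 µM) — the
unit-density assumption is the only one under which the study's own
arithmetic closes.

## Synthetic data

The generator draws what the fitting stage assumes: model curves evaluated
on the storage grid (0, 1, 3, 5, 7, 10, 14, 17, 21 days) plus i.i.d.
Gaussian noise truncated at zero (default SD 5% of each curve's dynamic
range), with a lognormal unit-mean preparation effect on k (default CV
10%) across `n_prep = 2` preparations × `n_meas = 2` measurements. All
randomness flows from one `numpy.random.default_rng` seed.

Presets encode the study conditions. Pigment decay uses k = 1.44, 0.30,
0.06, 0.09 day⁻¹ at pH 2, 3, 4, 6 with C₀ = 24 µM. Each oxidation preset
(product × pH × extract dose) uses the published rate constant and
induction time; its c0 is back-calculated as c0 = cmax/(1 + e^(2 + k·t_ind))
so that fitting the preset reproduces the published induction behaviour,
and conditions reported without an induction phase use the measured day-0
level (67 µM) directly. Plateaus are published values where printed
(e.g. 2172/986 µM hydroperoxides at pH 3 without/with extract, 3270 µM
propanal, 1241 µM hexanal) and otherwise set once to magnitudes consistent
with the described low-oxidation conditions (≤ 40–86 µM at pH 4–6).

Spectra are single Gaussian bands on a 1 nm grid whose centre moves
522 → 524 → 528 → 546 nm and whose amplitude falls 1.0 → 0.8 → 0.51 → 0.41
across pH 2 → 6 (piecewise-linear between anchors), broadening toward high
pH (σ = 45 + 7.5·(pH−2) nm); the surfactant option applies the
+8/+6/+2/−6 nm centre shifts and amplitude changes, and storage attenuates
the band by the pH's decay constant. Real extract spectra have asymmetric,
multi-component bands, co-pigmentation shoulders and instrument bandpass
effects that the generator does not emulate — passing tests demonstrate
correctness of the pipeline's arithmetic and estimator behaviour under the
assumed noise model, not instrument-level fidelity.

## Statistics and reporting

Condition comparisons use one-way ANOVA with Tukey's HSD at α = 0.05 on
per-replicate fitted parameters (matching the table structure of replicate
studies), condensed to a compact letter display by greedy
insert-and-absorb; letters are assigned in order of descending mean and the
partition is invariant under group relabeling. With zero within-group
variance everywhere, groups differ exactly when their means differ. The
pipeline simulates all 28 study conditions, fits per replicate, aggregates,
letters within each analyte × parameter, converts day-0/day-7 spectra to
Lab and ΔE₀₀ (day pair configurable), tabulates surfactant spectral
shifts, and writes CSV tables plus a JSON run log with the seed and config
hash. Identical config + seed yields byte-identical tables.

## Numerical choices and limitations

* Optimiser tolerances 1e-10 (ftol) to 1e-14; noiseless data are recovered
  to ≤ 1e-6 relative.
* Recovery accuracy is design-limited, not implementation-limited: with a
  plateau of 1000 µM, noise of 25 µM and a fitted initial level of 5 µM,
  the initial level is weakly identified in any single realization (its
  global least-squares estimate scatters more than ±15%), while the rate
  and plateau are tightly recovered; seed-averaged estimates are unbiased
  to a few percent. Problem sizes in the tests (25–200 seeds, 10 timepoints
  × 4 replicates) were chosen to characterise this behaviour compactly.
* The 5 nm colorimetric grid with linear resampling follows standard
  practice; no instrument bandpass correction is applied.
* Induction times within numerical tolerance of zero are reported as
  absent rather than as 0 days, matching the convention that a tangent
  intercept at or left of the origin carries no induction information.
* Mechanistic coupling between pigment decay and oxidation (shared radical
  chemistry) is deliberately not modelled; the generator reproduces the
  observed correlation only through its per-pH parameter sets.
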