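# Methods

## Binding models

**Ligand-depletion model (MST).** MST measures binding on the target side:
the response (normalized fluorescence or raw initial counts) interpolates
between an unbound and a bound signal with the occupied fraction of
target. Because the melanin nanoparticle concentration in the assay
(12.5 µM molar; 0.5 mg/mL at an estimated 40 kDa per particle) is not
small relative to the dissociation constants of interest, occupancy is
the exact root of the single-site mass balance,

    f = [(c + ct + Kd) − sqrt((c + ct + Kd)² − 4·c·ct)] / (2·ct),

not the trace-ligand hyperbola c/(c+Kd). The two agree in the limit
ct → 0 (verified to <10⁻⁴ relative error at ct = 10⁻⁶·Kd). The
discriminant is non-negative for all admissible inputs; a defensive clamp
with a warning guards against floating-point excursions. All
concentrations are µM internally; the mass↔molar melanin conversion
(mg/mL ÷ kDa × 1000) lives at the I/O boundary.

**Sips isotherm (traditional assay).** Bound amount per mg melanin:
B(L) = Bmax·Lⁿ/(Kdⁿ+Lⁿ), with B(0) ≡ 0 special-cased so 0ⁿ never
arises. n is constrained to (0, 1.5]: the heterogeneity index of a real
adsorbent is ≤ 1 in theory, but the fit is allowed modest overshoot so
that Langmuir-like data (n = 1) does not sit on a bound; reference-panel
values span 0.605–0.95.

## MST trace processing

A trace is ~30 s of fluorescence sampled at 0.25 s, with the infrared
laser switched on at 5 s. The cold window is the full pre-laser span;
Fnorm = mean(hot)/mean(cold).

**Hot-region selection.** Candidate hot windows of 1 s width slide in
0.5 s steps over the post-laser span. Per window, signal = span of
per-concentration mean Fnorm across the dilution series; noise = mean
within-replicate standard deviation of Fnorm (for singleton capillaries,
a residual-based estimate combining linearly detrended scatter in both
windows). The **maximum-SNR window** is selected, and flagged if it fails
the >5 acceptance threshold. An earliest-qualifying rule was considered
for cross-compound comparability but rejected: the thermophoretic
amplitude keeps developing for several time constants after laser-on, so
windows that merely clear SNR 5 early in the trace carry a systematically
flattened dose-response and inflate fitted Kd by tens of percent; the
max-SNR rule removes that bias while keeping the threshold as a QC flag.

**Mode selection.** When the pre-laser raw counts depend on ligand
concentration (the ligand quenches or enhances target fluorescence), the
initial-fluorescence readout replaces Fnorm. The switch requires both
Spearman |ρ| > 0.7 between cold counts and log concentration and a
relative span > 10% — two gates so that drift or jitter alone never
changes mode.

**Kd fitting.** Nonlinear least squares of the depletion model against
the per-capillary responses, free parameters {unbound signal, bound
signal, Kd}, target concentration fixed. Replicate series are pooled into
one residual vector rather than averaged, so the reported 68% confidence
half-width (1σ from the asymptotic covariance, the convention of the
instrument software this mirrors) reflects the full error structure.
Initialization: Kd at the geometric mean of tested concentrations,
signals from the low/high-concentration response means; Kd bounded to
[10⁻³, 10⁶] µM. Failures are results, not exceptions: `no_binding` when
the fitted amplitude is within 3 residual SDs of flat, `kd_at_bound`,
`wide_ci` when the half-width exceeds the estimate, `low_snr` when no
window reached threshold.

**Identifiability.** Under the screening design (16-step twofold series
from 500 µM, ct = 12.5 µM, 3% trace noise, 3 replicates) the Cramér–Rao
bound for Kd is ~12% relative SE at Kd = 30 µM but ~28% at 1 µM (strong
depletion: ct ≫ Kd) and ~93% at 1000 µM (Kd twice the highest tested
concentration). Recovery simulations match these scales: median |error|
6–13% for Kd in 1–100 µM, with estimates above the tested range honestly
reported through `wide_ci` (the panel's weakest binder, fitted at
3500 ± 13000 µM, is the archetype). No estimator can beat these bounds;
tests assert accuracy only where the design carries the information.

## Equilibrium assay analysis

Bound amount from supernatants: B = (total − free)/c_mel, units
µM/(mg/mL) = nmol/mg, with total taken from melanin-free control
supernatants. Negative B values (noise at weak binding) are retained —
truncation at zero biases Bmax upward.

**Weighting.** The default error model is constant-CV: per-sample σ
proportional to the control total concentration, reflecting
chromatographic quantitation whose error is relative, not absolute.
Unweighted OLS and empirical replicate-variance weighting are options;
with 5% multiplicative noise and the 0.25–250 µM design, the constant-CV
model gives ~92% two-SE coverage for Kd versus ~60% for OLS (the top
concentrations otherwise dominate the objective with underweighted
noise). Free concentrations are treated as exact (the conventional
choice); the resulting errors-in-variables effect makes nominal SEs on n
slightly optimistic at low noise.

**No-binding verdict.** Returned instead of parameters when bound amounts
are statistically indistinguishable from zero (one-sample t < 2), when
the optimizer fails, or when Bmax/Kd escape toward their bounds (no
saturation within the tested range) — mirroring how non-binders in the
reference panel are reported.

## In vivo prediction and classification

The unbound fraction at melanin concentration c_mel and total drug T
solves T = L + c_mel·B(L); the left side is strictly increasing, so the
root is unique and found by Brent's bracketed method on
[10⁻¹²·T, T] (rtol 10⁻¹²) — bracketed bisection-family convergence is
guaranteed, and Brent is simply faster than plain bisection. Defaults:
in vivo melanin 34.8 mg/mL (human RPE-choroid average across eye colors),
total 1 µM for the Sips route, 0.3 µM for the dilution route (the assay
concentration behind the literature unbound fractions).

The dilution route rescales a measured unbound fraction by the melanin
ratio D via fu' = 100/(D·(100/fu − 1) + 1), exact for linear binding;
cassette-assay values are first divided by 2.1 (empirical single- vs
cassette-incubation ratio for high binders). Literature values measured
at 3.6 mg/mL are first rescaled to the 1 mg/mL reference, then to in
vivo.

Class boundaries (Kd 6.5/65/650 µM; fu 0.1/1/10%) are half-open with the
boundary value assigned to the weaker-binding class, since the published
tier labels overlap at the cut points without a tie rule.

## Cross-method statistics

Comparable quantities: target capacity / Kd (MST; capacity = 12.5 µM
molar melanin) versus Bmax·c_mel / Kdⁿ (Sips, at the MST assay's
0.5 mg/mL), compared by Spearman rank correlation over the seven
compounds with parameters from both methods. The p-value is an exact
permutation probability for n ≤ 9 (t-approximation above). The Kd–fu
relation is an unweighted through-origin regression (slope = Σxy/Σx²);
log-space regression exists as an option but the reported slope is a
linear-space quantity. The regression runs on the panel's reported
per-compound in vivo fractions (11 compounds with both a Kd and a
prediction; the set is recorded in the output). Class limits are the
slope, rounded to its reported two significant figures, times the fu
breaks {10, 1, 0.1}%.

## Synthetic data generator

MST traces: baseline counts (optionally depressed by occupancy ×
`cold_trend_amplitude`, which exercises the initial-fluorescence path),
then a single-exponential thermophoretic depletion with time constant
3 s whose amplitude is `depletion_amplitude` × occupancy. Noise is
multiplicative log-normal parametrized by CV and mean-preserving —
fluorescence and LC-measured concentrations are positive and
CV-dominated; an additive option exists. Equilibrium data: free
concentrations are exact mass-balance roots at the true (Kd, Bmax, n);
controls are the totals; both noised. Defaults mirror the screening
protocol: 16-step twofold series from 500 µM, 12.5 µM target, 3
biological replicates, 3% CV, 30 s traces, laser-on at 5 s. All
randomness flows from the single config seed; identical configs are
bit-identical.

What the generator does **not** emulate: temperature-jump vs
thermophoresis phase structure, convection, capillary scan artifacts,
aggregation, LC calibration nonlinearity, or inter-day variability.
Passing recovery tests therefore validate the estimators under the
stated noise model, not instrument-specific systematics.

## Known limitations and irreproducible digits

Two cells of the reference panel's printed in vivo table cannot be
recovered exactly from the printed inputs, both from input rounding:
the weakest binder's dilution-route value (printed in vitro 98% gives
58.5%, printed in vivo 54%), and levofloxacin's mass-balance value
(printed parameters give 0.345%; n anywhere within the printed-rounding
band 0.725–0.735 spans 0.32–0.38%, covering the printed 0.33). Both are
documented where tested rather than silently corrected. The
through-origin slope recomputed from reported values is 64.7 (reported
as 65); recomputing it from freshly solved fractions instead gives ~60,
driven entirely by the 54%→58.5% cell.
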