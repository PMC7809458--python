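# Methods

## Scope and data model

The package operates on three CSV table kinds: intra-tooth enamel δ18O
(`tooth_id, layer_id, position_mm, d18O[, replicate_sd, taxon,
tooth_position]`), enamel 87Sr/86Sr (`tooth_id, sr_ratio[, position_mm]`),
and bone-collagen δ13C/δ15N with elemental QC fields.  Unknown extra
columns are preserved.  Rows violating record invariants (non-finite
deltas, negative positions, Sr outside the 0.70–0.74 plausibility window)
are rejected with row-level diagnostics rather than aborting the load.

Positions are distances along the growth axis from the enamel–root
junction, increasing toward the occlusal surface (earlier-formed enamel at
larger positions).  Published tables measured from the occlusal surface
load with `flip_positions=True`.  Duplicate `(tooth_id, position_mm)` rows
are treated as replicate drillings of one strip and averaged with a
warning.  Raw instrument deltas can be placed on the VSMOW scale with the
two-point normalization utility, the unique affine map sending two
measured standard values onto their accepted values.

## Seasonal sinusoid

Each series of n ≥ 5 samples is fitted with δ(x) = M + A·sin(2πx/λ + φ)
by nonlinear least squares.  For fixed λ the model is linear in
(M, A·cosφ, A·sinφ), so initialization scans a geometric grid of 120
wavelengths between 0.5× and 4× the sampled span, solves each exactly, and
the best candidate seeds a joint refinement (trust-region least squares,
λ bounded within [0.125×, 4×] of the span).  This makes the fit
deterministic and robust without user-supplied starting values;
`init={"wavelength": λ}` fixes λ when the annual crown length is known.

Classification: a series is non-sinusoidal when the optimizer fails, the
series is constant, or the fitted curve's amplitude is below k·σ_resid
(default k = 2) — the reproducible analogue of asking whether a clear
seasonal cycle is visible.  The amplitude used is the *within-span*
amplitude (half the fitted curve's peak-to-peak inside the sampled range):
for flat noisy series the unconstrained fit can place a very long
wavelength through the data, giving a large extrapolated A while the curve
barely moves inside the span, and the within-span measure rejects exactly
those fits.  For any series covering a full cycle the two amplitudes
coincide.

## Extreme extraction

The traditional workflow reads summer peaks and winter troughs off the
plotted curves by eye.  Two reproducible methods replace that:

* `fitted` — the model extrema M ± A, reported only when the fitted curve
  attains the extremum inside the sampled span (with a tolerance of λ/8
  beyond each end, since an extremum just off the outermost sample is
  still constrained by the data);
* `observed` (default) — the most extreme measured sample within λ/4 of a
  fitted extremum position, reflecting that visual picking tracks measured
  extreme samples.

Series covering only one extremum yield `peak_only`/`trough_only`
estimates with no fabricated values; mean-annual δ18O — the average of
peak and trough, analogous to forming a modern mean annual temperature
from monthly extremes — exists only when both are present.  Series
spanning more than ~1.5 cycles contribute their single most extreme peak
and trough, one summer and one winter value per tooth.

Accuracy trade-off: `fitted` extremes average out analytical noise (on
simulated cohorts they sit within ±0.3‰ of the dense noise-free signal),
while `observed` extremes carry one sample's analytical noise (±3·σ
worst-case at σ = 0.2‰).  `observed` remains the default because it is the
closer analogue of the visual procedure; for temperature work the two
agree to well under the compound error.

## Damping correction

Enamel maturation (a stretch of length L_m maturing simultaneously) and
the drilled strip height L_s each act as uniform moving averages along the
growth axis, attenuating a seasonal amplitude of wavelength λ by
f = |sinc(L_m/λ)|·|sinc(L_s/λ)|.  The measured amplitude is divided by f;
the mean-annual value is invariant.  Both window lengths are
config-required — they are taxon- and study-specific physiological and
sampling constants, and a silent default would masquerade as ground truth.
The example configuration uses L_m = 6 mm and L_s = 1.5 mm (a typical
drill-strip height; f ≈ 0.93 at λ = 30 mm).  The factor computation sits
behind one function so a different published attenuation geometry (e.g.
appositional-angle terms) can be substituted without touching the
correction.  Corrections are refused when f < 0.3 (default floor):
dividing by a small f amplifies noise without bound, and with the combined
window at or past one wavelength the response crosses its first zero and
the inverse is meaningless.  The within-pipeline λ used for the damping
model is the median fitted wavelength across analyzed teeth; per-tooth
models are used by the `reconstruct` subcommand.

## Transfer functions and compound error

Two affine stages convert corrected extremes to temperature: δw = a1·δp +
b1 (enamel phosphate → drinking water) and T = a2·δw + b2 (drinking water
≈ precipitation → air temperature).  Stage-1 calibrations published in the
opposite direction are inverted exactly on load; their quoted coefficient
uncertainties are rescaled first-order onto the inverted parameters (an
exact inversion of a coefficient *distribution* does not exist).  By
default the single annual-scale stage-2 regression is applied to both
seasonal extremes; separate warm/cold-season regressions can be supplied.
Because both stages are affine, MAT computed from the mean-annual δ equals
the mean of the two seasonal temperatures exactly, and layer-mean
temperatures equal the temperatures of layer-mean δ values; the pipeline
maps per tooth and then averages by layer.

Compound error is estimated by Monte Carlo (default n = 10 000 draws,
seeded): each draw perturbs the input δ18O by its measurement/fit sd,
draws (slope, intercept) of each stage from a bivariate normal with their
standard errors and stated covariance, and adds each stage's residual
standard error.  The reported half-width is the MC standard deviation
(`coverage="sd"`, the error-bar convention) or half the central 95%
interval (`coverage="ci95"`).  For a pure affine map with only input noise
σ the MC sd converges to |a1·a2|·σ, which the tests use as the analytic
oracle.  Draw counts below 1000 are refused.

## Inter-layer statistics

Group summaries, one-way fixed-effects ANOVA, Levene's equality-of-variance
test (mean-centred by default), Tukey HSD (studentized range;
Tukey–Kramer for unbalanced groups) and a qqnorm-style normality
diagnostic with a Shapiro–Wilk companion p (advisory only) are computed
per season, with layers ordered stratigraphically (1, 2, 3, 4, 5A, 5B).
Cohen's d uses the pooled sd with (n−1) weights and no small-sample
correction, with the contrast ordered earlier layer minus later layer so
that a rise in winter δ18O through time prints as a negative d.  The
winter-δ18O–collagen-δ13C correlation pairs each collagen specimen with
its layer's mean winter δ18O by default (`per_specimen`); `per_layer`
collapses to one pair per layer.  No multiple-testing correction is
applied beyond Tukey's own adjustment.

## Provenance screening

A tooth is classified local when all its 87Sr/86Sr measurements fall
within the bioavailable baseline mean ± 3 sd (k configurable); the
baseline (e.g. modern plants near the site) is user-supplied.  Intra-tooth
Sr ranges exceeding 3× the analytical sd are flagged as seasonally
heterogeneous (possible migration).  Collagen is screened on the standard
atomic C:N integrity window 2.9–3.6 (configurable); specimens without C:N
pass with a logged warning.  Layer trends report per-layer δ13C/δ15N mean
and sd, with sd absent (not zero) for single-specimen layers.

## Synthetic data generator

The generator inverts the inference chain as a forward model.  Per tooth:
layer-level true warmest/coldest-month temperatures (plus per-tooth
Gaussian spread) → drinking-water δ18O via the inverse stage-2 map →
enamel δ18O sinusoid via the inverse stage-1 map, with uniform random
phase (birth season is not modelled); the dense noise-free signal is
convolved with both averaging windows, sampled at near-regular positions
(±15% spacing jitter) and given Gaussian analytical noise (default 0.2‰,
the typical replicate reproducibility of phosphate measurements).  Sr
values are drawn around a local mean (0.7104 ± 0.0002), with planted
migratory teeth alternating ±0.0035 excursions; collagen δ13C/δ15N are
drawn per layer.  A truth table records every per-tooth parameter.

The paper-like default scenario mirrors the targeted study design: layers
2/5A/5B with 5+4+4 teeth, 14 samples per tooth over 1.2 annual cycles of a
30 mm wavelength (~180 samples), one planted non-sinusoidal tooth, winter
temperatures markedly colder and more variable in the oldest layer
(0.5 ± 1.5 °C vs 4.5 and 3.5 ± 0.8 °C), near-identical summers
(21/21/20 °C), and collagen δ13C higher in the cold layer.  These defaults
produce a strongly negative winter effect size between the oldest and
middle layers and a substantial negative winter-δ18O/δ13C correlation.

What the generator does not emulate: body-water turnover and diet–water
mixing physiology, growth-rate changes along the crown (λ is constant per
tooth), aridity or atmospheric-circulation effects on the
precipitation–temperature relation, and measurement drift.  Passing
recovery tests therefore demonstrates correctness of the inference chain
under its own assumptions, not the field accuracy of any particular
calibration.

## Numerical choices and limitations

* Sinusoid fitting tolerances are tight (xtol/ftol/gtol = 1e−14); the
  wavelength grid is geometric with 120 points.  Constant series short of
  positional spread or with fewer than 5 points raise typed errors.
* Forward convolution requires ≥ 50 samples per cycle and a regular grid;
  simulation uses λ/400.  Reflect-padding keeps interior amplitudes
  unbiased; oracle comparisons measure amplitude on the interior.
* The acceptance script runs 20 simulated cohorts of 13 teeth for the
  recovery medians and 20 000 Monte-Carlo draws for the error comparison;
  these sizes give stable medians while keeping a full run in seconds.
* Tukey p-values are clipped to [0, 1]; identical groups give p = 1 within
  numerical tolerance.
* Temperature estimates require both extremes; partial series propagate
  through δ18O-level outputs only.
* The pipeline's per-run seed fixes the Monte-Carlo draws; the simulator
  is deterministic per scenario seed (byte-identical tables).
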