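# Methods

## Data model and cleaning

Input is a long (tidy) table, one row per well reading: sample metadata
(`sample_id`, `reactor_id`, `treatment`, `day`, `matrix`), `substrate`
(catalog name or the reserved token `BLANK`), `replicate` (1–3), `time_h`
and `od590`. A 750-nm channel is accepted and stored but never used: all
analysis runs on the 590-nm dye signal. The substrate catalog is closed —
31 substrates partitioned into amines (2), amino acids (6), carbohydrates
(10), carboxylic acids (9) and polymers (4); an unknown substrate name is
a hard error with near-match suggestions, never a silently dropped row.
Note that this partition places the phosphorylated sugars
(glucose-1-phosphate, glycerol phosphate) among the carbohydrates; other
published EcoPlate groupings differ, and the guild sums depend on the
choice, so the catalog is an explicit, replaceable object.

Cleaning is a fixed sequence: per-sample blank mean subtracted at each
read time (blanks are never interpolated — a missing blank is an error),
negatives clipped to exactly 0, then technical replicates averaged.
Clipping before averaging is deliberately order-sensitive (a replicate set
{−0.3, 0.1, 0.2} averages to 0.1 clipped-first but 0.0 averaged-first);
`clean_plate(clip_before_average=False)` exposes the alternative order for
sensitivity checks only.

Imputation: when a treatment × day cell of solid samples misses exactly
one of its reactors and at least two donors are present, a synthetic
sample is appended whose OD at each (substrate, time) is the donors' mean,
flagged `imputed=True`; the flag propagates through every downstream
table, imputed samples are excluded from the fit-success bookkeeping, and
leachate samples are never imputed. Imputation acts on raw-level curve
values, not on derived integrals.

## Kinetics

Each curve is interpolated with a natural cubic spline (`pchip` available
as a shape-preserving option) onto `grid_points = 100` uniform nodes over
`[0, horizon_h = 96]` h. A `(0, 0)` anchor is prepended because the first
read is at 24 h and the dye signal is taken as zero at inoculation; reads
beyond 96 h (the 144-h read) shape the spline but the grid is cut at the
horizon; negative interpolated excursions are clipped to 0. The anchor is
a modeling convention, not a measurement, and it biases the activity
integral slightly downward (see Limitations).

The Gompertz model is fitted to the interpolated grid by trust-region
least squares started from a geometric heuristic (amplitude = grid
maximum; slope = steepest finite difference; lag = t-intercept of the
tangent at the steepest node, clamped to ≥ 0 for the start only). `A` and
`μ` are kept positive; `λ` is unbounded, so a curve already rising at the
origin drives the lag negative. One restart from a ×1.5-perturbed start is
attempted on failure. The option `fit_target="cumulative"` instead matches
the model's running integral to the spline's — off by default; fitting the
OD grid is the behavior of the standard growth-curve packages this stage
mirrors.

Outcome rules: `gompertz` (converged, `λ ≥ 0`) integrates the fitted
model; `spline_fallback` (`λ < 0`, or optimizer failure — a fit that does
not exist cannot be integrated) integrates the spline; `zero` (grid
identically 0) has AUC exactly 0. Both branches use the composite
trapezoid on the same 100-point grid, which is why spline and Gompertz
integrals of successful fits correlate ≥ 0.999: the fit is constructed on
that very grid. On noiseless curves evaluated directly on the grid,
parameter recovery is < 1% and the trapezoid AUC agrees with adaptive
quadrature of the closed form to < 0.5% (both are asserted in the tests).

## Profiling and normalization

Guild activity is the plain sum of member-substrate AUCs (a missing
substrate is an error, since a silent zero would bias the sum). Temporal
display uses per-reactor scaling to the day-0 value, so every series
starts at 1; a zero baseline yields missing scaled values with a warning
rather than infinities. Min–max normalization maps each variable onto
[0, 1] over the modeling cohort; it is affine-invariant and fails loudly
on constant variables. Summary errors are conventional standard errors
(sd/√n); with the default design, pooling by day gives n = 9 at day 0 and
n = 6 on days 57–358, while splitting by treatment at day 763 gives n = 3.

## Biodegradability regression and comparisons

The regression cohort is the solid samples (36 in the default design, one
of them imputed): RI₄ is a solid-matrix measurement, and activities are
merged with RI₄ records on (reactor, day, matrix) so the imputed plate
sample pairs with its independently measured respiration index. Both
covariates and the response are min–max normalized before the OLS fit —
with an intercept of ~0.26 on [0, 1] covariates this is the only
dimensionally coherent reading; `normalize_response=False` is exposed for
sensitivity. Note a structural consequence: normalizing the response
rescales all coefficients by the reciprocal of the realized range of the
noiseless normalized response, so even a noise-free cohort reproduces the
generative coefficients only up to that factor (the tests therefore
compare the pipeline fit against the same regression run on ground-truth
covariates, and check the generative coefficients exactly on the ground
truth itself).

Comparisons follow the standard small-sample toolkit: Levene
(median-centered) and Shapiro prechecks, one-way ANOVA + Tukey HSD between
the three treatments at the final campaign with a compact letter display
(groups sharing a letter are not distinguishable at α = 0.05), and
two-sided rank-sum tests between solid and leachate samples per day ×
guild, exact for small n, with `***`/`**`/`*` at 0.001/0.01/0.05. No
multiplicity correction is applied beyond Tukey's family-wise control.

## Synthetic generator

The generator reproduces the design exactly: reactors 1–3 aerobic, 4–6
mixed, 7–9 anaerobic; solids and leachate sampled on days 0/57/114/358/763
with the anaerobic reactors sealed in between (9 + 6 + 6 + 6 + 9 = 36
samples per matrix); reads at 24/48/72/96/144 h; 31 substrates + blank in
triplicate; the mixed day-763 solid sample of reactor 5 withheld to
exercise imputation. Every well shares a plate background offset
(0.05 OD); substrate wells add a Gompertz signal and all readings receive
additive Gaussian noise (default sd 0.01 OD), clipped at 0. Blank
subtraction cancels the shared background exactly, which is what makes
noise-free runs exactly recoverable.

Well classes: `zero` (never colors), `normal` (λ ~ N(12, 3²) h clipped to
≥ 4 h, μ ≈ 0.06·A h⁻¹), and `negative_lag` — slow growth already in
progress at the first read (μ/A ∈ [0.0085, 0.0115] h⁻¹, λ uniform on
[−18, −8] h). The last shape is chosen deliberately: a *fast* curve with
negative lag has plateaued by 24 h and fits with a short positive lag,
whereas in-progress slow growth robustly drives the fitted lag below zero
(fitted λ lands in [−4, −1] across the parameter box). Default class
fractions are 0.11 zero and 0.14 negative-lag, putting the success rate in
the region observed in this kind of campaign (~75–85% depending on noise);
guild trajectories follow the qualitative field pattern (carbohydrates
decaying to ~3% of baseline by the end, amines rising ~5-fold and polymers
~3-fold to a day-114 peak, moderate changes elsewhere), with a
treatment effect only at day 763 (anaerobic × 1.5, aerobic × 0.75) because
earlier campaigns sample identical conditions. Magnitudes are free
parameters, not claims about any particular dataset.

RI₄ is generated as `offset + span · (0.26 + 0.68·C_norm − 0.5·P_norm +
ε)` with `ε ~ N(0, 0.20²)` on the normalized scale (offset 1.5, span
7 mg O₂ kg⁻¹ DW, giving values from ~8 early to ~1–3 late); the noise sd
is fixed so the regression attains an adjusted R² around 0.7 at n = 36.
At `σ = 0` the generated RI₄ is an exact affine function of the true
normalized activities.

What the generator does **not** emulate: replicate-level systematic
effects (pipetting gradients, edge evaporation), dye saturation and
late-time signal decline, non-Gaussian heteroscedastic noise, between-well
correlation within a plate, and real community dynamics. Passing tests
therefore demonstrate that the pipeline's algebra, fitting rules and
bookkeeping are correct under the stated generative assumptions — not that
the Gompertz model is adequate for any particular real plate.

## Numerical choices and problem sizes

Trapezoid integration on the shared 100-point grid for both AUC branches;
`least_squares` (trf) with up to 400 function evaluations and one
restart; spline fallback to linear interpolation below 3 points; ties in
the rank-sum test handled by scipy's automatic exact/asymptotic policy.
The test suite runs the full default experiment once (2 232 curves) and a
noise-free replicate once, plus simulation studies at 200–1000 replicates;
everything completes in about a minute on one CPU, and the acceptance
script in about half a minute.

## Limitations

- The `(0, 0)` anchor plus sparse reads (first at 24 h) make the spline —
  and hence every AUC — a systematic slight underestimate of the true
  signal (~4–6% on noiseless synthetic wells); per-well `μ` and `λ` are
  only coarsely identified from five reads, although `A` and the AUC are
  stable. Campaigns wanting kinetic parameters per se should read earlier
  and more often.
- The zero outcome requires an exactly-zero curve; under measurement noise
  an inactive well is instead fitted like any other curve and lands in
  either remaining class depending on the noise realization. This mirrors
  practice, where fallback wells concentrate among low-activity curves.
- Min–max normalization ties every coefficient to the cohort's extremes;
  coefficients from different cohorts are not directly comparable.
- The anaerobic treatment is observable only at days 0 and 763 by design,
  so its comparisons ride on n = 3 endpoint cells.
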