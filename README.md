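# clppkit

Kinetic community-level physiological profiling (CLPP) of Biolog®
EcoPlate™ optical-density time series, for studies that link the carbon
source utilization capability of a microbial community to the
biodegradability of the material it lives in — typically landfilled
municipal solid waste monitored under different aeration regimes.

An EcoPlate carries 31 carbon sources plus a water blank, each in
triplicate; microbial respiration reduces a tetrazolium dye and the color
is read as OD at 590 nm over several days. Instead of endpoint summaries
such as average well color development (which needs a time-zero read),
clppkit quantifies each well kinetically:

1. **Cleaning** — subtract the per-sample blank mean at each read time,
   clip negative values to 0, average the technical replicates; one missing
   solid sample per treatment cell may be imputed as the element-wise mean
   of its sister reactors.
2. **Kinetics** — interpolate each curve with a cubic spline onto a
   100-point grid over 0–96 h (anchored at `(0 h, 0 OD)`; later reads
   support the spline) and fit the Zwietering-form Gompertz model

   `y(t) = A · exp(−exp((μe/A)(λ − t) + 1))`

   with asymptote `A` (OD), maximum slope `μ` (OD h⁻¹) and lag `λ` (h).
   The per-substrate activity statistic is the area under the curve on
   [0, 96] h: the fitted Gompertz when the fit converges with `λ ≥ 0`, the
   spline itself when `λ < 0` or the fit fails, and exactly 0 for a well
   that never colored. A success table accounts for the outcome per
   treatment × sampling day.
3. **Profiling** — sum substrate AUCs into five guilds (amines, amino
   acids, carbohydrates, carboxylic acids, polymers), scale each reactor's
   guild series to its own day-0 value, and min–max normalize variables:
   `x_norm = (x − min x)/(max x − min x)`.
4. **Inference** — ordinary least squares of the normalized 4-day
   respiration index (RI₄, mg O₂ kg⁻¹ DW, the standard biodegradability
   proxy) on the normalized carbohydrate and polymer activities,

   `RI₄ = β₀ + β_carb · Carbohydrates + β_poly · Polymers + ε`,

   plus the conventional comparisons: Levene/Shapiro prechecks, one-way
   ANOVA with Tukey HSD letters between treatments at the final campaign,
   and rank-sum tests (star-encoded) between solid and leachate samples.

A first-class synthetic generator (`clppkit.synthetic_data`) emulates the
full experimental design — nine reactors in three aeration treatments,
sampling days {0, 57, 114, 358, 763}, solid and leachate samples, reads at
{24, 48, 72, 96, 144} h, zero-activity and negative-lag well classes, one
withheld solid sample, and RI₄ generated linearly from the true normalized
guild activities — so every stage of the pipeline can be exercised and
scored against ground truth without any external data.

## Worked example

```
clppkit run --simulate --seed 1 --out results/
```

generates the default synthetic experiment (72 plates, 34 080 readings),
runs the full analysis in about 12 s and prints:

```
pipeline finished in 11.9 s; outputs in results/
Multilinear biodegradability model (normalized scales)
  RI4_norm = 0.3381 + 0.5385 * Carbohydrates + -0.3495 * Polymers
  n = 36, adjusted R^2 = 0.6827
  term          coef        se          p
  intercept        0.3381     0.0607   3.43e-06
  carbohydrates    0.5385      0.082   1.85e-07
  polymers        -0.3495      0.111    0.00335
```

The regression says: across the 36 solid samples, communities with a high
residual capability to respire carbohydrates sit in material that still
consumes much oxygen (high RI₄ — weakly stabilized waste), while a high
polymer-degradation capability marks material whose easy carbon is gone
(low RI₄ — aged, recalcitrant waste). `results/` also contains
`auc_per_substrate.csv` (per-well outcome, Gompertz parameters and AUC),
`group_activity.csv`, `scaled_activity.csv`, `normalized.csv`,
`success_table.csv` (e.g. `aerobic,0,80,93,86.0` — 80 of 93 curves in that
cell fitted with a non-negative lag), `comparisons.csv`, `ri4_model.txt`
and a `manifest.json` with content digests of every file.

The same stages are available as library functions (`read_plate_table`,
`clean_plate`, `fit_table`, `aggregate_groups`, `fit_ri4_model`, …) for
running on your own long-format plate tables; see the module docstrings
and `docs/methods.md`.

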