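# Methods

## Normalization model

**Tumor survival.** Each tumor focus contributes the ratio
r = BLI_end / F_day1 — end-point bioluminescence per unit of day-1
fluorescence, correcting for engrafted tumor size. Per dose,
s(d) = mean(r_treated at d) / mean(r_untreated). The estimator is
scale-invariant in the instrument units and deliberately **uncapped
above 1**: the growth-acceleration window needs the 125% / 150% survival
thresholds to be observable. Replicates aggregate by arithmetic mean
(screens report mean ± SEM); a median option exists for heavy-tailed
plates. Untreated controls carry dose 0, act only as the normalization
denominator, and never join the interpolation grid. Controls are pooled
per assay context (one control group per tumor per run); per-plate
control structure, if present, should be split into separate input files.

**Slice toxicity.** tox(d) = clamp((PI(d) − PI_healthy) /
(PI_dead − PI_healthy), 0, 1), anchored by the healthy-baseline and
dead-control slice populations of the same assay context. The lower clamp
treats PI below the healthy baseline as measurement noise rather than
negative death; inverted anchors (dead ≤ healthy) are a hard error.

## Curve metrics

All metrics operate on the measured piecewise-linear curve — no Hill/4PL
fit is ever used. The interpolation axis is log₁₀-dose for concentration
units (screens use log-spaced doses) and linear dose for radiation (Gy);
both are selectable per run. ECx is the **first upward crossing** of kill
through x/100 scanning low→high, ties broken toward the lower dose — a
conservative potency estimate for non-monotone curves. A curve whose
maximal kill never reaches x/100 is NR; a curve already at or above the
level at the lowest tested dose is flagged `below_range` and reported at
that dose. Nothing is extrapolated beyond the grid. The normalized AUC is
the trapezoidal area divided by the axis length, i.e. the mean response
over the tested range; kill AUCs can be negative under net growth. The
slope through EC50 is the slope of the piecewise-linear segment containing
the curve's own 50% crossing, in response units per axis unit (per decade
on the log axis); when the crossing does not exist the steepest segment
slope is used, and a flat curve has slope 0.

**Biphasic rule.** The screens describe biphasic killing verbally (rapid
kill at low doses, little further kill at high doses, residual tumor); the
operational rule here is: max kill over the lower half of the dose grid
≥ 0.25, additional kill beyond that ≤ 0.10, and > 10% tumor remaining at
the top dose. All three thresholds are configurable. A flat zero-kill
curve is not biphasic (no rapid low-dose killing), nor is a curve that
kills nearly everything.

## Window semantics

Windows 1–8 compare the tumor and slice arms; 9–11 judge the tumor curve
alone and are ternary. Two points were genuinely open and are this
package's design choices:

* **ECx windows.** At an in-range crossing d\*, tumor kill is x/100 by
  construction, so w = x/100 − tox(d\*). When the crossing precedes the
  grid (`below_range`), both responses are read at the lowest tested dose:
  w = k(d_min) − tox(d_min). This keeps the stated ±1 range attainable —
  a maximally potent non-toxic agent scores +1 at every level rather than
  x/100 — while matched tumor/tox curves still score exactly 0. When ECx
  is NR the window is w = k_max − x/100 − tox(d_max) (clamped): the
  shortfall from the target plus top-dose toxicity, so an agent that never
  reaches ECx cannot outscore one that does at equal toxicity. A stricter
  `worst` mode assigning −1 to every NR window is available and echoed in
  run metadata.
* **Slope window.** w = (m_T − m_O)/(|m_T| + |m_O|) bounds the comparison
  to ±1 regardless of units. When both measured slopes are zero the ratio
  is degenerate and the sign is decided by 50%-crossing status: a tumor
  sitting at/above 50% kill while toxicity never crosses is maximally
  favorable (+1), the reverse −1, two flat curves on the same side 0.
  This makes the perfect and worst-case agents score ±1 consistently
  across all eight comparative windows.

Toxicity measured on a different dose grid is interpolated onto the tumor
grid, in-range only; a tumor grid extending beyond the toxicity grid is an
error rather than an extrapolation.

## Aggregation

DSS = 100 × Σ wᵢ·windowᵢ with default weights (0.10, 0.05, 0.05, 0.10,
0.05, 0.05, 0.10, 0.35, 0.05, 0.05, 0.05) for (max kill, EC10, EC25,
EC50, EC75, EC90, slope, AUC, growth, biphasic, incomplete). Weights must
sum to 1 (validated to 1e−12); overrides are echoed into output metadata.
Scores are reported to 0 decimals in the matrix CSV, full precision
elsewhere. Drug × tumor matrices preserve untested pairs as missing cells;
the waterfall ordering sorts present scores descending with lexicographic
tie-breaks and carries a cohort tag.

## Batch quality control

Each slice batch contributes a random QC sample (six slices in screening
practice) run through the PI assay untreated. Each slice gets the same
healthy/dead death-index rescale used for toxicity; the batch passes when
the mean index is ≤ τ_abs (default 0.25) **and**, when at least two prior
batches exist, within κ (default 3) historical standard deviations of the
historical mean. The comparison-to-history procedure mirrors screening
practice; the numeric cutoffs are declared conventions of this tool,
configurable and echoed in every report.

## Synthetic assays and the analytic oracle

The generator emulates the screening design: 6 doses, 4 foci per dose,
log-spaced over 3 decades centered on the tumor EC50 (linear spacing for
Gy), with tumor survival following
s(d) = g·[f + (1 − f)/(1 + (d/EC50)^h)] — optional growth acceleration
g > 1 and an optional plateau cap producing biphasic shapes — and monotone
Hill toxicity. Replicate noise is multiplicative log-normal with mean-one
multipliers at a given CV (bioluminescence is positive and right-skewed);
raw measurements are back-constructed so normalization recovers the closed
form exactly at zero noise and in expectation otherwise. All randomness
flows from one seed; identical seeds reproduce byte-identical bundles.

The analytic oracle evaluates the same window definitions on a 10⁴-point
sampling of the closed-form curves, where the piecewise-linear metrics are
indistinguishable from the continuous curve. The one exception is the
slope window: a segment slope tends to the local derivative under grid
refinement, so its ground truth is evaluated at the design's own dose grid
(noiseless closed-form values). Measured on the scenario pack at 6 doses,
noiseless pipeline-vs-oracle disagreement is ≤ 0.012 per window
(≤ 0.004 on plain monotone scenarios; the worst case is an ECx window of
the growth-accelerated scenario, whose crossing falls in a high-curvature
0.6-decade segment) and ≤ 0.3 DSS points overall; under 10% replicate
noise the median DSS recovery error across 200 seeded screens is ≈ 2.3
points. What the simulation does **not** emulate: spatial growth and
invasion on the slice, plate-position effects, shared-control correlation
between drugs, and imaging saturation — so passing recovery tests
demonstrates correctness of the computation, not robustness to every
real-world artifact.

## Numerical choices and limitations

Dose grids must be strictly increasing and positive; log-axis
interpolation requires positive doses by construction. Exact threshold
touches on a flat segment report the segment's lowest dose. ECx equality
at the top dose counts as reached (NR is strict shortfall). The weight-sum
check uses an absolute tolerance of 1e−12. Problem sizes in the test suite
(200 simulated screens, 10⁴-point oracles) were chosen so the full suite
runs in seconds while keeping interpolation error far below the tolerances
tested. Known limitations: windows carry no confidence intervals (point
values only, as screens report); the biphasic rule is a threshold
heuristic on 6-dose grids and will mislabel curves whose plateau falls
entirely between grid points; published per-drug scores from screening
studies cannot be recomputed without their unpublished replicate-level
raw data, so correctness rests on the analytic constants and the
synthetic oracle.
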