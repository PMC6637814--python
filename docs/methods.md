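# Methods

## Problem setting

A frequent-sampling endocrine protocol measures five hormones — glucose
(mmol/L), insulin (mU/L), TSH (mU/L), cortisol (µmol/L) and GH (mU/L) —
from one serum tube drawn every 10 minutes for 24 hours, giving up to
144 × 5 = 720 values per participant. Time is stored as an integer sample
index with a step-in-minutes attribute (default 10); the clock anchor
(sampling starts ≈0900 h, lights off ≈2300–0800 h) is used only by the
simulator. Measurement errors come in two characteristic forms: isolated
spikes/drops affecting one value, and tube-level dilutions (saline flush,
clot) that depress all five hormones at one time point simultaneously.
Readings below an assay's lower detection limit are replaced by half the
limit at read time (the common assay-lab convention); detection limits are
configuration inputs, not constants.

## Smoothing and residuals

Insulin and GH are natural-log transformed before smoothing (their
distributions are strongly skewed); which hormones to transform is a
config list, not an automatic skewness test. The smooth is a centered
moving average (moving median available) of odd window *w*, default 5
points (50 min). Two decisions the window semantics forces:

- **Boundaries**: windows shrink at series ends (the first point averages
  itself and its two right neighbours). This keeps estimates at the edges
  at the cost of weaker smoothing there — curve-based detectors are
  intrinsically less reliable at series ends.
- **Missing values**: skipped within a window rather than invalidating it;
  a fitted value is missing only if the whole window is. Missing
  observations stay missing downstream — nothing is imputed.

Residuals are observed − smooth on the analysis scale. Standardization is
per participant per hormone over the full 24 h, with sample SD (n − 1).
A constant series has no residual scale; its z-residuals are reported as 0
and the series is flagged, never NaN. Series with fewer non-missing points
than the window get all-missing residuals and a warning.

## Tukey's fences

Quartiles use linear interpolation between order statistics (the common
"type 7" rule; configurable). Two fence conventions circulate — centered
on the median (Q2 ± k·IQR) or anchored on the quartiles (Q1 − k·IQR,
Q3 + k·IQR) — and both are implemented; the default is median-centered
with k = 3. Fences are computed on raw residuals (they are
scale-equivariant, so standardization is irrelevant) per participant per
hormone. Inequalities are strict: a point exactly on a fence is not
flagged. If IQR = 0 the fences collapse and any residual off the median is
flagged, with a warning.

## Stepwise approach

Defaults: z-cutoffs −3/+4, glucose floor 2.8 mmol/L, cross-sum threshold
−8, one iteration. All inequalities strict. Decisions in the gaps:

- The glucose floor flags only the glucose point, not the whole tube.
- In the cross-hormone sum, a missing hormone contributes 0 (not
  rescaled): the −8 threshold is calibrated to a five-hormone tube, and
  rescaling would change its meaning. Time points with an incomplete cross
  set are counted in a warning.
- The second pass repeats the refit and the cross rule only; the
  within-hormone cutoffs are reapplied only if `iterate_within` is set
  (off by default). Points flagged in pass 1 are treated as missing (not
  interpolated) during the refit, and standardization is recomputed on the
  reduced series.
- Final flags are the union of both passes; per-point provenance labels
  (within | glucose | cross | cross_pass2) are retained.

## EM mixture

The model: pooled standardized residuals follow a two-component univariate
normal mixture — narrow component ≈ true biological scatter around the
curve, wide component ≈ errors. Pooling is per hormone across all
participants; a single 144-point series is too short for a stable mixture.
The EM is explicit: E-step responsibilities, M-step weighted moment
updates, relative log-likelihood tolerance 1e-8, max 1000 iterations, SD
floor 1e-6. Initialization is deterministic ("quantile": narrow SD from
the 25th percentile of absolute centered residuals, wide from the 97.5th,
weight 0.9/0.1); degenerate fits (component collapsing onto a point)
restart from random draws up to 5 times. Components are relabeled by SD so
the wide one is always the outlier component; means are free parameters by
default, with a `fix_means_zero` mode pinning both on the fitted curve.
If the fitted SDs differ by less than 1.5×, a warning notes that the data
do not support two distinguishable components. P(outlier) is the wide
component's posterior; classification uses P > 0.9, and probability
weighting downstream uses w = 1 − P(outlier) — weighting *by* the outlier
probability would up-weight the errors.

## Simulator

The generator emulates the study conditions rather than any particular
dataset: per hormone, concentration(t) = baseline × (1 + a·cos(2π(clock −
acrophase)/24)) + Σ pulses + meal responses. Pulse onsets are Poisson over
the day (GH's 80% sleep-weighted, giving the nocturnal GH burst cluster);
amplitudes are log-normal; each pulse decays exponentially at the
hormone's clearance half-life. Glucose and insulin get gamma-shaped
responses to three fixed feedings at 30, 270 and 540 minutes after the
0900 h start (mid-morning, early afternoon, evening — the protocol fixes
three feeding times but not their clock values). Assay noise is
multiplicative log-normal with mean 1 at each hormone's CV; the defaults
(glucose 2%, insulin 5%, TSH 2.8%, cortisol 3.5%, GH 6%) sit inside the
reported inter-assay CV ranges (e.g. glucose 0.90–7.44%). Baselines and
amplitudes are round numbers at the physiological orders of magnitude of
healthy adults.

Errors: per-point spike/drop probability 2.5% + 2.5% (factors U(2, 5) and
U(0.1, 0.6)), per-tube dilution probability 2% with one shared factor
U(0.1, 0.6) applied to all hormones of the tube; dilution takes precedence
over a spike/drop at the same point, and a factor of exactly 1.0 is a
no-op and not recorded. Everything is reproducible bit-for-bit from one
seed (clean simulation and error injection use seeds spawned from it).

What the simulator does *not* emulate: secretion feedback (e.g.
glucose→insulin coupling beyond shared meal responses — so simulated
glucose–insulin cross-correlations are meal-driven and their lag structure
is flatter than in real data), assay drift, run/batch effects, missing-data
patterns, and errors that mimic physiology (a plausible-looking shifted
pulse). Passing tests on simulated data therefore demonstrate that each
detector implements its rule correctly and detects the error classes it
was designed for — not that the same sensitivity/specificity holds on real
sera.

## Evaluation layer

- Counts are computed per participant — % time points with ≥1 flagged
  hormone among time points with any data, % flagged data points among
  non-missing points — then averaged (mean, SD) across participants, not
  pooled.
- Descriptives (mean/median/min/max/SD) are on the original concentration
  scale; flagged points are removed first. The probability-weighted
  variant uses w = 1 − P(outlier) for mean/SD and computes order
  statistics over points with w > 0.5, since weighted order statistics
  are not otherwise defined here.
- Cross-correlation: Pearson per lag over pairwise-complete points, lag
  grid symmetric in steps of the sampling interval, default ±120 min
  (a declared choice). Convention, also documented on the result object:
  lag L pairs x(t) with y(t + L), so with x = glucose, y = insulin a
  negative lag at the maximum means the peak occurs with insulin shifted
  earlier. A lag with fewer than 10 overlapping pairs is reported missing.
- Venn overlap supports 2 or 3 methods (a proportional 2-D Venn diagram
  cannot show more), at time-point and data-point level.
- Performance against simulation truth: sensitivity, specificity,
  precision over non-missing points, with sensitivity also stratified by
  error type.

## Problem sizes and benchmarks

The test suite and the acceptance script use 1–10 simulated participants
at the full 144 × 5 grid — enough for every rule to operate at its design
conditions while keeping runs fast. The EM recovery benchmark draws 5000
points with exactly 5% from the wide component (stratified rather than
Bernoulli membership, so the check isolates estimator error from draw
noise); dilution recall is measured over 20 seeded simulations with
dilution factors ≤ 0.5 and default assay CVs.

## Known limitations

- Truncated boundary windows weaken detection at series ends; expert
  visual review retains an advantage there.
- The cross-sum threshold −8 is calibrated to five co-measured hormones;
  panels with different tube compositions need a rescaled threshold.
- The EM mixture over-flags genuine pulses when a hormone's variance is
  strongly time-of-day dependent (its narrow component underfits daytime
  scatter); this is a property of the method, visible in its low
  specificity on simulated pulsatile data.
- No reference-analyte (creatinine/urea) normalization for dilution
  confirmation; no deconvolution-based or entropy-based analyses.
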