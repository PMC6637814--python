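# pulseqc

Automatic detection of measurement errors in serial 24-h multi-hormone data.

Frequent-sampling endocrine studies draw blood every 10 minutes for 24 hours
(144 time points) and assay several hormones — typically glucose, insulin,
TSH, cortisol and growth hormone — from the same serum tube. Preanalytical
artifacts (dilution of a sample by the heparinized-saline line flush, blood
clots, handling errors) corrupt individual measurements or whole tubes, and
show up as outliers that can distort minima, maxima and cross-correlations
downstream. `pulseqc` implements three automatable detectors for such
outliers, a physiology-emulating simulator with injected ground-truth
errors, and an evaluation layer to compare the methods. It is aimed at
researchers cleaning pulsatile-hormone time series before secretion or
rhythm analyses.

## Methods

All detectors start from the same decomposition. For each participant *i*
and hormone *h* (insulin and GH on the natural-log scale, since their
distributions are strongly skewed), a centered moving average of window
*w* = 5 smooths the series, and residuals are the vertical distances

> r(t) = y(t) − ŷ(t),  z(t) = (r(t) − r̄) / s_r

with z standardized to mean 0, SD 1 within the person-hormone series.

1. **Tukey's fences** — compute quartiles Q1, Q2, Q3 of the residuals and
   IQR = Q3 − Q1; flag points outside [Q2 − k·IQR, Q2 + k·IQR] with
   k = 3 ("far out"; a quartile-anchored variant Q1 − k·IQR / Q3 + k·IQR
   is also available).
2. **Stepwise approach** — flag z < −3 or z > 4 (asymmetric, because
   pulsatile secretion makes rapid rises plausible and rapid falls not);
   flag any glucose < 2.8 mmol/L (physiologically impossible in healthy
   adults without a stress response); sum z across the five hormones of the
   tube at each time point and flag the whole tube when the sum < −8
   (average residual below the standard-normal 5th percentile, ≈1.64 SD —
   the signature of a diluted sample); then remove the flags, refit, and
   repeat the fit + tube rule once.
3. **EM algorithm** — pool standardized residuals per hormone across all
   participants and fit a two-component univariate normal mixture by
   expectation-maximization: a narrow component for true variation, a wide
   one for errors. Each point gets a posterior outlier probability;
   P > 0.9 classifies it as an outlier, or the probabilities weight
   downstream statistics as w = 1 − P(outlier).

The simulator generates circadian/pulsatile profiles per hormone (meal
responses for glucose/insulin, sleep-locked GH pulses, nocturnal TSH and
morning cortisol acrophases), multiplies in log-normal assay noise at
realistic CVs, and injects isolated spikes/drops plus tube-level dilutions
with a recorded truth mask, so sensitivity and specificity are measurable.

## Worked example

```python
import pulseqc as pq

panel, truth = pq.simulate_panel(pq.SimulationConfig(n_participants=3), seed=42)
for name, res in [("tukey", pq.detect_tukey(panel)),
                  ("stepwise", pq.detect_stepwise(panel)),
                  ("em", pq.detect_em(panel, seed=42))]:
    comp = pq.count_outliers(panel, res)
    perf = pq.detection_performance(res, truth, panel)
    print(name, comp.pct_datapoints_mean, perf.loc["overall", "sensitivity"])
```

prints (formatted):

```
panel: 3 participants, 144 time points, 5 hormones
injected errors: 111 (5 dilution tubes)
tukey     16.11% of data points, 55.79% of time points | sens 0.95 spec 0.88
stepwise   3.56% of data points, 12.04% of time points | sens 0.55 spec 0.99
em        26.90% of data points, 74.31% of time points | sens 0.99 spec 0.77
```

Reading this: the stepwise detector is conservative and very specific — it
flags 3.6% of data points and essentially never flags true physiology,
catching every dilution tube via the cross-hormone rule but missing mild
isolated errors that stay near the fitted curve. The two data-driven
methods trade the opposite way: they catch most injected errors but also
flag many genuine secretory pulses (the EM's wide component absorbs pulse
residuals), which is exactly why purely data-driven flagging is risky on
pulsatile data.

The same workflow is scriptable from the shell:

```bash
pulseqc simulate --n-participants 3 --seed 42 --out panel.csv --truth truth.csv
pulseqc detect stepwise --panel panel.csv --out flags.csv
pulseqc run --config examples/run.yaml
```

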