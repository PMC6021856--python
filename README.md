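# homesig

Behavioral analytics for ambient-assisted-living (AAL) smart homes.

A single-occupant home instrumented with a handful of low-power sensors —
bed and chair pressure pads, toilet/fridge/door contacts, passive-infrared
(PIR) motion detectors, a power meter on the TV — emits an irregular
stream of events, on the order of 10² per day. Caregivers of older adults
living alone need that stream turned into answers to three questions: *how
much* (hours in bed, toilet visits per night), *is it changing* (trends,
shifted routines), and *what are the habits* (recurring multi-sensor day
patterns). `homesig` implements the full cold path from raw event log to
those answers, plus a synthetic-household simulator so every stage can be
validated without access to real pilot data.

## The pipeline

1. **Signature matrices** (`homesig.events`). Events are resampled onto a
   regular grid (default 1-minute bins, half-open `[t, t+w)`): binary state
   sensors are 1 in every bin they overlap, impulsive sensors carry
   activation counts, real-valued sensors the time-weighted mean (with a
   threshold filter to binarize). The resulting time × sensor matrix is the
   substrate for everything downstream.

2. **Behavior explanatory models** (`homesig.bem`). For a daily quantity
   `y_d`, a pool of interpretable regressions is fitted over the feature
   subsets of {bias, linear trend, weekend}: ordinary least squares for
   real-valued quantities, Poisson (negative binomial when overdispersed)
   for counts. The pool member minimising

   `AIC = 2k − 2 ln L`

   is selected — the best fit with the fewest factors. The trend feature is
   the day index scaled to [0, 1], so its coefficient is the *total change
   over the window*. Gross outliers are removed beforehand by an IQR fence;
   days with |standardized residual| > 3 are flagged afterwards. Rolling
   15-day windows yield per-day coefficient vectors that feed a
   support-vector user classifier and one-class anomaly detectors.

3. **Sensor profiles** (`homesig.profiles`). A sensor's day is summarised
   in 48 half-hour bins: expected fraction of active time (state sensors)
   or probability of at least one activation (impulsive). Days are the
   sampling unit; confidence intervals come from a percentile bootstrap
   over days. Two periods are compared bin-by-bin with a permutation test
   (Welch-t / two-proportion parametric options) and the p-values are
   Holm–Bonferroni adjusted across the 48 bins, controlling the
   family-wise error rate of the comparison.

4. **Multivariate habit clustering** (`homesig.nn`, `homesig.habits`).
   Each day's binary 48 × sensors matrix is compressed by an autoencoder —
   a GRU sequence model or a 1-D temporal CNN, trained to minimise the
   binary log loss of its own reconstruction — and the latent vectors are
   clustered (mean-shift by default). Cluster prototypes are means of the
   member days back in the original sensor space. A raw-concatenation
   baseline with the same Euclidean metric quantifies what the embedding
   buys. No deep-learning framework is required: the networks run on a
   small reverse-mode autodiff engine (`homesig.autodiff`) included here.

5. **Stream rules** (`homesig.rules`) replay pilot-management checks over
   a log: low battery, missing keep-alives, grossly prolonged ON states.

6. **Synthetic household** (`homesig.simulate`). Impulsive sensors are
   inhomogeneous Poisson processes (sampled by thinning); state sensors
   are session processes (Poisson session counts, time-of-day start
   densities, truncated-normal durations). Weekend multipliers, linear
   trends, changepoints, outlier days, keep-alives and battery decay are
   all scriptable, and everything is deterministic given the seed.

## Worked example

```sh
homesig simulate --days 30 --seed 7 --out events.csv
homesig resample --in events.csv --specs examples/specs.yaml --binary --out sig.csv
homesig profile --in sig.csv --specs examples/specs.yaml --sensor bed --out prof.csv
```

or end-to-end from Python (this is what `scripts/acceptance.py --seed 1`
prints):

```
BEM bed-hours: selected ('bias', 'weekend'), AIC 213.8, mean level 8.64 h
profile: peak activation 0.85; 0 significant bins between halves
habit clusters: AE 4 (silhouette 0.53), raw 1 (silhouette -1.00); training loss 0.693 -> 0.383
stream rules: 0 alerts on the simulated log
```

Read: the occupant averages 8.6 h/day in bed with a mild weekday/weekend
difference and no trend; the bed profile peaks at 85% occupancy overnight;
no behavioral change between the two halves of the window (none was
simulated); the autoencoder embedding organises the days into 4 habit
clusters where raw-space clustering finds no structure; and the healthy
log raises no alerts.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the whole pipeline from scratch on a freshly simulated
household — resampling, model fitting and selection, profile comparison,
autoencoder training and clustering, rule replay — and writes the result
manifest to `--out`. The statistical guarantees (oracle equivalence of the
GRU/convolution/Holm primitives, resampling conservation, parameter
recovery, AIC parsimony, family-wise error control and power, bootstrap
coverage, habit-recovery and the embedding-vs-raw ordering, simulator
calibration, rule behaviour) are asserted by `tests/test_acceptance.py`.
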