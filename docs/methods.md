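# Methods

This note documents the models, the statistical procedures, the defaults
and the numerical choices in `homesig`, and what the synthetic-data tests
do and do not establish.

## Event model and resampling

Events follow a flat schema (gateway, sensor, variable, timestamp, typed
value fields). All storage and analysis is UTC; a display timezone enters
only at the reporting layer (daily aggregates, day boundaries). Bins are
half-open `[t, t+w)` left-aligned to the epoch minute, default `w` = 1 min.

A binary sensor's bin is active iff the sensor was ON during *any* instant
of the bin. The any-overlap rule is deliberately generous: at 1-minute
resolution it preserves short events (fridge, toilet) that a
majority-of-bin rule would erase. The cost is bounded: total active time
can differ from exact ON time by at most two bins per session (one at each
end), which the conservation tests assert. Real-valued sensors get the
time-weighted mean of the reported step function per bin; binarization is
a strict `value > threshold`, so raising the threshold is monotone
non-increasing on every cell. Malformed input rows are collected into an
error report with line numbers rather than aborting ingestion — field logs
are dirty, and keep-alives interleave with status events.

An ON left open at the end of a log is held open to the log end with a
warning; overlapping ONs are coalesced with a warning. Both are real
conditions in radio-constrained deployments (lost OFF packets).

## Behavior explanatory models (BEM)

The model pool is every feature subset containing the bias:
{bias}, {bias, trend}, {bias, weekend}, {bias, trend, weekend}. Bias is
always present because the fitted level (mean hours, mean count) is itself
a reported quantity. The trend regressor is the observation date scaled to
[0, 1] across the window, so the coefficient is directly the total change
over the window and its per-day rate is `coef / (days − 1)`.

Families: Gaussian quantities use OLS; penalised fits (ridge/lasso) are
excluded from the pool because a penalised likelihood breaks the AIC
comparison. Counts use Poisson regression; when the Pearson dispersion
(χ²/df) of a Poisson fit exceeds 1.5, a negative-binomial fit of the same
design joins the pool and AIC arbitrates — NB carries one extra parameter
(`k = p + 1`). AIC is computed as `2k − 2 ln L` from the exact
log-likelihood, never from a package's convention, and the selection is an
exhaustive argmin over the pool (asserted against recomputation in tests).

Pre-filtering drops nulls and points outside `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`
with linearly-interpolated quartiles. A constant series has IQR 0 and a
degenerate fence equal to the quartiles; points equal to them are kept, so
constant data passes through untouched. Post-fit outliers are days with
|standardized residual| > 3 (Gaussian: residual scaled by the root mean
squared error with df = n − k; counts: Pearson residual under the fitted
variance function). The threshold 3 is a package default, not an estimate.

Rolling analysis fits trailing 15-day windows at 1-day steps; a window
that cannot be fitted (too few points after prefiltering) is reported as
missing, and its daily feature vector is a row of zeros. Coefficients of
features that AIC deselected are likewise exported as 0: deselection means
no detectable effect. The user-discrimination and anomaly helpers are thin
wrappers over established components (scikit-learn SVC + t-SNE,
IsolationForest / one-class SVM); they are evaluation utilities, not
contributions, and their internals are out of scope.

## Sensor profiles and period comparison

The day is the sampling unit throughout. For each of the 48 half-hour bins
the day-level statistic is the fraction of active fine bins (state
sensors) or the indicator of ≥ 1 activation (impulsive sensors); the
profile estimate is its mean over days (minimum 5 days). Confidence
intervals are a percentile bootstrap over days (default 1000 resamples,
fixed seed): the percentile method respects the [0, 1] range, which
matters because profile estimates often sit at or near the boundaries. Its
true coverage on 40-day Bernoulli data measures ≈ 0.96 for nominal 0.95 —
slightly conservative due to the discreteness of day means — which the
calibration test accounts for by pooling coverage across bins.

Period comparison tests each bin with a two-sample permutation test on the
day-level statistics (difference in means, 5000 permutations by default,
one shared day permutation across bins per replicate since days are the
exchangeable unit). Parametric alternatives (Welch-t for state sensors,
two-proportion z for impulsive) exist for larger samples. The p-values of
one comparison's 48 bins form the multiplicity family and are
Holm–Bonferroni adjusted: sort ascending, multiply the i-th smallest by
`m − i` (0-based), enforce the running maximum, cap at 1. Identical
constant data in both periods yields p = 1 per bin, never a 0/0. The
direction of each bin's difference is reported alongside significance,
because the sign ("more bed presence after lunch in the second period") is
what a caregiver acts on. Adjusting across sensors as well as bins is a
stricter family a user can build by concatenating p-vectors; per-sensor
families are the package default.

## Autoencoders and habit clustering

Inputs are binarized 30-minute day matrices (48 × sensors), not 1-minute —
the compression target is the *shape* of a day, and 48 steps keeps the
networks trainable on a single CPU core.

Architectures (defaults chosen once to satisfy the training-progress
property, then frozen):

* **GRU**: one recurrent encoder layer, hidden size 32; the latent code is
  the final hidden state. The decoder mirrors the encoder: a GRU fed the
  latent code at every step with a per-step linear readout. The update
  gate mixes the previous state with a tanh candidate computed from the
  reset-gated state.
* **Conv1D**: two blocks of valid temporal convolution (16 then 8 filters,
  kernel 5) + ReLU + max-pool 2, then a dense map to a 16-d latent code.
  The decoder is dense (latent → hidden → logits) rather than mirrored
  transposed convolutions: at 48 time steps upsampling convolutions add
  parameters and code without measurable reconstruction benefit.

Training minimises the binary log loss of the reconstruction,
`L = −mean[y ln ŷ + (1−y) ln(1−ŷ)]`, evaluated in the numerically stable
logits form; a constant prediction of 0.5 scores exactly ln 2 ≈ 0.693,
which is the natural reference for "has it learned anything". Optimisers:
adam (default, lr 0.005), rmsprop, sgd. Batches of 16, 200 epochs by
default, everything seeded; non-binary input and NaN losses are hard
errors. Because no deep-learning framework is assumed, the graphs run on a
small reverse-mode autodiff engine over numpy (`homesig.autodiff`) whose
gradients are verified against central finite differences, and whose
forward passes are verified against independent scalar/sliding-window
oracles of the gate and convolution equations.

Clustering defaults to mean-shift on the embedding. The bandwidth comes
from scikit-learn's nearest-neighbour heuristic (`estimate_bandwidth`,
quantile 0.3): the average over points of the distance to their
`quantile`-fraction neighbourhood. A global pairwise-distance quantile was
considered and rejected — with k balanced, well-separated clusters only
~1/k of pairs are within-cluster, so a global 0.3-quantile lands at the
*between*-cluster scale and merges everything; the neighbour-fraction
version tracks the within-cluster scale instead. The quantile should
roughly match the expected cluster share (0.3 suits ≥ 3 habits; use 0.5
for two balanced routines); it is an explicit parameter everywhere.
Duplicate-point degeneracies (bandwidth 0) fall back to a single cluster
with a warning. k-means and spectral clustering are available when the
cluster count is known.

Prototypes are per-cluster means (medians optional) of member days in the
original 48 × sensor space. The silhouette score is computed in the space
each method clusters — the embedding for autoencoder variants, the raw
concatenated space for the baseline. This matters when reading the
comparison: each method is judged on the geometry it actually sees, and
the reported ordering (embedding ≥ raw) is about how much usable structure
each space exposes to the same algorithm. `coverage_top5` is the fraction
of days in the five largest clusters; fragmented clusterings score low.

## Stream rules

Batch replay over a sorted log, behaviourally identical to the hot path at
desk scale. Low battery fires when the latest battery reading is strictly
below the threshold (20% default); keep-alive gaps when the silence
exceeds `multiplier × keepalive_interval` (2 × 60 min default); prolonged
state when a binary sensor stays ON longer than the maximum (480 min
default), with the alert timestamped at the threshold crossing. One
ongoing condition yields one alert. The defaults are operational choices,
not estimates — the field reports no numeric thresholds.

## Synthetic household

The generator states a world and the analytics must recover it:

* **Impulsive sensors** are inhomogeneous Poisson processes with a
  48-bin intensity, sampled exactly by thinning against the daily maximum.
* **State sensors** are session processes: Poisson number of sessions per
  day, start bins drawn from a time-of-day density, durations
  truncated-normal (≥ 1 min), overlaps merged. Sessions may cross
  midnight.
* **Trends** ramp the expected daily quantity linearly across the window
  (rate for impulsive, session duration for state sensors), so the BEM
  linear-trend term is the correctly-specified model and parameter
  recovery is a fair test. Weekend multipliers scale rates/session counts
  on Saturdays and Sundays; outlier days scale a whole day; changepoints
  swap a sensor's routine at a day index.
* **Plumbing**: keep-alives every 60 min, one battery report per day
  decaying at 0.45%/day (a 6–9-month lifetime) with Gaussian noise. The
  battery trace exists to exercise the rules, not to model chemistry.

The default household (bed, chair, toilet, fridge, door, PIR, TV meter)
was calibrated by simulation and then frozen at ≈ 112 status events/day
with PIR contributing ≈ 55% — the order of magnitude and PIR share
reported from real pilots of this sensor mix.

For clustering tests the planted world uses near-deterministic *block*
routines (activation probability 0.95 inside habit blocks, 0.02 outside,
plus 10% unstructured Bernoulli(0.3) noise days). This is a modelling
choice with a quantitative justification: the irreducible reconstruction
loss of any model equals the mean Bernoulli entropy of the generating
probabilities, which is ≈ 0.46 nats for smooth bump profiles — above the
"loss halves from ln 2" training-progress bar — but ≈ 0.18 nats for block
routines. Real habits ("in bed 22:00–06:00") are closer to blocks than to
Gaussian bumps.

What the synthetic world does **not** contain: multi-occupant interaction,
sensor faults and dropouts beyond outlier days, seasonal/holiday structure,
and firmware-level PIR filtering interacting with hourly transmission
bursts (event timestamps are taken as true activation instants). A green
test therefore establishes correctness of the statistical machinery under
its stated assumptions, not robustness to every field artefact.

## Numerical and procedural choices

* Quartiles: linear interpolation; IQR = 0 keeps points equal to the
  fence.
* AIC identity `2k − 2 ln L` is enforced exactly; `k` counts fitted
  coefficients (+1 dispersion for negative binomial).
* Permutation p-values use the add-one estimator `(1 + #{|d*| ≥ |d|}) /
  (n_perm + 1)`, which is never 0 and is exact under exchangeability.
* Bootstrap and permutation seeds are explicit parameters; all simulator
  randomness flows from the scenario seed through one generator.
* Autoencoder training is deterministic given the seed (numpy-only
  stack, float64); silhouette of a single-cluster result is reported as
  −1 by convention and flagged by `n_clusters`.
* Resampling guards: ON-without-OFF held open with a warning; empty logs
  need an explicit span; partial days are flagged and excluded from daily
  regressions by default.

## Known limitations

* The autodiff engine is desk-scale: float64, Python-loop recurrences, no
  GPU. Training 60–90 days at 48 × 2–3 geometry takes seconds to tens of
  seconds; it is not meant for larger corpora.
* Negative-binomial fits occasionally fail to converge on short windows;
  such pool members are excluded and reported rather than silently
  dropped.
* The parametric comparison branch uses Welch-t / two-proportion stand-ins;
  at the 20-day samples typical of deployments the permutation default is
  the better-calibrated choice.
* Mean-shift results depend on the bandwidth quantile; the default 0.3 is
  tuned for ≥ 3 habit modes and will over-segment two balanced modes
  (use 0.5 there). This is inherent to the heuristic, and the parameter is
  exposed.
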