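# Methods

This note documents the models, algorithms, and numerical choices behind
`tbal`, in the package's own terms. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

The package targets continuous, real-time in-hospital mortality risk
assessment for ICU stays from irregular longitudinal EMR data. One ICU stay
is the unit of analysis; a patient may contribute several stays. Time is
measured in fractional hours from ICU admission (admission = 0). Two task
families are supported: **static** tasks triggered once at a fixed time
(hour 12) with a fixed outcome window (death within 1/2/4/7 days, any
in-hospital death, or ICU length of stay > 2 days), and the **dynamic** task
that re-issues a prediction at every surviving grid time for death within
the next 24 hours.

## Cohort eligibility

Stays shorter than 12 h or longer than 30 days are excluded, as are
patients younger than 18 or older than 80 years. Both bounds are inclusive
on the retained side (a 12.0 h stay and an 80-year-old patient are kept):
the exclusion wording — *shorter than* 12 h, *older than* 80 — is read
literally. `filter_eligible` returns a per-criterion exclusion tally; a
stay failing several criteria is counted under each.

## Preprocessing

The per-stay pipeline is `resample → drop_empty_bins → compute_delta →
impute → encode`. Removal of empty timepoints precedes imputation so that
interpolation never runs through phantom bins, and the delta matrix is
computed on the surviving (possibly non-uniform) grid.

* **Resampling.** The timeline is discretized into 1-hour bins; bin *t*
  collects observations in the half-open interval [t−0.5, t+0.5) (bin 0
  uses [0, 0.5)). Half-open binning avoids double-counting an observation
  landing exactly on a boundary. In-bin aggregation follows the variable
  dictionary (median for numerics, mode for categoricals in the shipped
  fixture dictionary; sum/max/min/last are also supported). Mode ties break
  toward the most recently observed category — recency is clinically
  meaningful and the rule is deterministic.
* **Mask and delta.** `M[t,d] = 1` iff at least one raw observation fell in
  bin *t* for variable *d*. The time-since-last-observation matrix follows
  the standard missing-data recurrence used by mask-aware recurrent models:
  `delta[0,d] = 0`, `delta[t,d] = (s_t − s_{t−1}) + (0 if M[t−1,d] else
  delta[t−1,d])`, so gaps accumulate real elapsed hours across unobserved
  and removed bins.
* **Imputation cascade.** Leading gaps take the stay's earliest observation
  (the only reading under which "carry forward" has something to carry at
  the head); a variable never observed in a stay takes the training-set
  median (numeric) or mode (categorical); interior numeric gaps are
  linearly interpolated in real time; trailing numeric gaps carry the last
  observation forward (interpolation has no right anchor there); interior
  and trailing categorical gaps become the explicit `"missing"` category.
  Masks and deltas are never modified by imputation, so the model always
  knows which values were observed.
* **Encoding.** Numerics are z-scored with training-split mean/SD
  (degenerate SD is floored at 1e−6, making constant variables encode to
  exactly 0); categoricals are one-hot over their dictionary categories
  including `"missing"`; one mask channel and one interval channel
  (delta / 24 h) are appended per variable. The 24 h interval scale keeps
  the delta channel interpretable and O(1) on desk-scale stays rather than
  z-scoring it. Imputation happens on the raw scale, encoding afterwards.
  Channel order is deterministic: numerics, categorical blocks, masks,
  intervals.

Normalization statistics and fallbacks are fitted on the training split
only; a sentinel test asserts that adding held-out stays changes them.

## Labels and splits

Static mortality labels are 1 iff death falls in `(trigger, trigger +
horizon]`; "12-hour to 1-day" therefore maps to (12 h, 36 h]. Stays whose
death precedes the trigger are excluded — their outcome is no longer a
prediction target. The in-hospital task uses an infinite horizon. Dynamic
labels are emitted at every surviving grid time t ≥ 1 h: label 1 iff death
∈ (t, t+24]; triggers at or after death are never emitted; survivors (whose
missing death time certifies survival to hospital discharge) contribute
label-0 triggers through ICU discharge; post-ICU in-hospital deaths produce
positives at in-ICU triggers within 24 h of death. Evaluation and
reporting use 4-hourly trigger marks.

Splitting is grouped by patient in a 7:2:1 train:test:val ratio with
largest-remainder rounding, so multi-stay patients never straddle splits; a
leakage check asserts this on every labels table.

## The TBAL model

The encoder is a (optionally stacked) bidirectional LSTM run over the
prediction prefix only. Attention is additive and time-aware:

    e_t = v · tanh(W_h h_t + b + w_tau · g(tau_t)),   g(tau) = log(1 + tau/24)

where `h_t` is the concatenated bidirectional state and `tau_t` is the time
from grid point t to the trigger. The log compression keeps the time term
bounded on week-long stays. Attention weights are a softmax over prefix
steps; the risk is `sigmoid(w · context + b)` of the attention-weighted
context. With `bidirectional=False, attention=False` the identical code
path is the baseline unidirectional LSTM classifying from its final hidden
state. Masks and deltas enter as input channels *and* (via tau) the
attention — the conservative superset of "time-awareness".

Dynamic prediction re-encodes every prefix rather than running one
bidirectional pass over the whole stay: a full-stay bidirectional pass
would leak future observations into earlier predictions. A fuzz test
mutates post-trigger rows and asserts bit-identical risks.

**Context window.** The encoder sees only prefix rows within
`max_context_h` hours of the trigger (default 72 h; the shipped dynamic
recipe uses 24 h, matched to the prediction horizon). Short-horizon
mortality risk is dominated by recent physiology, and the window also
bounds the O(T²) cost of prefix re-encoding. This is a deliberate
architectural choice, not an approximation knob: with it, predictions are
invariant to the absolute length of the history beyond the window, which
removes a prefix-length score bias that otherwise couples pooled
discrimination to the length distribution of dying stays.

The whole network, its exact backpropagation (verified against finite
differences in the test suite), Adam with decoupled weight decay, and
integrated gradients are implemented in NumPy (`tbal._nn`): the package is
dependency-light and fully deterministic given its seeds.

## Training

Static tasks use balanced minibatches (default 200 positives + 200
negatives per batch; the majority class is partitioned so each example is
seen every epoch, the minority class resampled) with plain mean BCE —
balancing is done by sampling. Dynamic tasks sweep the trigger stream with
weighted cross-entropy

    loss = −[ α·y·log p + (1−α)·(1−y)·log(1−p) ]

where `α = "auto"` resolves to the normalized inverse class proportions,
which algebraically equals the negative-class fraction (≈ 0.98 at 2%
prevalence). Optionally each epoch draws a fresh subsample of triggers per
stay (`triggers_per_stay`); over epochs the full stream is covered.
Early stopping restores the best-validation checkpoint with configurable
patience. The default monitor is validation AUPRC — the quantity of
interest under heavy imbalance — but at desk scale a validation split
holds only ~10–15 positive stays and its AUPRC swings severalfold between
epochs, repeatedly selecting undertrained checkpoints; the reference
recipe therefore monitors validation AUROC (`early_stop_metric="auroc"`),
which is far stabler at these sample sizes. L2 regularization is
decoupled weight decay on all non-bias tensors. Two dropout knobs
regularize against the many non-causal channels: inverted dropout on the
attention context (`TBALConfig.dropout`) and on whole input channels per
example (`TrainConfig.input_dropout`); the reference recipe uses 0.3 for
both, which raised held-out discrimination and spread attribution across
correlated informative variables. Validation is scored at 4-hourly
triggers, mirroring evaluation.

## Integrated gradients

Attributions use the m-term right-Riemann approximation of the path
integral from a baseline x′ (default all-zeros, meaningful because inputs
are z-scored/one-hot; an all-"missing" categorical baseline is available
behind a flag) to the input:

    IG_i = (x_i − x′_i) · (1/m) · Σ_{k=1..m} ∂F(x′ + (k/m)(x − x′))/∂x_i

with m = 50 by default. F is the predicted probability. The completeness
gap |Σ IG − (F(x) − F(x′))| is recorded per map. On a linear model the
closed form IG_i = w_i·x_i holds for any m ≥ 1 (the path gradient is
constant), and the test suite asserts it to machine precision.

A numerical caveat the package states openly: the right-Riemann sum has
O(1/m) error with constant ½|g(1) − g(0)|, g(α) being the directional
derivative along the path. Its *relative* error therefore blows up whenever
F(x) − F(x′) nearly cancels, regardless of m. Relative completeness checks
are only meaningful on inputs with a non-degenerate output swing, and the
acceptance fixtures condition on |F(x) − F(x′)| ≥ 0.01 for that reason.

Population rankings average |IG| over stays, triggers, and timesteps per
channel, then sum one-hot levels, mask, and interval channels into their
parent clinical variable (so "lactate" aggregates its value, missingness,
and recency channels); ties break lexicographically. Attribution is
computed per trigger on exactly the windowed prefix the model saw.

## Evaluation

AUROC is the Mann-Whitney concordance (ties ½); AUPRC is average
precision; both are computed by scikit-learn behind the module surface and
cross-checked in tests against brute-force pair-counting and
threshold-sweep oracles to 1e−12. Thresholded metrics use a configurable
threshold (default 0.5) and report undefined ratios as NaN with a flag
rather than 0. Confidence intervals use a 1000-replicate cluster bootstrap
resampling whole stays, because timepoints within a stay are dependent;
for static tasks this degenerates to the ordinary case bootstrap.
Replicates with a single class are dropped and counted. Temporal curves
stratify dynamic predictions by 4-hourly trigger time; subgroup reports
stratify by sex, race, and age (65 falls in the ≥65 stratum). The
cross-cohort harness trains the transfer model on the common-variable
subset from the start (a model trained on a wider feature set cannot score
a narrower one) and applies the source cohort's normalization statistics to
the target cohort.

## Synthetic EMR generator

The generator is the package's test scaffold, not a claim about ICU
physiology. Each stay carries a latent deterioration process: a shared
AR(1) severity (hourly autocorrelation 0.97) plus per-variable AR(1)
components, mixed with weight 0.6/0.4. Numeric variables are affine in
their latent driver plus observation noise (0.3 SD); categoricals threshold
it. Observation times follow an inhomogeneous Poisson process (exponential
inter-arrival gaps) whose rate increases with latent severity — partly
informative missingness, so the mask and delta channels genuinely carry
signal. The per-hour death hazard is `logistic(b + Σ_j β_j z_{j,t})` over
the designated causal variables; the intercept b is calibrated by bisection
so the expected in-hospital mortality (a closed form given the latent
paths) matches the target. A quarter of deaths are deferred past ICU
discharge to emulate post-ICU in-hospital death. Stay lengths are
log-normal (median 60 h, σ = 0.7, clipped to 16–400 h).

Reference conditions (the generator defaults): 1,850 patients with an 8%
second-stay probability (≈ 2,000 stays), 17 numeric + 3 categorical
variables of which `num_00..num_02` drive the hazard with log-hazard
coefficients (2.0, 1.6, 1.2) per latent SD, target in-hospital mortality
8.5%, per-variable mean sampling gaps drawn from 1–6 h. These sizes were
chosen to match the outcome prevalences of large public ICU cohorts
(~8% in-hospital mortality; ~2% of dynamic timepoints positive) while
remaining trainable in minutes on one CPU.

What the generator does *not* emulate: correlated lab panels,
interventions and feedback (treatment lowering risk), unit-specific
documentation habits, measurement drift, or inter-hospital coding
differences. Passing tests therefore demonstrate that the pipeline
recovers planted structure under realistic irregularity and imbalance —
not that the model would attain any particular performance on real EMR
data.

## Problem sizes in the shipped experiments

The acceptance experiments run at the reference conditions above: signal
recovery trains TBAL (hidden 32, attention dim 32, 24 h window, dropout
0.3 on context and input channels, lr 3e−3, up to 24 epochs, patience 6
on validation AUROC, 6 triggers per stay per epoch) on ≈ 2,000 stays and
ranks features from integrated gradients over the full held-out test set
(up to 8 maps per stay, 32 path steps); the transfer harness uses three
≈ 400-patient cohorts (one source, one same-distribution target, one with
all numeric means shifted by 1.5 SD) and a hidden-16 model; the
determinism check runs the full pipeline twice at 60 patients. Unit-test
fixtures are smaller still. These sizes are the package's reference
experiment design; the generator scales to larger cohorts unchanged.

A candid note on statistical resolution at this scale: the held-out test
split contains only ~25–40 dying stays, so patient-level dynamic AUROC
carries a cluster-level standard error of several points. The comparison
between the trained model and the strongest single variable's last
observed value is a near-tie under these conditions — a shared latent
severity (mixing weight 0.6) makes any one causal variable carry most of
the attainable signal — and its sign can flip between independent cohort
draws. The weakest causal variable (log-hazard coefficient 1.2) likewise
sits near the boundary of the integrated-gradients top-5 at this sample
size. Both behaviors are properties of the study scale, not of the
implementation.

## Known limitations

* The dynamic-task survivor censoring rule (label-0 triggers through ICU
  discharge) relies on the outcome being *in-hospital* death, which the
  stays table encodes exactly; with administratively censored data the
  final 24 h of survivor stays would need explicit censoring handling.
* Parameter-count parity with any particular published architecture is not
  claimed; `count_parameters` exposes the per-submodule decomposition so
  discrepancies can be inspected.
* The right-Riemann IG approximation's relative completeness error is
  ill-conditioned under output cancellation (see above).
* Thresholded metrics default to 0.5; no calibration post-processing is
  performed, so accuracy/F1 depend on that choice.
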