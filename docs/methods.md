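# Methods

## The race model

Action selection is modelled as a race between k independent decision
units, one per candidate finger press. On each trial, unit d draws a
drift rate β_d from N(μ, σ²) and rises linearly from baseline 0; the
first unit to reach the common threshold θ commits the response, so the
winning rate is β\* = max_d β_d and RT = θ/β\*. Chosen (free) responses
race k = 4 units; specified (cued) responses are the same process with
k = 1 — there is no separate "selection module", and the model contains
no stimulus-to-race delay and no post-decision motor delay (the
reciprocal-RT distributions are treated as entirely decision time).
Units are independent within a trial: no lateral inhibition, no
collapsing bounds.

θ is not identifiable from behaviour (only θ/β is observed), so it is
fixed at 1 and rates are expressed in threshold-fractions per second
(Hz). The EAA scale that θ would set cancels anyway once the EAA
regressor is mean-centered in the GLM. A single (μ, σ) is used per
condition rather than per finger; the per-finger reciprocal-RT moments
in this task are statistically indistinguishable, and the EAA formulas
assume a shared rate distribution.

### Expected accumulated activity

Given an observed RT on a chosen or specified trial:

* the winner contributes the triangle area EAA_W = θ·RT/2 — exactly
  linear in RT;
* each of the k − 1 losers was still accumulating at a rate known only
  to be *below* β\* = θ/RT, i.e. a normal truncated from above. Its
  expected rate is the truncated-normal mean
  E[β_L | β_L < β\*] = μ − σ·IMR(z\*) with z\* = (β\* − μ)/σ and
  IMR(z) = φ(z)/Φ(z), and its expected accumulated activity is
  E[β_L]·RT²/2.

Total EAA = EAA_W + (k−1)·E[β_L]·RT²/2; on specified trials the loser
term is identically zero. Two numerical choices:

* **IMR in log space.** φ(z)/Φ(z) is evaluated as
  exp(−z²/2 − ln√(2π) − log Φ(z)) using `scipy.special.log_ndtr`, which
  is stable far into the left tail (|z| ≫ 30) where the naive ratio is
  0/0.
* **Floor at zero.** μ − σ·IMR(z\*) goes negative when the truncation
  point is deep in the lower tail (a very fast winner with slow mean
  units). Accumulators rise from baseline 0, so a negative expected
  drift is meaningless and the loser expectation is clipped at 0. The
  floor makes total chosen EAA equal the specified value exactly at
  very short RTs.

A consequence of the formulas as stated: at very long RTs the loser
term behaves like (k−1)·μ·RT²/2, so total chosen EAA approaches k times
the specified (winner-only) value rather than converging back to it.
The intuitive "horse race" picture — at intermediate RTs the losers add
a large non-linear contribution; at extremes the curves approach each
other — holds at the short-RT end only. We implement the formulas as
printed; the long-RT regime is rarely visited at these rate parameters
(an RT of 1 s at μ = 1.7, σ = 0.3 is already a −2.3σ winner).

### Fitting the rate distribution

Reciprocal RTs r = θ/RT are treated as Gaussian and summarized by their
sample mean and SD (`mode="direct"`, the default: the mean equals the
median for a Gaussian, which is why the condition means are also the
reciprocal median RTs). On chosen trials the observed r is the maximum
of k unit rates; `mode="order_statistic"` de-biases the moments through
the mean a_k and SD b_k of the maximum of k standard normals
(σ̂ = SD(r)/b_k, μ̂ = mean(r) − σ̂·a_k; a₄ ≈ 1.0294, b₄ ≈ 0.7012,
computed by quadrature of the order-statistic density). Which
convention a given analysis used should be reported alongside the
parameters; the package default is `direct`, and the synthetic
generator is constructed so that `direct` recovers the configured
condition means (see below).

## Sequence redundancy

Equitability E = H/Hmax is the plug-in information of the 16 ordered
sequential response pairs over twice the marginal information of the
n + 1 contributing responses, in natural logarithms, with 0·ln 0 := 0.
The factor 2 in the denominator bounds pairwise information by twice
the marginal information; for an infinite unconstrained random
sequence E = 1 exactly (all cells 1/16, all marginals 1/4). Degenerate
sequences (one response only, Hmax = 0) return E = 0 with a warning.
Finite random sequences have E < 1 (plug-in entropy bias): the null
distribution at any length is provided by simulation
(`random_equitability_null`) rather than by a fixed reference value,
because E's null mean depends strongly on sequence length (≈ 0.95 at
41 pairs, → 1 as length → ∞). Pairs are formed between consecutive
trials *of the same condition*, skipping interleaved trials of other
types — the only reading that yields per-condition indices from an
intermixed design.

The repetition-rate ratio is the observed fraction of consecutive
identical responses divided by the 4-choice chance rate 1/4.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

* **Schedule** — n_trials = 123 (thirds of 41 chosen / specified /
  null, uniformly shuffled) at SOA 2.5 s, TR 2 s. 123 is the largest
  trial count divisible by 3 consistent with a ~310 s run.
* **Rates** — subject-level condition means drawn around 1.7 Hz
  (chosen) and 1.9 Hz (specified) with between-subject SD 0.1 Hz;
  within-subject trial-to-trial rate SD 0.3 Hz (chosen to give a
  realistic ~150 ms RT interquartile range). The configured means are
  targets for the *observed* mean reciprocal RT. Because the chosen
  observation is the maximum of k = 4 unit rates, the chosen unit-level
  mean is placed a₄·σ below the target; otherwise chosen responses
  would come out faster than specified, the reverse of what free-choice
  behaviour shows. Non-positive rate draws are rejected and redrawn
  (≪ 0.1% of draws at these parameters) so every RT is finite.
* **Repetition suppression** — the unit matching the previous chosen
  response is handicapped by an additive rate decrement δ, the simplest
  race-compatible sequential bias (a bias could equally enter through
  baseline; rate was chosen). Default δ = 0.021 Hz, the analytic root
  of P(suppressed unit wins) = 0.93 × 1/4 at σ = 0.3 — i.e. repetitions
  at 93% of the chance rate, the mild suppression typical when subjects
  are asked to "make a fresh choice" rather than "be random". Larger δ
  lowers equitability monotonically.
* **Errors** — optional wrong-finger responses on specified trials
  (default rate 0); error trials keep their RT and are modelled by a
  separate regressor.
* **BOLD** — y = X·β + drift + AR(1) noise, with a slow cosine drift
  (default amplitude 0) and stationary AR(1) noise (default ρ = 0.3,
  innovation SD 1). Multi-voxel mode assigns distinct beta maps per
  voxel, used to construct "EAA-responsive" versus "categorically
  responsive" synthetic regions.
* **Follow-up design** — a variant flags the first responsive trial
  (chosen or specified per subject), one isolated later chosen and one
  isolated later specified trial (2–4 min into the run), with all
  remaining moves pooled.

What the generator does **not** emulate: scanner artefacts, motion,
physiological noise, spatially structured noise, per-finger rate
differences, higher-order (beyond lag-1) sequential dependencies, and
any categorical BOLD difference not injected through the design.
Passing tests therefore demonstrate the estimators' correctness and
calibration under the model's own assumptions, not robustness to real
fMRI artefacts.

## GLM pipeline

**First level.** Events are 1 s boxcars (cue duration; delta sticks by
flag) on a TR/16 grid, convolved with a canonical double-gamma HRF
(response gamma shape 6, undershoot shape 16 weighted 1/6, 32 s
support, peak normalized to 1, peak at ≈ 5 s) and resampled at volume
times. Model 1: TASK (all chosen + specified events), an EAA modulator
and a categorical CvS modulator (+1 chosen / −1 specified); model 2
adds absolute RT; model 3 builds FIRST / LATER_CHOSEN /
LATER_SPECIFIED / OTHER plus OTHER×CvS. All modulators are
mean-centered over their contributing events *before* convolution, so
a constant shift of a modulator changes nothing. Error events get
their own ERR regressor. Unused (all-zero) columns are dropped with a
warning. A DCT basis implements the 128 s high-pass; a constant closes
the model.

Parametric modulators are deliberately **not** serially
orthogonalized: EAA, CvS and RT compete for shared variance, and the
design records their covariance in its metadata instead. An
`orthogonalize=True` flag reproduces the serial TASK → EAA → CvS → RT
convention for comparison.

Fitting estimates the lag-1 residual autocorrelation by Yule–Walker on
an initial OLS fit (clipped to |ρ| ≤ 0.99; skipped when the residual
is at numerical-noise scale), applies the AR(1) whitening transform to
data and design (first row scaled by √(1−ρ²)), and refits by least
squares. Rank-deficient designs raise an error naming the collinear
columns. Contrasts report estimate, t and a two-sided p at
n − rank(X) degrees of freedom.

**Second level.** Per-subject contrast values enter a one-sample t
against 0 (or a two-sample t for between-group questions such as
chosen-start versus specified-start first moves); multiple units are
corrected by Benjamini–Hochberg FDR. The full
non-sphericity/ReML ANOVA machinery of volumetric packages is
deliberately replaced by these t tests plus permutation analogs, which
are exact at this scale. The covariate analysis (e.g. equitability
against the chosen-vs-specified contrast) uses Spearman rank
correlation — the hypothesized relation is monotonic, not necessarily
linear — with a permutation null built by relabelling subjects,
family-wise corrected by the maximum statistic across units; the
observed labelling is a member of its own null, so p ≥ 1/(n_perm + 1).
Default 5000 permutations, two-sided throughout.

## Problem sizes and tolerances used in the checks

The test suite and recovery runs use 20-subject cohorts of 123 trials
(the design-scale of a single-run study), 30–100 replicate simulations
for power/calibration rates, 10⁵-draw Monte-Carlo oracles for
order-statistic moments (3-decimal agreement with quadrature), and
10⁶-sample truncated-normal oracles compared within 3 standard errors.
Rate-recovery tolerance is ±0.05 Hz on group means (≈ 2 between-subject
SEs at n = 20); GLM beta recovery is held to <10% mean bias. The
permutation calibration uses 499 permutations per simulation so the
0.05 level is exactly attainable (⌊0.05·500⌋/500), and 2000 simulations
for a ±0.01 band on the rejection rate.

## Known limitations

* EAA is derived conditionally on the observed RT; no account is taken
  of parameter-estimation uncertainty when propagating (μ, σ) into the
  per-trial EAA.
* The loser expectation uses the truncated mean only; trial-to-trial
  loser variance is not propagated into the regressor.
* The AR(1) coefficient is estimated once per series (no spatial
  pooling) and the drift basis is shared across models.
* `fit_rate_distribution(mode="order_statistic")` assumes exchangeable
  units; the repetition-suppression bias violates this mildly (one
  unit's mean is shifted by δ on most trials), producing a small
  downward bias at large δ.
* Volumetric (NIfTI) input/output is out of scope; time series are
  exchanged as CSV (volumes × voxels).
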