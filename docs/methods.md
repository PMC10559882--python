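# Methods

## The problem

A DNA sequence over {A, C, G, T} can be read as an ordered signal and
studied with time-series machinery: encode the residues as numbers, treat
position as time, and ask how well the near future of the encoded signal
can be predicted from its past. `btsforecast` implements a hybrid ensemble
for this task — classical long-memory models and a small
convolutional-recurrent network, combined by learned convex weights — along
with everything needed to evaluate it reproducibly on synthetic genomes.

## Sequence encodings

Three standard numeric representations ("biological time sequences") are
produced per sequence:

* **Spectral** — the direct integer map a→1, g→2, c→3, t→4. Invertible and
  bounded in [1, 4].
* **Chaos game representation (CGR)** — starting at the origin of the
  square [−1, 1]², each base moves the current point halfway toward the
  corner assigned to that base. The default corner assignment is
  A=(1, 1), C=(−1, −1), G=(−1, 1), T=(1, −1); the map is a parameter, since
  both C/T orientations appear in the literature. Every point lies strictly
  inside the square and the distance to the active corner contracts by
  exactly ½ per step. CGR is two-dimensional; to obtain one channel the
  package projects each point, by default to its Euclidean norm (symmetric
  in both coordinates; the x- or y-coordinate are available options).
* **Z-curve** — per prefix *i*, with cumulative base counts A_i, C_i, G_i,
  T_i, the three disparities X_i = (A+G)−(C+T) (purine/pyrimidine),
  Y_i = (A+C)−(G+T) (amino/keto), Z_i = (A+T)−(C+G) (weak/strong) are
  summed and square-rooted into a scalar. Algebraically
  X_i+Y_i+Z_i = 4·A_i − i, which is negative whenever the prefix is less
  than 25% A, so a real-valued convention is required: the default is the
  signed root sign(v)·√|v|, which preserves the direction of the disparity;
  clamping at zero is available. This choice is ours — the plain square
  root is simply undefined over the reals for A-poor prefixes.

## From sequence to data set

The per-base series is condensed into *data points* by averaging
consecutive non-overlapping windows of 60 bases (trailing partial window
discarded). The window length is a documented default rather than a known
rule: with 60-base windows every study genome length maps onto its
published data-point total as ⌊length/60⌋ (e.g. 35,937 → 598;
49,316 → 821), which is the only correspondence we found consistent with
all six published rows.

Points are split chronologically into train/validation/test with
n_val = n_test = ⌊0.15·n⌋ and the remainder (≈70%) to train — again the
only rule consistent with every published partition row. Two
normalizations are applied, each fitted **on the training segment only**
(no leakage; statistics are stored and inverted for reporting):
min–max to [0, 1] and variance standardization (x−mean)/sd with sample sd.
Each sequence thus yields six channels: {spectral, CGR, Z} × {minmax,
variance}. Supervised samples use a lookback of T = 8 points (configurable;
no principled value is known) with a one-step-ahead target.

## Single-sequence branch: ARFIMA

Each channel is modelled as ARFIMA(p, d, q). Fractional differencing
(1−B)^d is applied as a truncated binomial filter with weights
c_0 = 1, c_k = c_{k−1}(k−1−d)/k, truncated only by the available history
(series are ≤ ~825 points, so exactness is cheap). After differencing at a
fixed d, the ARMA part is estimated by conditional sum of squares
(zero-initialized residual recursion, Nelder–Mead over the coefficients
with a Yule–Walker warm start for the AR block). d is *searched*, not
jointly estimated: the particle-swarm tuner explores p ∈ {0..5} (integer),
d ∈ [−0.49, 0.49], q ∈ {0..5} with validation one-step MAPE as fitness,
mirroring the particle layout (p, d, q). The white-noise order (0, 0, 0)
is seeded into the swarm, so tuning can never validate worse than that
baseline. Forecasts are rolling one-step: predict, observe the truth,
update the filter state, never refit.

Per-channel forecasts are fused into the single-sequence output O_t^AR
with inverse-validation-MAPE weights normalized to sum to one. Because
the channels are different encodings with different units, each channel's
forecast is first re-expressed in the target channel's units by z-scoring
against its own training segment and rescaling to the target's training
mean/sd. This cross-encoding alignment is a design choice of this package;
without it a weighted sum across encodings is dimensionally meaningless.

## Multi-sequence branch: conv-LSTM

All six channels enter a small network: a one-dimensional valid
cross-correlation layer (16 kernels of width 3 by default, shared across
channels, linear — the convolution carries no activation, matching the
operation as usually printed; an optional ReLU is available), an LSTM with
N_hn hidden units on the feature sequence, and a linear head to the scalar
one-step forecast. Training is full-batch gradient descent on MSE with
fixed learning rate D_tr for N_tr epochs, global-norm gradient clipping at
5, and seeded scaled-uniform initialization (forget-gate bias 1), making
every run bit-reproducible. The backward pass is written out analytically
and verified against central finite differences in the test suite.

The three hyperparameters (N_tr epochs, N_hn hidden units, D_tr learning
rate — searched on a log scale) are tuned by the same particle swarm with
validation MSE as fitness; the default configuration is seeded into the
swarm.

**Self-adaptive pre-training (SaPt).** Before joint training, the network
is warm-started one channel at a time: all other channels are zero-masked
and the stage trains until validation loss has not improved for `patience`
epochs (best-validation weights kept), then the next channel is visited.
The epoch count of each stage is therefore chosen adaptively by the data —
that is the "self-adaptive" element. `patience = 0` disables the procedure
entirely. This operationalization is ours; the mechanism is named in the
literature but not specified.

## Fusion and evaluation

The two branch outputs are combined per time step as
C_t = w·O_t^AR + (1−w)·O_t^LSTM with a scalar convex weight found by grid
search (step 0.01) on the validation segment. The generic `learn_weights`
utility minimizes validation MSE; the pipeline selects the weight by
validation MAPE in original data units instead, aligning the combination
criterion with the headline evaluation metric (standard practice in
forecast combination when the deployment loss is known; since both
normalizations are affine, fusing in normalized space and inverting
commutes, so the choice of space is immaterial — only the criterion
matters). Scalar weights are the default because ~100 validation points
cannot identify per-timestep weight vectors; a vector variant exists
behind the same dataclass.

Evaluation is in original (inverse-normalized) units:

* **MAPE** (percent). Zero truths raise rather than being skipped —
  silent exclusion changes N and corrupts comparisons. Encoded targets are
  bounded away from zero by construction.
* **R²** — the squared Pearson correlation of truths and forecasts (the
  printed formula is the squared correlation, not the coefficient of
  determination; we implement it as printed). Affine-invariant, symmetric.
* **Accuracy growth rate** |MAPE_i − MAPE_j|/MAPE_i × 100.
* **Diebold–Mariano test** on the loss differential (squared-error loss by
  default), with rectangular HAC variance using h−1 autocovariance lags
  and two-sided standard-normal critical values 1.645 / 1.96 / 2.58 at
  90 / 95 / 99% confidence. (Published prose attaches 1.96 to "90%",
  inconsistent with its own 1.645 statement; 1.96 is the 95% value and is
  treated as such.) The Harvey small-sample factor is available but off by
  default.
* **VAR** — squared sample (ddof = 1) standard deviation of residuals, a
  stability measure.

## Synthetic data

The generator produces (a) DNA under an i.i.d. base model or a first-order
Markov chain (row-stochastic 4×4 transition matrix, started from its
stationary distribution), and (b) ARFIMA(p, d, q) series with known
parameters, simulated by driving Gaussian noise through the MA polynomial,
the AR recursion (500-sample burn-in), and the inverse fractional filter.
All draws flow from one explicit seed; there is no hidden global state.

What the synthetic data does *not* emulate: coding structure, repeats,
GC-skew trends, or any biological constraint beyond base composition.
Passing tests on synthetic genomes therefore demonstrate that the
machinery is correct and calibrated, not that real genomes are predictable
to any particular accuracy.

## Benchmarks and problem sizes

* **Smoke benchmark** — six i.i.d. 6,000-base sequences (100 data points
  each) through the full pipeline at the default desk-scale swarm budgets
  (ARFIMA: 8 particles × 5 iterations; network: 4 × 3). Random DNA has
  essentially no temporal structure, so accuracy is near the noise floor;
  the benchmark checks that every stage runs, produces finite metrics and
  is bit-reproducible.
* **Ablation benchmark** — one 6,000-base Markov sequence with
  self-transition probability 0.99, condensed with 20-base windows
  (window-to-window correlation ≈ 0.75), a stand-in for the compositional
  patchiness of real genomes (isochores, GC islands). On this benchmark
  each removable part of the framework — SaPt, the conv layer, the AR
  branch, swarm tuning — is switched off in turn and the median validation
  MAPE across seeds is compared against the full model. Sizes (one
  sequence, reduced swarm budgets, ≤ 250 epochs) are chosen so the
  5-variant × 20-seed sweep is a desk-scale computation.

## Numerical notes and limitations

* The CSS surface can be multimodal in the MA coefficients; candidates
  with near-unit-root MA polynomials are rejected (loss = ∞) to keep the
  residual recursion stable. Non-convergent fits raise with diagnostics.
* Fitted AR polynomials with roots inside the unit circle produce a
  warning, not an error: rolling one-step forecasts remain well-defined.
* `frac_difference` drops the first d points for non-negative integer d
  (exact differencing leaves them undefined) and keeps full length for
  fractional d; `frac_integrate` is its exact inverse given the same
  history.
* Particle-swarm defaults are the constriction-equivalent constants
  w = 0.729, c1 = c2 = 1.49445, swarm 20, 30 iterations, velocity clamped
  to half the box range; integer dimensions are rounded at evaluation only.
  The pipeline uses smaller budgets by default (documented above) —
  raise them for serious runs.
* Objective failures inside the swarm (exceptions, non-finite fitness) are
  logged and treated as +∞ rather than crashing the search.
* MAPE-based fitness is meaningful only for series bounded away from zero;
  where a validation truth is exactly zero the tuner and weight learner
  fall back to (R)MSE.
* The network is intentionally minimal (one conv layer, one LSTM, linear
  head, plain gradient descent). It is not a general deep-learning stack:
  no mini-batching, no adaptive optimizers, no GPU.
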