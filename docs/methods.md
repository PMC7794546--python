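# Methods

`spectune` automates the construction and tuning of one-dimensional
convolutional neural networks (1D-CNNs) for regression on fixed-length
spectra, with visible–near-infrared (vis–NIR) diffuse reflectance of soil and
a soil-organic-carbon (SOC, g·kg⁻¹) target as the reference use case. This
note records the model, the numerical choices, and the limits of what the
synthetic experiments demonstrate.

## The optimisation problem

A configuration λ assigns a value to every active hyperparameter of a
tree-structured search space Λ. Its quality is the k-fold cross-validated
root-mean-squared error

    objective(λ) = (1/k) Σᵢ RMSE(λ, D_train⁽ⁱ⁾, D_valid⁽ⁱ⁾),   k = 10 by default,

where each summand trains the 1D-CNN described by λ on the fold's training
part and scores it on the fold's validation part, in the original target
units. The optimiser seeks argmin λ ∈ Λ.

## The search space

The space mixes types and is conditional (a tree): ON/OFF flags gate whole
subtrees, so e.g. pool size exists only when its Conv-block's pooling state
is ON, and Conv-block i's hyperparameters exist only when at least i blocks
are requested.

* Input channels: five flags — reflectance R, absorbance ABS = log₁₀(1/R),
  ABS + first derivative, ABS + second derivative, ABS + standard normal
  variate. At least one must be ON.
* Per Conv-block: filters [4, 64], kernel [2, 10], stride [2, 10], padding
  {Same, Valid}, batch-norm flag, activation ∈ {ReLU, LeakyReLU, ELU, SELU,
  Swish}, pooling flag → {type {Average, Max}, size [2, 5], stride [1, 3],
  padding}, dropout flag.
* Per FC-block: nodes [5, 256], batch-norm flag, activation, dropout flag.
* Shared: Conv- and FC-block dropout rates [0, 0.5], optimiser ∈ {Adagrad,
  RMSProp, Adam}, batch size [16, n_samples], epoch budget [100, 1500],
  number of Conv-blocks [1, 4] and FC-blocks [1, 3].

Block-count and pool-size ranges are not fixed by the reference problem;
the defaults above are deliberately small windows and are constructor
arguments of `default_space`. Per-block hyperparameters are indexed per
block (block 2 has its own filters, kernel, …) rather than shared; the
dropout *rate* is shared per block type, matching how the reference optimum
reports a single FC-block rate.

## Architecture construction

A configuration expands deterministically into a layer list: for each
Conv-block `conv → [BN] → activation → [pool] → [dropout]`; then `flatten`;
for each FC-block `dense → [BN] → activation → [dropout]`; finally
`dense(1, linear)`. Width arithmetic follows the ubiquitous convention —
Same: `ceil(w/stride)` with symmetric zero padding; Valid: `floor((w −
kernel)/stride) + 1`. The reference optimum (4 channels, one Conv-block with
55 filters, kernel 5, stride 4, Same, SELU; FC-blocks of 251 and 219 nodes)
on a 211-point input yields conv width 53 and flatten width 53 × 55 = 2915,
which the builder reproduces exactly and the test suite asserts.

Configurations whose width arithmetic collapses below one point are not
repaired; the objective returns a finite penalty of 2 × sd(target) —
strictly worse than the trivial mean predictor — so the optimiser receives
an informative signal and learns to avoid the region. Diverged trainings
(non-finite loss) are penalised the same way.

## Preprocessing

Derivatives are central finite differences with one-sided differences at the
borders, so every channel preserves the spectrum length and the ON channels
stack into an (n, points, channels) array. Savitzky–Golay smoothing is
deliberately not used: the space carries no window/polyorder
hyperparameters, and plain differences are the minimal reading of
"first/second derivative". SNV uses the population (1/n) standard deviation
and rejects spectra with sd below 1e-12.

Two standardisations are applied inside each CV fold, both fitted on the
fold's training rows only and declared extensions of the reference recipe
(which is silent on input scaling): per-channel z-scaling of the stacked
input, and z-scaling of the target with predictions transformed back before
RMSE. Both are required for stable gradient-descent training from random
initialisation at realistic target scales.

## Training backend

The network layers (strided 1-D convolution, batch normalisation, the five
activations, average/max pooling, inverted dropout, dense) and the three
mini-batch optimisers (Adagrad lr 1e-2; RMSProp lr 1e-3, ρ 0.9; Adam lr
1e-3, β 0.9/0.999) are implemented in vectorised numpy with hand-derived
backpropagation; the test suite validates every layer's gradients against
central-difference numerics. Learning rates are not part of the search space
(the reference study leaves them unstated); the backend defaults above are
recorded in run metadata. Weight init is LeCun-normal (compatible with
SELU); the dropout rate is the probability of *zeroing* a unit — the
framework-universal convention, and the only reading under which an optimal
FC rate of 0.22 inside a [0, 0.5] range is sensible.

Early stopping holds out 15% of each training fold as a monitor set (never
the fold's validation part), patience 50 epochs, min_delta 0, and restores
the best-epoch weights; the configured epoch count is a maximum budget. All
of these are `TrainingSettings` fields.

## TPE

The optimiser is a tree-structured Parzen estimator: after `n_startup`
uniform trials, the history is split at the γ-quantile of the objective into
good (l) and bad (g) sets; per-hyperparameter densities are estimated —
truncated-Gaussian Parzen mixtures blended with a uniform prior (weight 1)
for numerics, Laplace-smoothed category counts for categoricals and flags —
and the next configuration takes, dimension by dimension down the
conditional tree, the value maximising l/g (the Expected-Improvement ranking
for this surrogate). Finite domains are maximised by exact enumeration;
numeric domains over 24 candidates drawn from l. Conditional densities use
only trials where the hyperparameter was active; penalised trials land in
the bad set through their penalty objective.

Numerical choices that mattered in development:

* **Per-dimension maximisation.** Scoring joint candidate vectors by the sum
  of log l − log g over ~45 dimensions lets sampling noise from the many
  irrelevant dimensions drown the few informative ones; factored per-
  dimension maximisation (what hyperopt and optuna actually do) restored the
  expected advantage over random search.
* **Bandwidth floors.** Scott's rule, floored at 1% of the domain width,
  at width/min(100, n+2) (wide while evidence is scarce, narrowing as it
  accumulates), and at half the lattice step on integer domains. Without the
  latter two the sampler froze on the first good cluster it found —
  visible as a small-integer hyperparameter locked on one value for an
  entire run.
* **Defaults** γ = 0.15, n_startup = 12, n_candidates = 24, prior weight
  1.0 — between hyperopt's (0.25/20) and optuna's (~0.1/10) conventions,
  selected by paired benchmarking against random search on the packaged
  surrogate. All are `TPEParams` fields.
* Integer values are sampled continuously, rounded to the lattice and
  clipped; densities are evaluated at the rounded value. Categorical ties in
  l/g are broken by domain order (ratios are compared by division, not log
  difference, so exact ties stay ties).

Random search draws every trial uniformly and shares the history schema, so
convergence traces of the two optimisers are directly comparable. Trial i's
randomness depends only on (seed, i) and the history content, which makes
interrupted runs resumable bit-for-bit from their serialised history.

## Hyperparameter importance (fANOVA)

A random-forest surrogate (64 trees, min leaf 3, feature subsampling 0.8,
bootstrap, seeded) is fitted to (configuration → mean objective) over the
*independent* hyperparameters — those active in every trial; conditional
ones (pool settings, higher block indices) do not exist in all records and
are dropped. For each tree, each dimension's marginal predictor is computed
exactly by cell-volume integration of the tree's piecewise-constant function
(uniform weight over numeric domains, uniform over category/lattice points —
matching the uniform search prior; no Monte Carlo); the first-order
importance of a dimension is Var(marginal)/Var(tree), averaged over trees,
and the remainder is reported as interaction/higher-order variance, so the
fractions sum to one. Zero-variance histories yield an all-zero report with
a degenerate flag. The forest's out-of-bag R² is reported as surrogate fit
quality. Categorical splits are ordinal over category indices (a restriction
to contiguous subsets, inherited from the forest implementation); marginal
integration still weights categories uniformly.

Penalised trials are retained by default (they mark bad regions);
`encode_history(..., include_penalised=False)` excludes them.

## Synthetic spectra

The generator emulates the structure of a large topsoil vis–NIR library:
4201-point reflectance spectra on 400–2500 nm at 0.5 nm, downsampled 1:20 by
strided selection to 211 points — the stride-4 Same convolution of the
reference optimum then gives ceil(211/4) = 53, consistent with that
configuration's known layer table, which is why strided selection rather
than block averaging was adopted. Spectra are a flat mean albedo with smooth per-sample offset/tilt
jitter, minus Gaussian absorption bands: roughly half the bands are
"analyte" bands whose depth is linear in the target, the rest have random
per-sample depths (a mineral-matrix role); i.i.d. noise (sd 0.003) is added
and values are clipped to (1e-6, 1]. The target is lognormal
(exp N(3.0, 0.8²), median ≈ 20 g·kg⁻¹, long upper tail), i.e. positive and
right-skewed as SOC distributions are.

What the synthetic data does **not** emulate: real absorption-feature
positions and co-linearity structure, instrument artefacts, the
mineral/organic population mixture, or any geographic structure. Passing the
synthetic experiments therefore demonstrates the correctness of the
machinery (shape arithmetic, leak-free CV, optimiser and importance
behaviour), not field-level predictive accuracy; accuracy on the real
library requires that library and production-scale search budgets, both out
of scope here.

## Problem sizes used in the shipped experiments

The test suite and `scripts/acceptance.py` run everything at desk scale, as
the package's own choice of demonstration size: 120–200 samples, 2-fold CV,
epoch budgets of tens (overriding the [100, 1500] production range via
`default_space(epochs=...)`), 60-trial search budgets on a deterministic
surrogate objective for optimiser comparisons, and 500-trial synthetic
histories for importance recovery. The deterministic surrogate
(`spectune.surrogates.cnn_proxy_objective`) encodes the qualitative landscape
of the reference problem — training-related hyperparameters dominate, one
Conv-block is best, the first-derivative channel helps slightly — so that
optimiser behaviour can be benchmarked in milliseconds per trial.

## Known limitations

* The numpy backend is CPU-bound and single-threaded; it is meant for
  desk-scale runs and correctness, not for the production-scale search.
* Average pooling with Same padding divides by the full pool size (zeros
  included) rather than the valid-element count.
* LeakyReLU's negative slope is fixed at 0.01.
* fANOVA reports first-order (main-effect) fractions only; interactions are
  aggregated into a single residual.
* The all-channels-OFF corner of the space is invalid by construction;
  uniform sampling redraws the five flags, and the TPE suggestion falls back
  to the best-scoring single channel, so the flags' marginal distribution is
  uniform only conditional on validity.
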