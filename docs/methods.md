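# Methods

`tippingews` studies a single question: given only a univariate record of a
fluctuating system under slow external forcing, can one tell whether the
system is heading towards a catastrophic transition (C.T.), a smooth
transition (S.T.), or no transition at all (N.T.)?  The package supplies the
three ingredients needed to study it end to end: a labelled simulator of
stochastic bifurcating dynamics, the classical critical-slowing-down (CSD)
indicator pipeline with four standard ML baselines over it, and a
length-invariant LSTM-FCN deep classifier trained directly on raw series.

## Simulated data

### Model form and library

All training data come from stochastic differential equations

    dX/dt = f(X, p) + g(X) ξ(t),

where `f` is the deterministic skeleton, `p` a slowly ramped control
parameter and `ξ` environmental noise.  The default library holds ten
specifications spanning the four local bifurcations that exhibit CSD:

| name | skeleton | bifurcation | class |
|---|---|---|---|
| `fold_grazed` | logistic growth − Type-III grazing (r=1, K=10, h=1) | fold (upper branch) | C.T. |
| `fold_harvest` | logistic − constant harvest (p_crit = rK/4) | fold (upper branch) | C.T. |
| `fold_lower` | fold normal form, low-density branch | fold (lower branch) | C.T. |
| `transcritical_harvest` | logistic − proportional harvest (p_crit = r) | transcritical | S.T. |
| `pitchfork` | supercritical pitchfork normal form | pitchfork | S.T. |
| `hopf` | supercritical Hopf normal form (2-D, one recorded component) | Hopf | S.T. |
| `nt_*` | the four families above at fixed sub-critical p | — | N.T. |

The grazing-model fold point is computed at library-construction time from
the tangency condition of p(x) = r(1−x/K)(x²+h²)/x (≈2.6044 for the default
parameters); the other bifurcation points are closed-form.

Two generator design choices matter and are deliberate:

* **Commensurate state units.**  The normal-form models are expressed in
  rescaled units (state ×5) and around an operating level B(p) = 5 − 2p
  that tracks the forcing, for two reasons.  First, ecological and climate
  states are measured around nonzero operating points whose position moves
  with the environmental driver — in a harvested population the abundance
  declines as pressure rises *before* any bifurcation; a normal form pinned
  at zero until its crossing is the unphysical member of such a library.
  Second, a batch-normalised network trained on a mixture of amplitude-10
  and amplitude-0.05 series effectively discards the small ones.  Both the
  deviation-form embedding and the rescaling change units, not dynamics.
* **Crossing placement.**  The control ramp is linear over the simulated
  interval and scaled per series so that p crosses its bifurcation value at
  a uniformly drawn fraction (0.75–0.95, mean ≈0.85) of the series.  A fixed
  fraction would make truncated-series length a perfect class give-away;
  the jitter keeps long pre-tipping segments without that degenerate cue.

Transition-class series are truncated at the recorded crossing point
(margin 0 by default, configurable), so classifiers see pre-transition data
only.  Density-like states are clipped at zero.  Labels follow bifurcation
type: fold → C.T.; transcritical, pitchfork, supercritical Hopf → S.T.;
ramp never reaching a bifurcation → N.T.

### Noise

Environmental noise is a stationary AR(1) process

    ξ(T+1) = k ξ(T) + σ √(1−k²) φ(T) + β w(T) √(1−β²),   β = (1−|ρ|)/|ρ|,

with `k` the autocorrelation coefficient (|k| ≤ 0.8), `σ` the intensity and
`ρ` the species response correlation (default 1, making the β term vanish;
the placement of the √(1−β²) radical is ambiguous in common typography of
this recursion, and this reading preserves the white-noise limit and the
stationary variance σ² — it is guarded to β ≤ 1).

The noise is defined on the recorded time points T = 1..400 while the
integrator refines the drift at dt = 0.01 (100 substeps per point).  Each
point's noise value is held constant across its substeps, scaled so the
point's total Euler-Maruyama noise mass is g·ξ(T)·√Δ (the unit-step
scheme).  The recorded forcing therefore has pointwise variance σ² and
lag-1 autocorrelation exactly k for every k — including anticorrelated
k < 0 — while the deterministic skeleton is integrated accurately.  Red
forcing concentrates power at low frequencies, so the *state* responds
more strongly (≈1.8× variance for an OU state at k = 0.8 at equal forcing
power); that physical amplification, not any change in noise loudness, is
what makes the coloured datasets harder.

### Datasets

`build_dataset` produces balanced three-class collections with an exact,
per-class and per-model stratified 80/20 train/test split.  Variant W is
white noise throughout (k = 0).  Variant C draws |k| uniformly from the
weakly correlated band [0, 0.4] for training series and from the strongly
correlated band (0.4, 0.8] for test series, with random sign — the split is the point of the
variant: the classifier is evaluated under noise it never saw.  The cut at
0.4 is the midpoint of the admissible range.  Default σ = 1 (diffusion
functions carry per-model amplitudes: multiplicative 0.05·X for the
population models, additive 0.1 for the rescaled normal forms).  Everything
is deterministic given the dataset seed.

## Generic early-warning indicators

The classical pipeline detrends a series with a Gaussian kernel smoother
(bandwidth expressed as percent of series length by default, matching
EWS-toolbox convention; an absolute-points mode exists) and computes rolling
statistics over the residuals: SD, coefficient of variation (SD over the
|mean| of the *raw* window), lag-1 autocorrelation (AR1), the
conditional-least-squares AR(1) regression coefficient (ACF1 — listed
separately from AR1 because both appear as distinct indicators in
practice), return rate 1/|AR1|, and a spectral density ratio (periodogram
power in the lowest 5% of frequencies over the top 50%; the band edges are
a documented convention, configurable).  Each track is summarised by its
tie-corrected Kendall τ-b against time.  Feature vectors concatenate the τ
summaries over the bandwidth grid {20, 30, 40} × window grid {40, 50, 60},
ordered indicator-major; τ rather than the raw tracks is the summary
because it is the field's standard trend statistic and makes the feature
length series-length-independent.  Degenerate windows (zero variance, zero
AR1 for the return rate) yield NaN; τ is computed on finite values; an
all-tied or all-NaN track contributes feature 0 with a logged warning.

Rolling statistics are computed by cumulative-sum identities and vectorised
FFTs; the test suite checks them against naive per-window recomputation.

## Classical baselines

Logistic regression (L2, C = 1), RBF SVM (C = 1, γ = scale, probability
outputs), random forest (500 trees) and a one-hidden-layer MLP (100 ReLU
units, early stopping) are fitted to the feature vectors through
scikit-learn.  Scale-sensitive learners (LR, SVM, MLP) receive train-set
z-scoring inside their pipelines; the forest does not.  Exact tuned
hyperparameters of the original study are not published; these defaults are
the library standards and are all exposed in `BaselineConfig`.

## The deep classifier

The LSTM-FCN maps a raw univariate series of any length T ≥ 8 to three
class probabilities:

* **FCN branch** — three stacked blocks of same-padded 1-D convolution,
  batch normalisation and ReLU, `Z = ReLU(BN(W ∗ X))`, with filter counts
  (128, 256, 128) and kernels (8, 5, 3) by default (the canonical LSTM-FCN
  values), followed by global average pooling over time → a D-vector
  (D = last block's filter count).
* **LSTM branch** — the series fed stepwise as scalars to a 128-unit LSTM
  (zero initial hidden and cell states, forget bias 1); the final hidden
  state is kept.
* **Head** — branch outputs concatenated, two fully connected layers
  (128 → 3), terminal softmax.

The implementation is pure NumPy with hand-derived backpropagation through
every layer (verified against central finite differences in the test
suite), float32 by default with a float64 switch.  Training uses Adam
(lr 10⁻³ full scale), three-class cross-entropy, cosine learning-rate decay
and global-norm gradient clipping at 1.0 — the last two because a
from-scratch LSTM over 400 steps otherwise occasionally stalls on the
hardest model pairs.  Raw series enter unmodified (no normalisation) by
default; a global z-score switch exists for ablation.

Ragged batches (mixed lengths are inherent: truncated transition series are
shorter than N.T. series) are right-padded under an explicit validity mask:
convolution outputs, batch-norm statistics and gradients exclude padded
positions, pooling averages over each series' true length, and the LSTM
gradient is injected at each series' own final step.  A padded batch is
bit-for-bit equivalent to per-series forward passes, which the test suite
asserts; inference simply groups by length.  This masking matters: batching
by exact length instead makes mini-batches nearly class-pure, and batch
normalisation then learns batch-composition statistics that do not transfer
to inference.

## Evaluation protocols

Experiments are seeded functions of a base seed; metrics are averaged over
independent trials with normal-approximation 95% confidence intervals (the
CI method is a package choice).  Protocols: multi-trial accuracy,
row-normalised confusion matrices, imperfect-sampling curves (random
order-preserving subsampling of test series over a fraction grid,
default {0.05..1.0} in steps of 0.05), leave-one-model-out cross-validation
(train on all library models but one, evaluate on the held-out model's
series, warning when the held-out class is absent from training), and
truncation curves (accuracy on prefixes ending a margin before the
crossing).  AUC for three classes is macro-averaged one-vs-rest.

### Reduced-scale protocol

The bundled reproduction (`scripts/acceptance.py`, `tests/test_acceptance.py`)
runs a desktop-sized version of the full study: 50 series per class
(150 per dataset, 120/30 split), a proportionally narrower network
(filters 32/64/32, 64 LSTM units, 64-unit head) and 60 epochs at lr
5·10⁻⁴ with batch 16 — about the same number of parameter updates as the
full-scale 25-epoch schedule — averaged over 5 trials.  These constants
live in `tippingews.experiments` (`DESK_*`).

## Numerical choices and degenerate inputs

* Euler–Maruyama at dt = 0.01, recording every 1.0 time unit; the scheme's
  first-order convergence and the OU stationary variance are asserted in
  tests.  A divergence guard raises a simulation error naming model and
  step.
* Internal indexing is 0-based; recorded time points are reported 1-based.
* Kendall τ of an all-tied track is undefined (NaN), mapped to feature 0.
* Windows with zero variance yield NaN indicators; CV with a zero raw mean
  yields NaN.
* Checkpoints store the architecture config (JSON) plus weights and
  batch-norm running statistics (npz); loading verifies shape and config
  and reproduces predictions exactly.

## What the simulations do and do not show

The generator emulates the canonical low-dimensional route to tipping:
slow one-parameter forcing, additive/multiplicative stationary noise,
well-separated time scales, no observation error, regular sampling (except
where subsampling is the experiment), and transitions of known type and
time.  Real records violate most of these at once: drivers move
non-monotonically, noise is non-stationary, sampling is irregular, and the
"true label" may be contested.  Passing the bundled benchmarks therefore
shows that the method recovers the designed signal under the stated
conditions — not that any particular field series will be classified
correctly.  The leave-one-model-out protocol probes one axis of that gap
(novel dynamics at test time) and shows exactly where generalisation fails:
folds whose collapse orientation is unrepresented in training.

## Known limitations

* No spatially extended, networked, higher-codimension or global
  bifurcations; no noise-induced or rate-induced tipping labels.
* Only one- and two-dimensional skeletons; the recorded series is a single
  component.
* Training cost is CPU-bound NumPy; the full-scale configuration
  (hundreds of series per class, width-256 network) is hours, not minutes.
* The coloured-noise bridge between the recorded-point recursion and the
  fine-step integrator is an explicit modelling decision (see Noise);
  other discretisations are defensible and would change Dataset-C
  difficulty.
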