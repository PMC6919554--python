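# Methods

## Model

`aclspeech` fits sparse linear classifiers for speech emotion recognition
whose weights are jointly optimized for two tasks: separating binary emotion
labels and reconstructing articulatory kinematic targets.  For a single
articulatory target the training objective is

    f(w) = −(1/N) Σ_i [ y_i log σ(wᵀx_i) + (1 − y_i) log(1 − σ(wᵀx_i)) ]
           + λ₁ ‖w‖₁
           + (λ₂/M) Σ_j (a_j − wᵀx_j)²

where x ∈ R^D are supra-segmental acoustic feature vectors, y ∈ {0,1} binary
emotion labels (arousal or valence axis), a_j the per-segment mean of one
articulatory channel (e.g. jaw height), and σ the logistic function.  The N
classification rows and the M reconstruction rows are independent sample
sets: they may come from different speakers or entirely different corpora,
which is what makes the method usable when articulatory recordings are scarce.
λ₁ > 0 controls sparsity; λ₂ ≥ 0 trades articulatory reconstruction against
classification.  The objective is convex for fixed (λ₁, λ₂).

With K targets, one weight column w_k is fit per target — the joint cost is a
sum of independent single-target costs, so columns can be fit in any order
with identical results — and stacked into W = [w₁ … w_K].  At recognition
time the posterior is the arithmetic mean of the per-column posteriors,
p(y=1|x) = (1/K) Σ_k σ(w_kᵀx); restricting the mean to one target or one
anatomical group gives ablation results without retraining.  Categorical
recognition (neutral/angry/sad/happy) trains one-vs-rest models per class and
takes the argmax of the class posteriors; exact ties resolve to the earliest
class in the canonical order (neutral, angry, sad, happy).  Inference never
touches articulatory inputs.

Three training criteria are exposed: **ACL** (the joint objective above),
**ACO** (acoustic-only, λ₂ = 0, i.e. plain L1-regularized logistic
regression), and **AR** (articulation-only least-squares regression of each
target on the acoustic features; minimum-norm solution when rank-deficient).

## Features

Frame-level low-level descriptors — by default 26 Mel-filter-bank energies,
pitch, the first two formants, and overall intensity (30 descriptors at 200
frames/s) — are summarized per vowel segment or utterance by five statistics
(mean, standard deviation, minimum, maximum, range), giving D = 150 features.
The registry is configurable and the math is dimension-agnostic, so toy
registries are used in fast tests.  Articulatory channels are summarized by
their mean over the segment.  Numerical choices here: the standard deviation
uses the n−1 denominator and is defined as 0 for single-frame segments;
missing frames (unvoiced pitch) are masked from all five statistics, and a
trajectory with no observed frame is an error rather than a silent zero.
The frame rate is metadata only; no resampling is performed.

## Optimization

The reference solver is accelerated proximal gradient (FISTA) with
soft-thresholding and function-value adaptive restart, initialized at w = 0
(deterministic).  The step size is the reciprocal of the exact Lipschitz
bound ‖X‖₂²/(4N) + 2λ₂‖X_r‖₂²/M, so no line search is needed.
Soft-thresholding produces exact zeros on inactive coordinates, and whenever
λ₁ ≥ ‖∇smooth(0)‖_∞ the zero vector is returned exactly (subgradient
optimality).  Convergence requires both a relative objective change ≤ the
tolerance (default 1e−5) and a subgradient-optimality residual ≤ 10× the
tolerance; the default iteration cap is 10,000 and non-convergence raises an
error carrying diagnostics.  Because the problem is convex, the attained
objective is solver-independent within tolerance; the test suite checks it
against an independent generic solver (L-BFGS-B on the split w = u − v
reformulation) and, for λ₂ = 0, against a standalone L1-logistic solver.
The cross-entropy is evaluated with the log-sum-exp identity, which is
equivalent to clamping probabilities away from 0/1 at machine precision and
never produces −∞ on saturated sigmoids.

No intercept is used by default — the objective above has none — though an
unpenalized intercept can be enabled by augmenting the features.

**Standardization.**  Acoustic features are z-scored per column and
articulatory targets per channel before optimization, and the classification
set's centering/scaling is stored in the model so that inference on raw
features is self-contained.  A single weight vector must serve both the logit
scale and physical target units (millimetres, velocities), and without
standardization the meaning of the λ₂ grid would depend on the measurement
units.  When the reconstruction rows come from a different corpus they are
standardized with their *own* column statistics: per-corpus z-normalization
is standard practice in cross-corpus paralinguistics and keeps the
reconstruction term well-posed when corpora differ by channel offsets.  This
is a documented package choice, not implied by the objective.

## Model selection

The search grid defaults to λ₁ ∈ {0.1, 0.5, 1.0} and λ₂ ∈ {0.001, 0.005,
0.01, 0.05, 0.1}.  Two protocols:

* **Speaker-dependent repeated partitions** — classification trains and
  tests on random halves (ratio 0.5) of one designated speaker's segments;
  reconstruction rows come from the remaining speakers or from another
  corpus, never from the test data.  λ is chosen by mean test recall over 15
  selection partitions and then re-scored on 10 fresh evaluation partitions;
  the two phases draw from disjoint seed streams derived from the master
  seed, so the reported recall never reuses selection data.
* **Leave-one-speaker-out (LOSO)** — one fold per speaker, that speaker held
  out of classification *and* reconstruction training (asserted structurally
  on every fold).  λ is chosen by the best average recall over speakers; by
  default the average for a fold excludes the fold itself (nested selection,
  avoiding a mild optimism), with a `pooled_selection` switch restoring the
  simpler pooled average.  Both behaviors are provided because either reading
  of the protocol is defensible.

Ties on mean recall break toward larger λ₁ and then smaller λ₂ — the sparser,
less constrained model.  Failed fits at a grid point count as missing, not as
zero recall.

## Evaluation

UAR (unweighted average recall) is the mean of per-class recalls; confusion
matrices are reported as counts and as row percentages.  The chance reference
BCUAR is permutation-based by default (mean UAR of the fixed predictions
against 1,000 seeded label permutations; an analytic 1/C reference is the
limiting value for a label-independent predictor).  Reconstruction quality is
the Pearson correlation between each target and its linear reconstruction
over the training reconstruction rows, optionally averaged per speaker first;
a zero-variance reconstruction (fully sparsified weights) scores 0 with a
warning.  Classifier differences are tested with the two-sided
pooled-variance difference-of-proportions z-test at α = 0.05.  Feature
importance is ranked by |weight| with exact zeros excluded.

## Synthetic corpora

Real corpora with simultaneous audio and articulography are licensed and
small, so the package ships a generator that emulates the structure the
method assumes rather than any acoustic realism:

* features: standard normal base + per-speaker offsets (sd 0.5) + a
  per-corpus shift vector (sd 0.5) — the simplest structure exhibiting
  speaker and corpus variation;
* targets: a_k = x·w*_k + noise (sd 0.5), with each sparse w*_k (support 10)
  overlapping the label support (size 10) in a fraction ρ of coordinates
  (default 0.8); shared coordinates copy the label weights so the
  articulation–emotion relationship has a consistent sign;
* labels: y ~ Bernoulli(σ(x·w*_y)) with weight magnitude 1, or categorical
  sampling from four one-vs-rest weight vectors over a shared support.

Defaults are 400 segments from 3 speakers at D = 150 with the 18-target
articulography layout (tongue/jaw/lip × position/velocity/acceleration ×
X/Y); a 15-target facial-marker layout (five chin/lip channels × X/Y/Z) is
used for the partner corpus in cross-corpus experiments.  Everything is
reproducible from the spec seed via spawned generator streams.

ρ is the transfer knob: at ρ = 0 the reconstruction term is uninformative for
classification *by construction*, which gives a negative control.  What the
generator does **not** emulate: heavy-tailed and highly collinear filter-bank
statistics, vowel-dependent acoustic structure, label noise from annotator
disagreement, or nonlinear articulation–acoustics coupling.  Passing the
synthetic benchmarks therefore demonstrates correctness of the machinery and
the qualitative transfer mechanism, not expected recall on real speech.

## Benchmark experiment sizes

Chosen so the full suite runs in about a minute on one CPU while leaving
clear statistical margins (all use 20 seeds):

* **Recovery / CC ordering** — 400 segments, D = 150, noise sd 0.5; AR
  support recovery is scored by F1 with a coordinate called active when its
  |weight| reaches 25% of the column maximum (least squares has no exact
  zeros); observed F1 ≈ 1.0, and mean training CC orders AR > ACL > ACO.
* **Transfer** — 4 targets, 60 classification training segments from one
  speaker out of four, 375-row speaker-independent reconstruction pool;
  λ₁ = 0.1 with λ₂ selected from the geometric sub-grid {0.001, 0.01, 0.1}
  by the repeated-partition protocol (5 selection / 5 evaluation trials); the
  acoustic-only baseline is the same pipeline with λ₂ = 0 on identical
  partitions (paired comparison).
* **Cross-corpus** — paired corpora with shared truth (18-target layout for
  classification corpus, 15-target partner), λ = (0.1, 0.1), 3 partitions per
  seed.
* **Planted grid** — 30 features, 16 training segments, ρ = 1, target noise
  0.2, grid {0.1, 1.0} × {0.001, 0.1}: λ₁ = 1.0 zeroes the model at this
  scale and λ₂ = 0.001 ignores the informative constraint, so (0.1, 0.1)
  dominates by construction.

## Degenerate inputs and edge rules

Binary decisions use ≥ at threshold 0.5.  Zero-variance feature columns get
scale 1 (no division by zero).  A classification set must contain both
classes; partitions that lose a class are resampled up to 20 times and then
error.  In the seeded benchmark experiments, a corpus draw whose designated
speaker is too class-imbalanced for the partition protocol is rejected and
redrawn from the next seed in the stream (bounded at 10 attempts) — the same
bounded-retry philosophy applied one level up.  An empty reconstruction pool, an unknown emotion label, or a missing
descriptor each raise a named error.  Model files are JSON with full-precision
decimal floats (`repr`), so save/load round-trips are bit-faithful, and the
acoustic-only criterion is serialized identically to ACL with λ₂ = 0.

## Known limitations

The model is strictly linear; nonlinear articulation–acoustics relationships
are outside scope.  Posteriors are uncalibrated and combined only by the
arithmetic mean.  λ search is exhaustive over a small grid, not continuous.
The synthetic generator's Gaussian feature base understates the collinearity
of real filter-bank statistics, which would slow the lasso path and lower
support-recovery F1 at equal sample sizes.
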