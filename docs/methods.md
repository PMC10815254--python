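# Methods

## Problem setting

A missense variant can destabilize a protein's backbone dynamics without
changing its average structure.  The pipeline classifies variants of
uncertain significance (VUS) by comparing the *distribution over time* of
their backbone torsion angles against variants of known effect.  The input
unit is one MD snapshot reduced to its Ramachandran scatter plot: an ordered
vector of (φ, ψ) dihedral pairs, one per residue.  One variant contributes a
time-ordered sequence of such frames (334 per variant in the reference
protocol, taken from the tail window of a production run); every frame is
treated as an individual sample.

## Model

**Featurization.**  Frames are flattened residue-major (φ before ψ) to
vectors of length 2R and standardized per feature (z-score).  Standardization
parameters are fitted on labeled (training) frames only; unknown variants
are transformed with the frozen parameters, so no information leaks from the
prediction set into the model.  Angles stay in degrees throughout; constant
features get their scale floored at 1e-8 and standardize to exactly 0.
Raw angles are used rather than a sin/cos embedding; the wrap discontinuity
at ±180° is immaterial for basins well inside the principal range, but users
simulating basins near the boundary should recenter their data.

**Time-one-lagged autoencoder.**  Encoder
`H = E(X) = W_{M+1} ∘ σ_M ∘ … ∘ σ_1 ∘ W_1 X` with M = 3 hidden layers
(widths 512, 256, 64 by default), leaky-ReLU activations (slope 0.01), and a
*linear* final layer to the latent dimension q = 6; the decoder mirrors the
widths in reverse, also ending linearly.  Training minimizes
`L(X, X*) = (1/N) ‖X* − D(E(X))‖²` where X* is the frame one time step
after X and pairs never cross variant boundaries.  Reconstructing the next
frame rather than the current one suppresses fast thermal noise in the
latent space and retains slow torsional modes.  Weights are
Glorot-uniform; biases start at zero (the conventional companion of Glorot
initialization — a Glorot bound is ill-defined for a bias vector).
Optimization is mini-batch Adam, lr 0.001, batch 64, 50 epochs, no early
stopping.  In the linear/lag-0 limit the architecture reduces to PCA, which
the test suite verifies against an eigendecomposition oracle.

**Labels and balancing.**  Pathogenic-derived frames form the *deleterious*
class; benign- and wildtype-derived frames are pooled as *unknown*.  Two
balancing mechanisms exist because benign variants are scarce in practice:
(1) wildtype augmentation — frames thinned from a long wildtype simulation
(e.g. every 10 ns of a 1 μs run, via `select_window(..., stride=...)`) are
added on the unknown side; (2) SMOTE — the minority class is oversampled to
parity with points `x_i + u (x_nn − x_i)`, u ~ U[0,1], x_nn among the k = 5
nearest minority neighbours.  SMOTE is applied in latent space by default
(the classifier consumes latents and Euclidean interpolation there is
well-posed); input-space balancing is available by balancing before
encoding.  Inside cross-validation SMOTE is re-fitted on each training
split only.

**Classifier.**  `N(H) = σ″ ∘ W″_{M″+1} ∘ σ ∘ W″_{M″} ∘ …` with M″ = 3
hidden layers of 512 nodes, no dropout, leaky-ReLU hidden activations and a
sigmoid on the final two-unit layer only.  The two sigmoid outputs are
normalized to sum to 1 and read as (P(unknown), P(deleterious)); training
uses binary cross-entropy on one-hot labels (the MSE loss applies to the
autoencoder only).  Adam lr 0.001, batch 64, 20 epochs by default — on the
synthetic benchmark the loss plateaus well before that, and the 20-model CV
stays within a few minutes of CPU time.

**Aggregation.**  A variant's P(deleterious) is the mean of its frames'
probabilities (a majority-vote aggregator is available); the call is the
argmax, an exact 0.5/0.5 tie resolving conservatively to "unknown"; a
winning probability above 0.85 flags high confidence.

**Model selection.**  Repeated stratified cross-validation at frame level:
samples are permuted, stratified into 4 folds, and the classifier is
retrained per fold; 5 repeats give 20 models, with train/test ROC AUC,
accuracy and balanced accuracy `(sensitivity + specificity)/2` recorded per
model.  The pseudo-seed scan retrains the whole pipeline for seeds
0, 100, …, 10000 and keeps the seed calling the fewest unlabeled variants
deleterious (ties → smallest seed), a deliberate bias against
over-predicting deleteriousness; seeds whose training diverges are excluded
with a warning.

## Synthetic data generator

Each residue's angles follow a wrapped AR(1) process
`d_t = a d_{t−1} + sqrt(1 − a²) σ ε_t` around a basin centre, with the
stationary spread σ = 1/√κ (radians) matching a von Mises concentration κ
and initial deviation drawn from the stationary distribution.  Defaults: the
benign/wildtype basin sits at the α-helical (−60, −45), κ = 8
(≈ 20° spread), a = 0.5, 334 frames per variant.  The pathogenic class
shifts the φ centre of 20% of residues (the first ⌈0.2R⌉ by default) by the
`separation` parameter, so pathogenic perturbations are local, as variant
effects on real structures mostly are.  All variants of a class share the
basin structure; only noise realisations differ (streams are derived from
(seed, class, variant index), so everything is bit-reproducible).

What the generator does *not* emulate: multi-basin hopping, correlated
motion between residues, glycine/proline-specific Ramachandran topology,
anharmonic tails, and any coupling between φ and ψ.  Passing tests on this
data show the pipeline's statistical machinery is correct and that it
recovers class structure of the kind assumed; they do not certify accuracy
on real MD trajectories.

## Numerical choices

- Determinism: numpy Generators seeded from the run seed everywhere
  (init, batch shuffling, SMOTE, fold splits); CPU-only execution.
  Identical seed + config + data give byte-identical prediction CSVs.
- Sub-seeds: CV repeat r uses seed + r for its permutation and SMOTE; the
  fold-f classifier uses seed·folds-derived offsets so the 20 models are
  distinct but reproducible.
- Scale flooring 1e-8; probability clipping 1e-12 inside the BCE loss;
  sigmoid computed in the numerically stable split form.
- Degenerate inputs: trajectories shorter than the lag are skipped with a
  warning (error in strict mode); a single-sample minority class is a hard
  error pointing at wildtype augmentation; single-class label vectors make
  AUC undefined and raise.
- XVG parsing reconstructs frame boundaries from the recurring
  residue-label cycle; a `residue_count_hint` overrides detection when
  labels repeat within a frame.  Strict mode (default) rejects a truncated
  final frame.

## Design decisions that were genuinely open

- Joint autoencoder training over all classes (wildtype + benign +
  pathogenic) rather than per class: one latent space in which class regions
  can overlap or separate.
- The autoencoder is trained once per run; cross-validation resamples the
  classifier only.  The assessment therefore measures the latent
  classifier's generalization, which is where the class decision lives.
- Frame-level CV splitting follows the stated protocol but leaks
  within-variant correlation between train and test folds; `groups=` offers
  variant-grouped splitting, and variant-level claims should use it.
- Mean frame-probability aggregation per variant (the per-frame
  probabilities are already calibrated to [0, 1]; the mean preserves
  graded confidence where majority voting saturates).
- Decision threshold 0.5 for confusion-matrix metrics; variant calls use
  argmax, which for two normalized outputs is the same thing.

## Benchmark problem sizes

The packaged benchmark (tests and `scripts/acceptance.py`) uses 20 residues,
10 variants per class, 334 frames per variant, a 60° φ shift on 4 residues
and κ = 8 — small enough to run the full 20-model CV in minutes on one CPU
while keeping every architectural dimension (q = 6, 3 × 512 classifier) at
its reference value.  Under these conditions the mean train and test AUC
round to 1.00/1.00.  Smaller configurations in the unit tests shrink widths
and epochs, not the method.

## Limitations

- The probabilities are not calibrated (no Platt/isotonic step); they are
  normalized sigmoid scores.
- Only two classes are modeled; "unknown" conflates benign and wildtype by
  construction.
- The seed-scan objective (fewest deleterious calls) deliberately trades
  sensitivity for specificity and can under-call true positives; soft
  voting across seeds is not implemented.
- No physics: the package consumes torsion trajectories, it does not
  produce them, and it cannot see effects outside backbone torsions
  (e.g. protein–protein interface changes).
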