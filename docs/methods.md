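# Methods

## Problem and model

The package classifies volumetric brain MR images into two classes (the
motivating application is MGMT promoter methylation status in
glioblastoma, where the label predicts response to temozolomide). The
core method is adaptive fine-tuning transfer learning — a volumetric
SpotTune: instead of deciding once which layers of a pretrained network
to fine-tune, a small *agent* network decides **per image** which
residual blocks run with frozen pretrained parameters and which with
fine-tuned copies.

The main network is a 3D ResNet50: 16 bottleneck residual blocks in four
stages (3, 4, 6, 3), instantiated as two structurally identical stacks — a
frozen copy F₁…F₁₆ and a fine-tunable copy F̂₁…F̂₁₆ initialized as exact
value copies — behind one shared stem (7³ convolution, stride 2, pad 3,
batch norm, 3³ max-pool) and one shared classifier (global average pool →
single logit → sigmoid). The agent is a 3D ResNet10 whose head emits a
two-way logit pair αℓ per block. For block ℓ and input x the routed
update is

    x_ℓ = I_ℓ(x) · F̂_ℓ(x_{ℓ-1}) + (1 − I_ℓ(x)) · F_ℓ(x_{ℓ-1})

where each block carries its own skip path (identity, or the standard
strided 1³ projection on stage boundaries) and I_ℓ(x) ∈ {0, 1} is the
routing decision.

### Gumbel-Softmax routing

The binary policy is discrete, so gradients reach the agent through a
Gumbel-Softmax straight-through estimator. With α̃ the softmax of the
agent's raw scores (guaranteeing positive arguments for the logarithm)
and G i.i.d. standard Gumbel noise,

    X = argmax_c [log α̃_c + G_c]                        (hard sample)
    Y_c = softmax_c ((log α̃_c + G_c) / τ)               (relaxation)

One shared noise draw G serves both expressions; the forward pass uses
the hard X while the backward pass differentiates Y (value = hard,
gradient = relaxed). The temperature τ (default 100, as in the study
protocol) controls how discrete Y is: as τ → 0 the relaxation matches
the one-hot argmax, as τ → ∞ each row tends to (½, ½). Both limits are
property-tested. Per-image Gumbel streams are counter-based — derived
from (run seed, image key, sample index) — so batch composition never
changes an image's draw.

## Numerical core

The networks run on a small reverse-mode autodiff engine over numpy
arrays (`spottune3d.nn`): tape-based `Tensor` operations, im2col-based 3D
convolution with a kernel-offset scatter for the backward pass, batch
normalization, max pooling, Adam, and a reduce-on-plateau scheduler. All
arithmetic is float64, which makes the package's exactness claims
(frozen/tuned equality at initialization, zero-policy ≡ frozen forward,
weight-inflation linearity) true to machine precision rather than to a
float32 tolerance. Gradients are verified against central finite
differences in the test suite's underlying development checks; the public
tests verify the behavioural identities instead.

Frozen semantics are strict: frozen blocks never receive gradient, and
their batch-norm layers always run in inference mode (running statistics
are never updated), so a frozen block's function is constant throughout
training. The same pinning applies to whichever tuned blocks a freeze
plan leaves untrainable.

## Data pipeline

**Preprocessing** (defaults reproduce the published geometry on
BraTS-shaped 155×240×240 1 mm inputs): apply the three-subregion tumor
mask (union of enhancing tumor, necrotic core, edema; BraTS codes 1/2/4),
crop a fixed 140×172×164 window centered on the tumor centroid (shifted
minimally to stay in bounds; the window size corresponds to the largest
tumor in the cohort), block-mean downscale by 2 to 70×86×82 at 2 mm,
zero-pad the last axis to square 86×86 slices (extra voxel on the high
side for odd deficits), and min-max scale each patient-modality volume to
[0, 1]. Normalization uses the whole cropped array (masked-out zeros
included); the alternative — normalizing over in-mask voxels only — is a
documented open choice.

**Splitting**: the common test set is round-half-up(0.3 × |DSC subset|)
patients drawn from the DSC subset (the patients that have every
modality), stratified by class with largest-remainder quota rounding;
each modality group's training pool is its own patients minus the test
set. On the study-shaped cohort this reproduces 183/151/132 training
patients and 57 test patients exactly. Five CV folds partition each
training pool (optionally label-stratified round-robin, used by the
pipeline driver so tiny folds keep both classes).

**Augmentation** (training folds only): per original, one left-right
flip, one in-plane rotation uniform in [−180°, 180°], one Gaussian-noise
copy (σ = 0.02 on the [0, 1] scale), and one elastic deformation
(8-voxel control spacing, 2-voxel displacement SD) — n originals → 5n
volumes, clipped to [0, 1]. The noise and elastic parameters are not
constrained by the source protocol and are configurable.

**Balancing** (training folds only): the majority class is pruned
uniformly at random to the minority count, removing augmented copies
before originals. Validation and test sets keep their class imbalance.

## Training and model selection

Defaults mirror the study protocol: binary cross-entropy on the single
logit, Adam with starting learning rates 1e-5 (main) and 1e-4 (agent), at
most 90 epochs, batch 12, τ = 100, and one shared reduce-on-plateau
schedule on validation loss (patience 20 epochs, factor 0.1) driving both
optimizers. The scheduler fires on the (patience+1)-th consecutive
non-improving epoch. Per-epoch validation logs loss, AUC, AP, SEN, SPE
and the selection score

    M = 0.6·[SEN ≥ 0.5] + 0.4·[SPE ≥ 0.5]     (inclusive thresholds)

at probability threshold 0.5. Model selection takes, among epochs with
M = 1.0, the highest validation AUC (earliest epoch on ties); with no
passing epoch the final epoch is used and flagged as a fallback.

**Freeze plans.** Four trainability configurations: `spottune` (tuned
copy + agent + classifier train; frozen copy and stem fixed), `random`
(no checkpoint; stem + one ResNet50 stack + classifier all train),
`transfer_frozen` (only the classifier trains), and `transfer_relaxed`
(classifier plus the final two residual blocks). "Final two blocks" is
read literally as blocks 15 and 16, not the last stage. Non-routed plans
run as a plain ResNet50 through the tuned stack.

**Weight transfer.** Checkpoints are flat name→array maps in the
MedicalNet/torchvision staged naming (`conv1.*`, `layerS.B.*`); an
adapter strips foreign prefixes and maps staged names onto both the
frozen and the tuned copy, so both start from the same transferred
values. Classifier/agent keys may be absent (fresh initialization);
missing body keys or shape mismatches raise with the offending key named.
Multi-channel inputs adapt the single-channel stem by weight inflation:
the kernel is replicated n times along the input-channel axis and divided
by n, which preserves the response to channel-replicated inputs exactly.

## Evaluation

AUC (rank/Mann–Whitney with midrank ties) and average precision come from
scikit-learn; SEN/SPE at threshold 0.5; methylated is the positive class
throughout. SpotTune models are stochastic — each forward draws a fresh
hard policy — so a model is evaluated by drawing 100 policies per patient
at seed 42 and averaging the probabilities before computing metrics. CV
folds are combined by the arithmetic mean of per-patient probabilities,
then modality groups (DSC = 3 perfusion derivatives, DTI = 4 diffusion
derivatives, Struct = T1/T1GD/T2/FLAIR, and their pairwise/threeway
unions) the same way; for equal fold counts this nested mean equals the
flat mean (tested).

Network categories are compared with a tie-corrected Friedman chi-square
on within-patient ranks (identical inputs give statistic 0, p = 1),
followed — only when Friedman is significant at the configured α — by
Nemenyi pairwise p-values from the studentized-range distribution on mean
ranks. The paired per-patient quantity is the probability assigned to the
patient's true class; per-patient correctness is an available
alternative. Which pairing the original analysis used is not recoverable
from its text.

## Synthetic cohort

The generator emulates the structure of the motivating dataset, not its
appearance: 240 patients (defaults), a 208-patient DTI subset and a
189-patient DSC subset with strictly nested availability, exact class,
gender and age-band marginals, three-subregion ellipsoidal tumor masks at
a random in-volume center, and smoothed-Gaussian-noise backgrounds. The
class signal is one knob: methylated patients' enhancing-rim voxels are
shifted by `effect_size` (default 0.2 at background noise SD 0.1 —
a moderate, non-saturating signal). Counts are taken directly from the
specification rather than inferred from percentages.

One source-data note: the published cohort description gives DTI class
counts (91 methylated, 127 unmethylated) that sum to 218, while every
other statement (208 DTI patients; 151 DTI training + 57 test) requires
208. The generator keeps the subset total and uses 91/117 so the nested
invariants and the split arithmetic hold exactly.

What passing tests on phantoms do **not** show: anything about real MR
contrast, scanner effects, registration error, or the actual difficulty
of methylation prediction — the phantom class signal is planted and
strong by construction. They do show that the pipeline's arithmetic,
routing mechanics, freeze semantics and evaluation protocol behave as
specified end to end.

## Reduced-scale learnability protocol

Full-scale training (90 epochs, 70×86×86 inputs, ~10⁸ parameters) is out
of desk-scale reach, so end-to-end learnability is demonstrated on a
scaled protocol (`spottune3d.experiments`): a 60-patient target cohort of
32³ phantoms with an enhancing-rim shift of 5 background-noise SDs,
preprocessed by the standard chain (crop 28³, downscale 2, pad to 14³);
a 4-block basic-block backbone (width 8) with a width-4 agent; the
transferred checkpoint synthesized by pre-training the plain backbone for
15 epochs on an independent source cohort (different seed) — the
package's stand-in for a released pretrained model; per-fold SpotTune
training for 20 epochs at batch 8 with learning rates 1e-3/1e-3 (the
study's 1e-5/1e-4 are calibrated to its 90-epoch full-scale runs and
underfit a 20-epoch run); 5-fold ensembling by mean probability; and
50-draw stochastic evaluation at seed 42 on the held-out common test set.
Fold models use their final epoch: with 8–12-patient validation folds the
criterion-M selection is noise-dominated, which is exactly the fallback
behaviour the selection rule defines.

Per-patient validation/test sets at this scale have 18 patients, so AUC
moves in steps of 1/80; single-fold results vary by several points across
seeds, which is why the learnability check averages fold-ensemble AUC
over three seeds.

## Known limitations

- The numpy engine is single-threaded BLAS-bound; full-scale 90-epoch
  training is not practical with it, and no GPU path exists.
- The hyperparameter random-grid search of the original protocol is
  exposed only as configuration ranges; no search driver is implemented.
- Phantom realism is deliberately minimal (see above).
- The trainable-parameter count of the full network depends on head
  details the source does not pin down; the implementation reports its
  own count rather than asserting a published one.
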