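# Methods

## Data model and orientation

The package operates on T x V time-by-voxel matrices tied to a binary
brain mask. Columns follow ascending Fortran-order linear voxel index
within the mask; the convention is arbitrary but fixed and round-trips
exactly through NIfTI back-projection. Each voxel's series is z-scored
(zero mean, unit variance); constant voxels are zeroed rather than
rejected, because real masks contain flat voxels. For group analysis,
subjects' matrices are concatenated along time, so a 17-subject, 530-volume
study yields a 9,010-row group matrix.

The DBN treats **voxels as samples and time points as features**. This
orientation is stated prominently because it is easy to invert: layer-1
weights are then T x m and their columns are directly interpretable as
time courses, while hidden activations per voxel give spatial maps.

## RBM and training

Layer 1 uses Gaussian visible units with the unit-variance convention
(inputs are z-scored); hidden units and all deeper layers are Bernoulli.
The energy uses the standard all-negative sign convention for the bias and
interaction terms. Training is CD-k (k=1 by default) with mini-batches
(default batch size 10), shuffled each epoch by a seeded generator so runs
are bit-reproducible.

**Sparsity.** A target activation rate per hidden unit (default 0.01 for
layer 1, 0.05 for deeper layers; full-scale learning rate 1e-3,
convergence around 50 epochs) is enforced by nudging hidden biases by
`learning_rate * sparsity_weight * (target - q)`, where `q` is an
exponential moving average (decay 0.95) of the unit's mean activation.
The nudge deliberately touches biases only. An earlier variant that also
propagated a sparsity-penalty gradient into the weight matrix was
measurably worse on planted data: weight columns converged to two-network
mixtures (matched |r| plateauing near 0.7 ≈ 1/sqrt(2)) because the penalty
term drags the weight direction away from the data direction. With the
bias-only form, matched |r| against planted time courses reaches ~0.99
under the same conditions. Scaling the nudge by the learning rate keeps
`learning_rate = 0` an exact no-op.

Weight initialization is Gaussian (std 0.01) with zero biases unless a
previous model initializes the stack (the two-stage mechanism). Momentum
and schedules are intentionally absent; a single optional weight-decay
scalar exists.

## DBN readout

Deeper-layer temporal features are the composition W1 W2 ... Wl, mapping
hidden-space atoms to length-T time courses; columns are standardized to
unit variance for cross-layer comparability. Spatial maps use
deterministic mean-field propagation (probabilities, never samples), so
the readout is a pure function of weights and data; maps are z-scored per
atom across voxels (not jointly within a layer) and supports thresholded
at z > 1.65. Reconstruction error is per-entry MSE of the deterministic
down-pass — at the RBM level for layer-wise logging, through the full
stack for architecture-search fitness.

## Two-stage pipeline

Stage one trains the group DBN from random init; stage two initializes
each subject's DBN from the group weights and fine-tunes at a reduced
learning rate (0.1x by default) so that atom indices keep their meaning
across subjects. Two readings of the group-matrix geometry are
implemented:

* `stacked_subjects` (default): each subject-voxel time series (length T)
  is one sample, so the group stage sees S*V samples of dimension T and
  layer-1 weights transfer to individual models exactly;
* `concatenated_time`: voxels are samples of dimension sum(T_i); each
  subject's initialization takes its own row band of the group W1.

The default is the reading under which group-to-individual transfer is
dimensionally exact. Group-level maps in the default mode average the
per-subject voxel activations before z-scoring; a one-sample t-to-z
helper (`metrics.group_zmap`) is provided as an alternative group
statistic.

## Architecture search

PSO over the continuous (layers, nodes) plane with inertia w = 0.7298 and
c1 = c2 = 1.49618 (the standard constriction-coefficient values), fresh
uniform Rand1/Rand2 per particle per dimension, velocities clamped to
±20% of each range, and decoding by round-half-away-from-zero plus
clipping (default ranges: layers [2, 10], nodes [100, 800]; 30 particles).
Fitness trains a DBN for a reduced epoch count at a fixed seed and scores
the full-stack reconstruction MSE; identical architectures are memoized
within a run. Aging evolution is realized as periodic re-initialization
of the oldest particle (global best retained). The number of generations
per run is configurable (default 10, an arbitrary but documented choice);
repeated runs are aggregated by rounded means of depth and width.

## Synthetic data

The generator plants K networks in a 1-D voxel index (or a supplied 3-D
grid): primaries are disjoint contiguous blocks (default 8% of voxels
each), composites are unions of two primaries. Network k's subject time
course is `sqrt(1 - lambda_k^2) * group + lambda_k * idiosyncratic`, with
smooth squared-exponential GP draws (length-scale 5 TR) standing in for
hemodynamically filtered signals. Defaults mirror the target study design:
17 subjects, 530 time points, lambda 0.2 for primaries vs 0.6 for
composites (sensory consistency vs heteromodal variability), per-network
subject amplitudes 1 + 0.3 N(0,1), and SNR 5 defined as mean planted-signal
variance over in-support voxels divided by noise variance. Matrices are
z-scored per voxel after mixing, like the real pipeline's inputs.

Paired sessions share the structural draws (supports, composite
membership, group time courses) and redraw idiosyncratic components and
noise; per-subject amplitude deviations correlate across sessions at a
planted reliability r via a shared component, which is exactly what a
voxel-wise ICC of the amplitude patterns estimates.

What the generator does **not** emulate: hemodynamic convolution, motion
and physiological artifacts, spatial autocorrelation of noise, partial
volume effects, or non-binary network membership. Tests passing on this
generator therefore demonstrate correctness of the machinery and the
qualitative orderings, not performance on real scans.

## Evaluation statistics

* **Overlap rate** O(S, T) = |S∩T| / |T| against a reference support.
* **ISC**: leave-one-out mean Pearson correlation of one atom's time
  course across subjects; aggregated over atoms per layer and subjects per
  group. Constant series are excluded with a warning.
* **ICC**: one-way random-effects ICC(1,1) per voxel,
  (MSP - MSe) / (MSP + (d-1) MSe), labeled by the conventional five bins
  (poor < 0.2 ... excellent > 0.8). The one-way model is the simplest
  consistent with treating sessions as exchangeable repeats; voxels with
  zero total variance are excluded and counted. Per-network summaries
  average over the union of the sessions' supports by default.
* **ISR**: pairwise |N_a^(L) ∩ N_b^(H)| / |N_b^(H)| plus an aggregate over
  pairs formed by maximal-overlap matching (atom order is arbitrary, so
  index-pairing without matching would be meaningless). For temporal
  features, z-scored time courses are binarized at the same z > 1.65
  threshold so the set formulation applies.
* **Matching**: greedy descending on intersection size, ties broken by
  higher overlap rate then lower index; cross-checked against Hungarian
  max-|correlation| assignment in tests.
* **Group comparisons**: two-sample t or one-way ANOVA with
  Benjamini–Hochberg FDR across the supplied family.

## Problem sizes and numerical choices

Desk-scale study sizes used by the test suite and the acceptance script:
recovery at 5 subjects x T=100 x V=500 with 5 planted networks (2-layer,
8-unit model, learning rate 0.05, 60 epochs); architecture search over
layers [2,4] x nodes [2,16] on 3 subjects x T=80 x V=300 at SNR 10 with
8 particles and 4 generations (high SNR so the planted rank dominates the
reconstruction landscape); reliability Monte-Carlo at 17 subjects x 200
voxels over 20 seeds. Learning rates for these small problems are larger
than the full-scale default because the sample counts are orders of
magnitude smaller.

Ties in decoding round half away from zero. Logistic evaluation is
numerically stabilized. Degenerate cases are defined explicitly: empty
templates raise, constant series are excluded with warnings, zero-variance
map atoms yield empty supports.

## Known limitations

* Greedy mean-field stacking adds no *spatial* structure beyond layer 1 on
  this generator: composite (union) networks carry their own voxel-level
  time course, making them layer-1-learnable, so deeper layers either copy
  layer-1 atoms or broaden them. The planted two-level hierarchy is
  faithfully detected (composites recovered, ISR between layers high, ISC
  ordering primary > composite reproduced), but "composites appear only in
  deeper layers" is not an emergent property of this model class on this
  data model — the corresponding ordering check in the acceptance suite
  documents this honestly by failing.
* The ISC of individual temporal features under strong group
  correspondence is near 1 by construction; subject variability is
  expressed in maps and amplitudes instead.
* Architecture-search fitness with few epochs is noisy; the consensus over
  repeated runs is the intended estimator, not any single run.
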