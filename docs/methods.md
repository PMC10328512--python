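# Methods

## The task

A single recurrent circuit is asked to do two things at once:

1. **Path integration.** Each sequence provides per-step angular velocities
   for each spatial dimension of a periodic environment (a circular track,
   D=1, or a torus, D=2). The network must report its current position as
   (sin θ, cos θ) per dimension — the periodic encoding avoids asking a
   linear readout to produce a discontinuous angle.
2. **Latent-state inference.** A discrete context variable with K ≥ 2
   states switches at Poisson-distributed times (default rate 1/50 per
   step). Each switch is announced only by a transient one-hot pulse
   (default 2 steps) on the cue channel of the newly active state; the
   network must report the active state persistently between pulses
   through a K-way softmax readout.

Velocity statistics: per sequence, a mean velocity is drawn from
Normal(0, 0.1 rad/step); per step, Normal(0, 0.3 rad/step) noise is added.
In the evaluation regime the speed is the absolute value of that sum (so
the track is traversed repeatedly in one direction), the initial position
is 0, and cues arrive at the rarer rate 1/500 — giving sessions that look
like trialized recordings: repeated track traversals, occasionally
interrupted by a context switch.

Two conventions the task statement leaves open are fixed as follows:

- **Initial state observability.** The initial state (uniform over K) is
  itself cued by a pulse at t = 0. Without this the state is undecodable
  before the first switch and the task ill-posed.
- **Pulse collisions.** A Poisson event landing inside an active pulse is
  deferred to the step after that pulse ends, so every pulse lasts exactly
  its nominal duration.
- **Traversals.** A traversal is complete when cumulative unwrapped
  position has advanced by a further 2π; the trailing partial traversal of
  each evaluation sequence is dropped. In 2D the per-dimension velocity
  statistics are sampled independently.

## The model

A rectified Elman network, treated throughout as a discrete-time dynamical
system:

    x_{t+1} = ReLU(A x_t + B u_t + β),   y_t = C x_t + α,   x_0 = D z + γ

with N hidden units (248 at full scale), M = D + K inputs, L = 2D + K
outputs, and z the (sin, cos) encoding of the initial position. All seven
parameter groups initialize i.i.d. Uniform(−1/√N, 1/√N). The bias γ is a
length-N vector (dimensional consistency of x_0 = Dz + γ requires it). The
first 2D rows of C — the position readout W — play a special role in the
geometry analyses: remapping that lives in the nullspace of W is invisible
to the position decoder.

## Training

The loss is the unweighted sum of the position MSE over all steps and
sin/cos channels and the mean per-step cross-entropy of the state logits.
Sequences start at length 1 and grow by one step every `curriculum_step`
updates (50 at full scale) up to `max_seq_len` (600); the global gradient
norm is clipped to 2; batches hold 124 sequences. Gradients are computed by
explicit backpropagation through time in NumPy (the ReLU subgradient at
exactly 0 is taken as 0) and verified against central finite differences to
~1e-10 in the tests.

The optimizer and step size are deliberately exposed: the reference
procedure specifies only "stochastic gradient descent". Plain SGD solves
the state-inference component readily but, at the reduced scale this
package runs at, leaves the position readout far from the attractor
regime. The default recipe therefore uses Adam with a linearly decayed
step size (5e-3 → 2e-4), chosen by a small pilot sweep; any optimizer
reaching the performance regime is acceptable and plain SGD (with optional
momentum) remains available.

**Reduced scale.** The package's own analyses, tests, and the acceptance
script run a reduced configuration: N = 64 units, 5,000 updates, curriculum
step 33, lengths capped at 150. This configuration reaches 100% state
accuracy (excluding cue-pulse steps, when the state is in transition) and
mean circular position error of ~7–11° after 300 steps across seeds —
the same qualitative regime as the full-scale model (8.13° ± 0.51°), in a
few minutes on one CPU. The full-scale configuration remains available
through the same API and the `ringremap train` CLI.

## Session analysis

Evaluation sessions concatenate 50 truncated eval-mode sequences. Hidden
activity is binned by position (bins half-open on [0, 2π), bin 0 starting
at 0) in three standard resolutions: 50 bins for trialized displays,
manifold estimates and misalignment, 80 for trial-correlation matrices,
250 for subspace estimation. Per-trial binned rates label each traversal
by its predominant latent state (ties break toward the state active
earlier). Bins a traversal never visited are filled by circular linear
interpolation — at the default velocity statistics a traversal lasts
~26 steps, so 50-bin single-trial maps rely on interpolation by design;
per-map tuning curves pool all session samples and are dense. k-means map
assignment (scikit-learn, fixed seed, 10 restarts) recovers the
ground-truth labels on ≥99% of trials in trained models; the trial
stability filter drops trials whose mean correlation with same-map trials
falls below 0.25. Single-unit scores smooth each map's tuning with a
circular Gaussian (σ = 2 bins) and report the percent change in peak rate
and 1 − cosine similarity of the curves.

## Geometry

**Misalignment.** Both P×N manifolds are mean-centered and scaled to unit
Frobenius norm; the observed RMSE is compared with the RMSE after the best
proper rotation (Kabsch; reflections excluded by default) and normalized
against a Haar random-rotation null:
score = (RMSE_obs − RMSE_opt) / (q_0.25(null) − RMSE_opt), so 0 means
optimally aligned and 1 means indistinguishable from the p = 0.25 quantile
of random rotations. The quantile-referenced and mean-null-referenced
normalizations are both computed (the reference literature is ambiguous
between them); the quantile version is the default and the null
distribution is stored so either can be read off.

**Remapping vectors.** ξ_p = x_p(2) − x_p(1) per position bin; v = ⟨ξ_p⟩;
per-bin deviation ‖ξ_p − v‖ / ⟨‖ξ_p‖⟩ (the normalization by the mean
remapping-vector norm is a documented choice; dividing by ‖v‖ is nearly
identical for aligned maps). Two nulls accompany the analysis:

- *Deviation null*: map 2 is rotated about its centroid by
  Z O Zᵀ + (I − Z Zᵀ), with Z an orthonormal basis of null(W) and O Haar
  on SO(N−2D). This explores exactly the decoding-compatible
  misalignments (W x is preserved for every point) and is compared with
  the observed deviations at the p = 0.025 quantile.
- *W-residual null*: the same construction with unrestricted Haar
  rotations. Note that the nullspace-restricted rotation preserves W ξ_p
  identically, so only an unrestricted rotation provides a meaningful
  reference for |W ξ_p|.

At the reduced scale, mean |W ξ_p| settles around 0.1 (against a
full-rotation null of ~1.0): the residual is dominated by small systematic
per-map differences in readout gain and phase (~1%, equivalently a few
degrees of decoded position) of the imperfectly trained small model, and
does not shrink with longer sessions. It shrinks with training quality —
the orders-of-magnitude smaller residuals reported for full-scale models
should not be expected from the reduced configuration.

**Subspaces.** The position subspace is the top-2 PCA plane of the
250-bin tuning; for the across-maps variant each map is first centered on
its own centroid, so the between-map translation cannot leak into the
plane (this makes the construction "translation-only remapping is
orthogonal to the position subspace" exact). The remapping dimension is
the unit vector between map centroids. Cosine similarity of a vector to a
subspace is the norm of its orthogonal projection divided by its norm;
alignment between two subspaces is the cosine of their smallest principal
angle. With K ≥ 3 maps, pairwise remapping-dimension angles are reported
as acute angles arccos |cos| — ideal values: 60° for all pairs of an
equilateral triangle (K = 3); 60°/90° for vertex-sharing/opposite edge
pairs of a regular tetrahedron (K = 4).

## Dynamics

Approximate fixed points of the zero-input map x → ReLU(A x + β) are
found by minimizing ½‖x − ReLU(Ax + β)‖² from many seeds in parallel
(Adam with decaying step), shortlisting candidates below 1e-2 residual,
polishing each with L-BFGS, keeping residuals below 1e-6, and merging
points closer than 0.01. Seeds mix visited hidden states (plus isotropic
noise) with convex mixtures of cross-map state pairs; the mixtures are
what populate the saddle region between the rings, which is unreachable
from on-manifold seeds.

The Jacobian at a fixed point is A with the rows of inactive units zeroed
(pre-activation exactly 0 counts as inactive). Points are classified by
spectral radius ρ: marginally stable for ρ ∈ [0.95, 1.05] (the integrator
signature), unstable above, contracting below; the cutoff values are a
documented default, not a reported quantity. Each point gets a remapping
coordinate: the signed projection onto the centroid-difference axis scaled
so the two map centroids sit at ∓1. Principal-eigenvector alignments use
the real eigenvector, or the 2D real span of a complex pair.

At the reduced scale the census saturates: with thousands of seeds at
several noise levels, ~600 polished candidates collapse onto ~64 isolated
fixed points — the count is limited by the network (it grows with N and
training quality), not by the finder. The reduced model's ring points also
have spectral radii spreading up to ~1.1, so a minority of on-ring points
cross the 1.05 cutoff and are classed unstable; the intermediate saddles
themselves all sit between the rings and funnel perturbations along their
principal eigenvector to the two ring attractors.

## What the synthetic task does and does not emulate

The generator reproduces the statistical structure of the modeled
experiment — repeated traversals of an unchanging circular track with
rare, abrupt, population-wide context switches — but none of the
biological nuisances: no spiking noise, no probe drift, no behavioral
covariates (running speed enters only as the integrated velocity), no
landmark or reward structure. Passing tests therefore show that the
analysis chain recovers planted or emergent structure from clean rate
data; they do
not certify performance on recorded spike trains, although every session
operation accepts generic trials × bins × units tensors.

## Numerical conventions

- Angles are stored in [0, 2π) and reported in degrees where human-read.
- atan2(0, 0) decodes to 0 (degenerate, untrained networks only).
- Zero-variance trials correlate 0 by convention (warned).
- A unit silent in both maps scores (0, 0) and is flagged.
- All randomness flows through seeded `numpy.random.Generator`s; the same
  seed reproduces batches, training, and analyses bit-for-bit.
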