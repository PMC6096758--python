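# Methods

`lvreg` registers a 3D left-ventricle (LV) model to a single 2D X-ray
projection by an artificial agent that repeatedly takes the most
promising small in-plane move.  This note describes the model, the
numerical choices and the synthetic study conditions the package ships
with, and what the tests do and do not establish.

## Registration model

The pose search space is restricted to the three in-plane degrees of
freedom of the imaging plane: horizontal translation `tx` (mm), vertical
translation `ty` (mm) and rotation `rz` (degrees) about the projection
axis through the LV centre.  Depth is assumed approximately correct
after isocentring, and cardiac/respiratory motion is out of scope, so
out-of-plane parameters are not modelled.  Because the rotation pivots
at the model centre *after* the current translation, transform
parameters compose additively and the parameter-wise negation is the
exact inverse.

Two images describe a state:

* **fixed** — a digitally reconstructed radiograph (DRR) of the whole
  volume, 300 mm x 300 mm field of view;
* **moving** — a projection of the binary LV mask, 120 mm x 120 mm,
  rendered with the (transformed) LV centre both at the image centre and
  at the centre of projection.

Keeping the moving image LV-centred means translations do not change it
at all — they only select a different 120 mm subwindow (ROI) of the
fixed image.  The agent always compares the moving image with the ROI at
the current transform.  The registration loop exploits this by caching
moving images per rotation angle.

All images are sampled on a grid in the *isocentre plane* (the plane
through the centre of projection perpendicular to the projection axis),
so fixed and moving pixels are commensurable in mm with no
magnification bookkeeping.  The C-arm pose is parameterised by the
primary (LAO/RAO, about the patient's longitudinal axis) and secondary
(cranial/caudal, about the lateral axis) angles, composed
primary-then-secondary.

### DRR rendering

Pixels are perspective line integrals of attenuation.  The production
path is an exact Siddon-style voxel traversal: each ray is clipped to
the volume box and walked voxel by voxel, accumulating `mu * chord`.
This is the exact integral of the piecewise-constant voxel model, which
a brute-force per-voxel ray-box oracle (`lvreg.validation.drr_oracle`)
confirms to ~1e-6 % per pixel.  A dense-sampling trilinear integrator
(step = half the smallest voxel spacing, composite trapezoid) is kept as
a pure-NumPy fallback; it is approximate near voxel edges.  DRR
intensities are raw line integrals — no film/exponential model — which
is benign because only gradients and standardised intensities are
consumed downstream.  Moving-image pixels are mask thickness (mm),
normalised to [0, 1].

## The imitation-learning agent

The Markov decision process has six actions: one +/- step per degree of
freedom (defaults 1 mm, 1 degree; configurable).  The reward of an
action is the decrease of the transformation distance to the ground
truth,

    r = D(T_g, T_t) - D(T_g, T_{t+1}),
    D(T_1, T_2) = sqrt(dtx^2 + dty^2 + (w * drz)^2),

with `w` = 1 mm/degree by default so that a degree counts as a
millimetre — a sensible scaling given the 35 mm / 15 degree perturbation
ranges; `w` is configurable.  A discount factor `gamma` belongs to the
MDP definition and is carried in the configuration, but the supervised
target is the per-step reward itself, so `gamma` is inert.

The network is a pair of unshared convolutional encoders (fixed ROI and
moving image) whose features are concatenated and decoded by fully
connected layers into the six rewards.  Each encoder: four 3x3
convolutions, each followed by ReLU, 2x2 max pooling and batch
normalisation (internally the pool runs before the ReLU, which is
mathematically identical for monotone activations and cheaper).  The
reference shape is 128x128 inputs, 32-32-64-64 channels, 256-128-64-6
decoder; the default is the CPU-scale reduction 64x64 / 4-8-16-16 /
128-64-32-6, chosen so that a full training run fits in minutes on one
core.  Both shapes are available via `AgentConfig`.

Training minimises the mean-squared error of the 6-vector of rewards
(labels in raw D-units) with RMSProp: minibatch 80, learning rate 0.01
decayed by 0.8 every 10,000 iterations, momentum 0.9.  The optimiser
uses heavy-ball momentum 0.9 on the RMS-normalised step and the same
0.9 as the squared-gradient smoothing constant; a global gradient-norm
clip of 10 guards the early iterations at this relatively hot learning
rate.  Batch ordering is seed-deterministic.  The layers themselves are
implemented in NumPy with numba kernels for the convolution/pooling hot
paths (a pure-NumPy fallback mirrors them); gradients are verified
against central finite differences in the test suite.

At test time the policy is greedy: predict rewards, take the argmax
(ties break to the lowest action index), re-render, repeat.  The loop
stops when the last four actions form two exact reversals (terminal
oscillation) or after `max_iterations` (200); on oscillation the final
state is the window state whose best predicted reward is smallest — the
state closest to "no move helps".  The ROI window leaving the fixed
field of view is recorded as divergence, never raised.

## Synthetic study conditions

The phantom generator stands in for contrasted chest CT.  Each phantom
(default 96^3 voxels at 2 mm) contains: a soft-tissue thorax (0.019/mm),
two lungs (0.012/mm), a contrasted-LV ellipsoid of 20 x 25 x 35 mm
semi-axes (0.023/mm) with seeded position jitter (8 mm) and tilt
(15 degrees), a spine-like cylinder (0.060/mm) and a liver-like dome
(0.030/mm).  The contrasts are deliberately calibrated so that the DRR
shows a *faint* heart shadow while the spine and the liver dome provide
the strongest gradients — the regime in which plain gradient metrics
fail by locking onto the confounders and their positive-gradient
variants recover, which is the behaviour the baseline comparison is
meant to exhibit.  Optional Gaussian attenuation noise defaults to 0.

Training perturbations are drawn uniformly: translations up to 35 mm
per component, rotation up to 15 degrees, a centre-of-projection offset
up to 10 mm (uniform direction, uniform magnitude), primary angulation
within +/-15 degrees and secondary within +/-5 degrees.  Ground truth is
the identity transform; the perturbed state's exact reward vector is the
training label, and labels are re-verifiable from the stored
perturbation.

What the phantom does **not** emulate: rib cages, texture/noise of real
detectors, contrast-agent inhomogeneity, anatomical variability beyond
affine jitter, or any motion.  Passing tests therefore demonstrate that
the mechanism works — rendering, reward learning, greedy convergence,
the baselines' failure mode — not that the trained network transfers to
clinical fluoroscopy.

## Gradient-based baselines

GC is the mean normalised cross-correlation of the x and y
central-difference derivative images; GI sums
`w(a) * min(|grad f|, |grad m|)` and GO averages `w(a)` over pixels
where both gradients exceed a noise floor of 1e-6 of the per-image
maximum magnitude, with the standard angular weighting
`w(a) = (cos 2a + 1)/2`.  The "+" variants clamp the negative gradient
components of the *fixed* image only: the competing spine/liver
gradients live in the fixed image, while the moving model projection
contains nothing but the LV, so discarding half of its edge information
only hurts.  (Clamping both images was evaluated and made GC+ register
worse than GC on these phantoms — the opposite of the intended
behaviour.)  The optimiser for the baselines is a deterministic
multi-resolution coordinate ascent with step schedule
8→4→2→1 mm / 4→2→2→1 degrees, chosen over stochastic optimisers for
reproducibility.

## Evaluation protocols

Accuracy uses the target registration error of a cross landmark: the LV
centre plus four endpoints 10 mm along the in-plane axes.  TRE is the
root-mean-square over the five points of the displacement between their
estimated- and ground-truth-transformed positions, evaluated in the
isocentre plane (which avoids detector-magnification ambiguity).
Tables report mean, population SD and the 50/60/70/80/90/100th
percentiles (linear interpolation between order statistics).

Robustness (no ground truth) perturbs the model on the regular
translation grid -30..30 mm at 5 mm sampling — 13 x 13 = 169
perturbations — with uniform random rotations in +/-15 degrees,
re-registers, and reports the deviations `e_f = ||x_f - median(x_f)||`
of the final projected landmark positions from their component-wise
median, plus the fraction below 5 mm, the 90th-percentile deviation and
the diverged count (diverged runs are excluded from the median).

## Problem sizes of the shipped experiments

The end-to-end learning experiment (`lvreg.experiments`) uses 40
phantoms (32 train / 8 held out), 50 perturbations per training phantom
(1,600 samples), 96 px fixed images, 64 px inputs, 3,000 training
iterations, and 40 held-out registrations — sizes chosen so the whole
run completes in a few minutes on a single core while still exercising
every stage of the pipeline.  Under these conditions the trained agent
typically reduces the mean held-out TRE to ~10% of its starting value
with >95% of cases improved; reproducing the full-scale published
accuracy would require hundreds of real CT volumes and GPU-scale
training, which is outside this package's scope.

## Known limitations

* Three in-plane degrees of freedom only; no depth, no deformation.
* The NumPy/numba network trains small models well but is not a
  general-purpose deep-learning stack (no GPU, no autodiff).
* Batch normalisation running statistics degenerate for one-sample
  batches (inherent to batch statistics; relevant only to contrived
  overfitting runs).
* The robustness protocol's median reference is the component-wise
  median of 2D positions, a declared convention.
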