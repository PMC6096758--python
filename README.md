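# lvreg

Registration of a 3D left-ventricle (LV) model to a single 2D X-ray
projection by an artificial agent.

In image-guided cardiac procedures (e.g. cardiac resynchronisation
therapy) a preoperative anatomical model — an LV segmentation from MR or
CT — must be overlaid on live X-ray fluoroscopy, where soft tissue is
barely visible.  `lvreg` implements a model-to-image approach: instead of
matching voxel intensities across modalities, a projection of the binary
LV model (the *moving* image) is aligned to the X-ray frame (the *fixed*
image) over the three in-plane degrees of freedom — translations
`t_x, t_y` (mm) and rotation `r_z` (degrees) about the projection axis.

The core is an imitation-learning agent.  Registration is cast as a
Markov decision process with six actions (a ± step per DOF).  The reward
of an action is the decrease of the transformation distance to the
ground truth,

    r_{t+1} = D(T_g, T_t) − D(T_g, T_{t+1}),

where `D` is the L2 norm of the parameter difference (degrees weighted
1 mm/°).  A pair of convolutional encoders embeds the fixed-image region
of interest and the moving image; a fully connected decoder predicts the
six rewards; training is supervised regression against the exact rewards
of randomly perturbed states.  At test time the agent greedily applies
the highest-reward action, re-renders, and repeats until the action
sequence oscillates.

The package also provides everything needed to study the method without
clinical data:

* a DRR renderer (exact Siddon voxel traversal) and the LV-centred
  moving-image/ROI rendering scheme (300 mm fixed / 120 mm moving FOV);
* a synthetic chest-phantom generator (faint heart shadow, spine- and
  liver-like confounders) with NIfTI I/O;
* gradient-based baseline metrics GC, GI, GO and their positive-gradient
  variants GC+, GI+, GO+ with a deterministic coordinate-ascent
  optimiser;
* cross-landmark TRE accuracy tables and a perturbation-grid robustness
  protocol (169 perturbations on a −30..30 mm / 5 mm grid);
* a `lvreg` command-line workbench (`phantom`, `trainset`, `train`,
  `register`, `evaluate`, `robustness`).

See `docs/methods.md` for the model details and numerical choices.

## Worked example

Greedy registration of a perturbed phantom case, driven here by the
exact-reward oracle policy (swap in a trained `RewardAgent.as_policy()`
for the learned agent):

```python
import numpy as np
from lvreg import (CArmGeometry, InPlaneTransform, MDPConfig, PhantomConfig,
                   compute_tre, generate_phantom, make_cross_landmark,
                   oracle_policy, register, render_drr)

volume, model = generate_phantom(PhantomConfig(shape=(48, 48, 48),
                                               spacing_mm=4.0, seed=7))
geometry = CArmGeometry().with_center(model.center)
fixed = render_drr(volume, geometry, size=96)

t_true = InPlaneTransform()                      # ground-truth alignment
t_start = InPlaneTransform(tx_mm=22.0, ty_mm=-14.0, rz_deg=9.0)
landmark = make_cross_landmark(model.center, arm_length_mm=10.0,
                               geometry=geometry)

cfg = MDPConfig(input_side=32)
policy = oracle_policy(t_true, cfg.actions)
traj = register(policy, fixed, model, geometry, t_start, cfg)

print(f"start TRE : {compute_tre(t_start, t_true, landmark, geometry):6.2f} mm")
print(f"final TRE : {compute_tre(traj.final, t_true, landmark, geometry):6.2f} mm")
print(f"iterations: {len(traj)}  stop: {traj.stop_reason}")
```

Output:

```
start TRE :  26.11 mm
final TRE :   0.00 mm
iterations: 50  stop: oscillation
```

The start TRE is the RMS displacement of the five cross-landmark points
(centre + 10 mm arms) under the perturbation; 50 greedy 1 mm / 1° steps
return the model exactly to the ground-truth pose, at which point the
actions begin to oscillate and the loop stops.

Training a learned agent end to end at CPU scale (40 phantoms, 1,600
samples, 3,000 iterations, a few minutes on one core):

```python
from lvreg.experiments import LearningExperimentConfig, run_learning_experiment

res = run_learning_experiment(LearningExperimentConfig(seed=1))
print(res.tre_start_mm.mean(), res.tre_final_mm.mean(), res.fraction_improved)
```

A typical run reduces the mean held-out TRE from ≈25 mm to ≈3 mm with
over 95% of cases improved.

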