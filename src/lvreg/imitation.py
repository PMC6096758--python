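"""MDP core: actions, rewards, perturbation sampling and the greedy agent loop.

The registration is cast as a Markov decision process.  A state is the
current in-plane transform of the LV model; the six actions step one
degree of freedom (tx, ty, rz) up or down by a fixed increment.  The
reward of an action is the improvement in the transformation distance to
the ground truth,

    r = D(T_g, T_t) - D(T_g, T_{t+1}),

positive exactly when the action moves the model closer to alignment.
Training is supervised imitation: the network is shown the (ROI, moving)
image pair of a perturbed state together with the exact reward vector of
that state, and at test time the greedy policy repeatedly takes the
action with the highest predicted reward.

A discount factor ``gamma`` is part of the MDP definition and is carried
in :class:`MDPConfig`, but the supervised target is the per-step reward
itself, so ``gamma`` does not enter training; it is exposed for
completeness only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .geometry import CArmGeometry, InPlaneTransform, transform_distance
from .phantom import AnatomyModel
from .projection import (
    CaptureRangeError,
    ProjectionImage,
    extract_roi,
    render_model_projection,
    resample_to_input,
)

__all__ = [
    "ActionSet",
    "RewardVector",
    "MDPConfig",
    "PerturbationSpec",
    "GeometryPerturbation",
    "TrainingSample",
    "Trajectory",
    "TrajectoryStep",
    "compute_rewards",
    "sample_perturbation",
    "build_training_set",
    "register",
    "oracle_policy",
]

log = logging.getLogger(__name__)

#: Callable signature of a reward-predicting policy.
Policy = Callable[[np.ndarray, np.ndarray, InPlaneTransform], np.ndarray]


@dataclass(frozen=True)
class ActionSet:
    """Six actions: one +/- step per degree of freedom.

    Order: tx+, tx-, ty+, ty-, rz+, rz-.
    """

    step_t_mm: float = 1.0
    step_r_deg: float = 1.0

    def __post_init__(self) -> None:
        if self.step_t_mm <= 0 or self.step_r_deg <= 0:
            raise ValueError("action steps must be > 0")

    def __len__(self) -> int:
        return 6

    @property
    def deltas(self) -> list[tuple[int, float]]:
        """(dof index, signed step) per action, in action order."""
        return [
            (0, +self.step_t_mm),
            (0, -self.step_t_mm),
            (1, +self.step_t_mm),
            (1, -self.step_t_mm),
            (2, +self.step_r_deg),
            (2, -self.step_r_deg),
        ]

    def apply(self, t: InPlaneTransform, action: int) -> InPlaneTransform:
        dof, delta = self.deltas[action]
        return t.step(dof, delta)

    def inverse_action(self, action: int) -> int:
        return action ^ 1  # +/- pairs are adjacent

    def labels(self) -> list[str]:
        return ["tx+", "tx-", "ty+", "ty-", "rz+", "rz-"]


@dataclass(frozen=True)
class RewardVector:
    """Per-action rewards aligned with :class:`ActionSet` order."""

    rewards: np.ndarray  # (6,)

    def __post_init__(self) -> None:
        r = np.asarray(self.rewards, dtype=float).reshape(6)
        if not np.all(np.isfinite(r)):
            raise ValueError("rewards must be finite")
        object.__setattr__(self, "rewards", r)

    def argmax(self) -> int:
        """Index of the best action; ties break to the lowest index."""
        return int(np.argmax(self.rewards))


@dataclass
class MDPConfig:
    """Agent loop configuration."""

    actions: ActionSet = field(default_factory=ActionSet)
    gamma: float = 0.9  # part of the MDP definition; unused by training
    rot_weight: float = 1.0  # mm per degree inside D
    max_iterations: int = 200
    input_side: int = 64

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must be in [0, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class GeometryPerturbation:
    """Per-sample C-arm variation: COP offset and angulation."""

    cop_offset_mm: np.ndarray  # (3,)
    primary_angle_deg: float
    secondary_angle_deg: float

    def apply(self, geometry: CArmGeometry, model_center: np.ndarray) -> CArmGeometry:
        from dataclasses import replace

        return replace(
            geometry,
            primary_angle_deg=self.primary_angle_deg,
            secondary_angle_deg=self.secondary_angle_deg,
            center_of_projection=np.asarray(model_center, float)
            + self.cop_offset_mm,
        )


@dataclass(frozen=True)
class PerturbationSpec:
    """Ranges of the training perturbations.

    Defaults follow the training protocol: translations up to 35 mm per
    component, rotation up to 15 degrees, a random centre-of-projection
    offset of up to 10 mm, primary angulation within +/-15 degrees and
    secondary within +/-5 degrees.  All components are drawn uniformly.
    """

    max_translation_mm: float = 35.0
    max_rotation_deg: float = 15.0
    max_cop_offset_mm: float = 10.0
    primary_range_deg: float = 15.0
    secondary_range_deg: float = 5.0

    def __post_init__(self) -> None:
        for name in (
            "max_translation_mm",
            "max_rotation_deg",
            "max_cop_offset_mm",
            "primary_range_deg",
            "secondary_range_deg",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TrainingSample:
    """One supervised sample: image pair, reward label and provenance."""

    fixed_roi: np.ndarray  # (side, side) standardised
    moving: np.ndarray  # (side, side) standardised
    label: RewardVector
    phantom_seed: int
    perturbation: InPlaneTransform
    geometry_perturbation: GeometryPerturbation


@dataclass
class TrajectoryStep:
    iteration: int
    transform: InPlaneTransform
    action: int | None  # action taken FROM this state (None at the end)
    rewards: np.ndarray | None
    tre_mm: float | None = None


@dataclass
class Trajectory:
    """Recorded greedy-registration run."""

    steps: list[TrajectoryStep] = field(default_factory=list)
    final: InPlaneTransform | None = None
    diverged: bool = False
    stop_reason: str = ""

    def transforms(self) -> list[InPlaneTransform]:
        return [s.transform for s in self.steps]

    def __len__(self) -> int:
        return len(self.steps)


def compute_rewards(
    t_g: InPlaneTransform,
    t_t: InPlaneTransform,
    actions: ActionSet,
    rot_weight: float = 1.0,
) -> RewardVector:
    """Exact reward vector of a state: D(T_g, T_t) - D(T_g, T_t o a)."""
    d0 = transform_distance(t_g, t_t, rot_weight)
    r = np.empty(6)
    for i in range(6):
        d1 = transform_distance(t_g, actions.apply(t_t, i), rot_weight)
        r[i] = d0 - d1
    return RewardVector(rewards=r)


def oracle_policy(
    t_g: InPlaneTransform,
    actions: ActionSet,
    rot_weight: float = 1.0,
) -> Policy:
    """Ground-truth reward predictor (exact rewards for any state).

    Used as the imitation target and to validate the greedy loop
    independently of any learning.
    """

    def policy(fixed_roi, moving, t: InPlaneTransform) -> np.ndarray:
        return compute_rewards(t_g, t, actions, rot_weight).rewards

    return policy


def sample_perturbation(
    spec: PerturbationSpec, rng: np.random.Generator
) -> tuple[InPlaneTransform, GeometryPerturbation]:
    """Draw one training perturbation (transform + geometry variation).

    Translation components and the rotation are uniform within their
    ranges; the COP offset is a uniformly-oriented 3D vector with uniform
    magnitude up to the maximum.
    """
    t = InPlaneTransform(
        tx_mm=float(rng.uniform(-spec.max_translation_mm, spec.max_translation_mm)),
        ty_mm=float(rng.uniform(-spec.max_translation_mm, spec.max_translation_mm)),
        rz_deg=float(rng.uniform(-spec.max_rotation_deg, spec.max_rotation_deg)),
    )
    direction = rng.normal(size=3)
    nrm = np.linalg.norm(direction)
    direction = direction / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
    offset = direction * rng.uniform(0.0, spec.max_cop_offset_mm)
    geo = GeometryPerturbation(
        cop_offset_mm=offset,
        primary_angle_deg=float(
            rng.uniform(-spec.primary_range_deg, spec.primary_range_deg)
        ),
        secondary_angle_deg=float(
            rng.uniform(-spec.secondary_range_deg, spec.secondary_range_deg)
        ),
    )
    return t, geo


def build_training_set(
    phantoms: Sequence[tuple["object", AnatomyModel, int]],
    spec: PerturbationSpec,
    per_volume: int,
    actions: ActionSet,
    rot_weight: float = 1.0,
    seed: int = 0,
    input_side: int = 64,
    fixed_size: int = 96,
    fixed_fov_mm: float = 300.0,
    moving_fov_mm: float = 120.0,
    base_geometry: CArmGeometry | None = None,
) -> list[TrainingSample]:
    """Generate supervised training samples from phantom volumes.

    For each phantom, ``per_volume`` perturbations are drawn; the fixed
    DRR is rendered with the per-sample C-arm variation (ground truth at
    the identity transform), the ROI and moving image are rendered at the
    perturbed state, and the label is the exact reward vector of that
    state.  Samples whose ROI leaves the fixed FOV are rejected and
    redrawn (logged).

    ``phantoms`` is a sequence of (AttenuationVolume, AnatomyModel, seed)
    triples; the seed is recorded as provenance.
    """
    from .projection import render_drr

    if per_volume < 1:
        raise ValueError("per_volume must be >= 1")
    rng = np.random.default_rng(seed)
    base = base_geometry if base_geometry is not None else CArmGeometry()
    samples: list[TrainingSample] = []
    moving_size = input_side  # render the moving image at input resolution
    for volume, model, ph_seed in phantoms:
        produced = 0
        while produced < per_volume:
            t_pert, geo_pert = sample_perturbation(spec, rng)
            geometry = geo_pert.apply(base, model.center)
            fixed = render_drr(volume, geometry, fov_mm=fixed_fov_mm, size=fixed_size)
            try:
                roi = extract_roi(
                    fixed,
                    t_pert,
                    geometry,
                    model_center=model.center,
                    fov_mm=moving_fov_mm,
                    size=input_side,
                )
            except CaptureRangeError:
                log.info(
                    "rejected out-of-range perturbation %s (phantom %d)",
                    t_pert,
                    ph_seed,
                )
                continue
            moving = render_model_projection(
                model,
                t_pert,
                geometry,
                fov_mm=moving_fov_mm,
                size=moving_size,
            )
            label = compute_rewards(
                InPlaneTransform(), t_pert, actions, rot_weight
            )
            samples.append(
                TrainingSample(
                    fixed_roi=resample_to_input(roi, input_side),
                    moving=resample_to_input(moving, input_side),
                    label=label,
                    phantom_seed=ph_seed,
                    perturbation=t_pert,
                    geometry_perturbation=geo_pert,
                )
            )
            produced += 1
    return samples


def _oscillating(actions_taken: list[int], actions: ActionSet) -> bool:
    """Last four actions form two exact reversals (a, inv a, a, inv a)."""
    if len(actions_taken) < 4:
        return False
    a, b, c, d = actions_taken[-4:]
    return a == c and b == d and b == actions.inverse_action(a)


def register(
    policy: Policy,
    fixed: ProjectionImage,
    model: AnatomyModel,
    geometry: CArmGeometry,
    t0: InPlaneTransform,
    cfg: MDPConfig,
    moving_fov_mm: float = 120.0,
) -> Trajectory:
    """Greedy iterative registration.

    At each iteration the moving image and the fixed-image ROI of the
    current state are rendered, the policy predicts the six action
    rewards, and the highest-reward action (ties to the lowest index) is
    applied.  The loop stops when the last four actions form two exact
    reversals (terminal oscillation) or at ``max_iterations``; on
    oscillation the final state is the window state whose best predicted
    reward is smallest.  Leaving the fixed FOV is recorded as divergence,
    not raised.

    Moving images are cached per rotation angle: in-plane translations
    re-centre the model, so only ``rz`` changes the moving image.
    """
    traj = Trajectory()
    t = t0
    actions_taken: list[int] = []
    moving_cache: dict[float, np.ndarray] = {}
    input_side = cfg.input_side

    def moving_input(t: InPlaneTransform) -> np.ndarray:
        key = round(float(t.rz_deg), 9)
        if key not in moving_cache:
            mv = render_model_projection(
                model, t, geometry, fov_mm=moving_fov_mm, size=input_side
            )
            moving_cache[key] = resample_to_input(mv, input_side)
        return moving_cache[key]

    for it in range(cfg.max_iterations):
        try:
            roi = extract_roi(
                fixed,
                t,
                geometry,
                model_center=model.center,
                fov_mm=moving_fov_mm,
                size=input_side,
            )
        except CaptureRangeError:
            traj.diverged = True
            traj.stop_reason = "left fixed field of view"
            traj.final = t
            return traj
        roi_in = resample_to_input(roi, input_side)
        mov_in = moving_input(t)
        rewards = np.asarray(policy(roi_in, mov_in, t), dtype=float)
        action = int(np.argmax(rewards))
        traj.steps.append(TrajectoryStep(it, t, action, rewards))
        actions_taken.append(action)
        t = cfg.actions.apply(t, action)
        if _oscillating(actions_taken, cfg.actions):
            window = traj.steps[-4:]
            best = min(window, key=lambda s: float(np.max(s.rewards)))
            traj.final = best.transform
            traj.stop_reason = "oscillation"
            traj.steps.append(TrajectoryStep(len(traj.steps), t, None, None))
            return traj
    traj.steps.append(TrajectoryStep(len(traj.steps), t, None, None))
    traj.final = t
    traj.stop_reason = "max_iterations"
    return traj
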