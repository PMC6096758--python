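"""Gradient-based similarity metrics and a deterministic local optimiser.

The comparison arm of the framework: gradient correlation (GC), gradient
information (GI) and gradient orientation (GO), plus their "positive
gradients only" variants (GC+, GI+, GO+).  The positive variants clamp
the negative derivative components of the *fixed* image to zero before
the metric is evaluated: in chest projections the positive gradients
correspond mainly to the visible heart shadow, which suppresses the
tendency of the plain metrics to lock onto the spine or the liver dome
(the strongest gradients in a DRR).  The moving image contains only the
LV model, so its full gradient field is always used.

GI and GO use the angular weighting ``w(a) = (cos(2a) + 1) / 2`` of the
gradient-information literature, where ``a`` is the angle between the two
gradient vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .geometry import CArmGeometry, InPlaneTransform
from .phantom import AnatomyModel
from .projection import (
    CaptureRangeError,
    ProjectionImage,
    extract_roi,
    render_model_projection,
)

__all__ = [
    "GradientField",
    "gradient_field",
    "gc",
    "gi",
    "go",
    "METRICS",
    "get_metric",
    "optimize_metric",
]


@dataclass
class GradientField:
    """Per-pixel image gradient: components, magnitude and orientation."""

    gx: np.ndarray
    gy: np.ndarray

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.gx, self.gy)

    @property
    def orientation(self) -> np.ndarray:
        return np.arctan2(self.gy, self.gx)


def gradient_field(image: np.ndarray, positive_only: bool = False) -> GradientField:
    """Central-difference gradient (one-sided at borders).

    With ``positive_only`` the negative derivative components are clamped
    to zero before magnitude/orientation are derived.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 2:
        raise ValueError("image must be at least 2x2")
    gy, gx = np.gradient(img)  # rows (y), cols (x)
    if positive_only:
        gx = np.clip(gx, 0.0, None)
        gy = np.clip(gy, 0.0, None)
    return GradientField(gx=gx, gy=gy)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalised cross-correlation; 0 when either channel has no variance."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def gc(fixed_roi: np.ndarray, moving: np.ndarray, positive_only: bool = False) -> float:
    """Gradient correlation: mean NCC of the x and y derivative images.

    ``positive_only`` clamps the fixed image's negative gradients (GC+).
    """
    f = gradient_field(fixed_roi, positive_only)
    m = gradient_field(moving, False)
    return 0.5 * (_ncc(f.gx, m.gx) + _ncc(f.gy, m.gy))


def _angle_weight(f: GradientField, m: GradientField) -> np.ndarray:
    """w(a) = (cos 2a + 1)/2 with a the angle between gradient vectors."""
    dot = f.gx * m.gx + f.gy * m.gy
    mf, mm = f.magnitude, m.magnitude
    denom = mf * mm
    cos_a = np.zeros_like(denom)
    ok = denom > 0
    cos_a[ok] = np.clip(dot[ok] / denom[ok], -1.0, 1.0)
    # cos(2a) = 2 cos^2 a - 1  =>  w = cos^2 a
    return np.where(ok, cos_a**2, 0.0)


def gi(fixed_roi: np.ndarray, moving: np.ndarray, positive_only: bool = False) -> float:
    """Gradient information: sum of w(a) * min(|grad f|, |grad m|).

    ``positive_only`` clamps the fixed image's negative gradients (GI+).
    """
    f = gradient_field(fixed_roi, positive_only)
    m = gradient_field(moving, False)
    w = _angle_weight(f, m)
    return float((w * np.minimum(f.magnitude, m.magnitude)).sum())


def go(fixed_roi: np.ndarray, moving: np.ndarray, positive_only: bool = False) -> float:
    """Gradient orientation: mean w(a) where both gradients are non-negligible.

    The noise floor is 1e-6 of each image's maximum gradient magnitude;
    returns 0 if no pixel qualifies.  ``positive_only`` clamps the fixed
    image's negative gradients (GO+).
    """
    f = gradient_field(fixed_roi, positive_only)
    m = gradient_field(moving, False)
    mf, mm = f.magnitude, m.magnitude
    eligible = (mf > 1e-6 * mf.max()) & (mm > 1e-6 * mm.max()) if mf.max() > 0 and mm.max() > 0 else np.zeros_like(mf, bool)
    if not eligible.any():
        return 0.0
    return float(_angle_weight(f, m)[eligible].mean())


#: Metric registry keyed by the standard row labels.
METRICS: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
    "gc": lambda f, m: gc(f, m, False),
    "gc+": lambda f, m: gc(f, m, True),
    "gi": lambda f, m: gi(f, m, False),
    "gi+": lambda f, m: gi(f, m, True),
    "go": lambda f, m: go(f, m, False),
    "go+": lambda f, m: go(f, m, True),
}


def get_metric(name: str) -> Callable[[np.ndarray, np.ndarray], float]:
    try:
        return METRICS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown metric {name!r}; choose from {sorted(METRICS)}"
        ) from None


def optimize_metric(
    metric: Callable[[np.ndarray, np.ndarray], float] | str,
    fixed: ProjectionImage,
    model: AnatomyModel,
    geometry: CArmGeometry,
    t0: InPlaneTransform,
    step_schedule: tuple[tuple[float, float], ...] = (
        (8.0, 4.0),
        (4.0, 2.0),
        (2.0, 1.0),
        (1.0, 1.0),
    ),
    moving_fov_mm: float = 120.0,
    image_size: int = 64,
) -> tuple[InPlaneTransform, float]:
    """Multi-resolution coordinate hill climb maximising a similarity metric.

    At each (translation step, rotation step) stage of the schedule,
    coordinate ascent tries +/- moves on each degree of freedom until no
    single move improves the metric, then the steps are refined.  Fully
    deterministic.  Moves that would leave the fixed FOV are skipped
    (the search is clipped to the capture range).

    Returns the best transform and its metric value; the value is never
    below the value at ``t0``.
    """
    fn = get_metric(metric) if isinstance(metric, str) else metric

    moving_cache: dict[float, np.ndarray] = {}

    def moving_for(t: InPlaneTransform) -> np.ndarray:
        key = round(float(t.rz_deg), 9)
        if key not in moving_cache:
            moving_cache[key] = render_model_projection(
                model, t, geometry, fov_mm=moving_fov_mm, size=image_size
            ).pixels.astype(float)
        return moving_cache[key]

    def score(t: InPlaneTransform) -> float | None:
        try:
            roi = extract_roi(
                fixed,
                t,
                geometry,
                model_center=model.center,
                fov_mm=moving_fov_mm,
                size=image_size,
            ).pixels.astype(float)
        except CaptureRangeError:
            return None
        return fn(roi, moving_for(t))

    best_t = t0
    best_s = score(t0)
    if best_s is None:
        raise CaptureRangeError("starting transform outside the capture range")

    for step_t, step_r in step_schedule:
        improved = True
        while improved:
            improved = False
            for dof, step in ((0, step_t), (1, step_t), (2, step_r)):
                for sign in (+1.0, -1.0):
                    cand = best_t.step(dof, sign * step)
                    s = score(cand)
                    if s is not None and s > best_s:
                        best_t, best_s = cand, s
                        improved = True
    return best_t, float(best_s)
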