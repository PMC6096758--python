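"""Projective C-arm geometry and in-plane rigid transforms.

Coordinate conventions
----------------------
World coordinates are in millimetres, right-handed, with patient axes

* ``x`` — lateral (towards the patient's left),
* ``y`` — anterior (towards the front of the patient),
* ``z`` — longitudinal (towards the head).

The C-arm pose is described by two gantry angles.  The *primary* angle
(LAO/RAO) rotates the imaging chain about the patient's longitudinal axis
``z``; the *secondary* angle (cranial/caudal) rotates it about the lateral
axis ``x``.  The rotations are composed primary-then-secondary.  In the
neutral anterior-posterior pose the projection direction (source towards
detector) is ``+y``, the detector horizontal axis is ``+x`` and the
detector vertical axis is ``+z``.

Image fields of view are expressed in the *isocentre plane*: the plane
through the centre of projection perpendicular to the projection axis.
Every detector pixel corresponds to the perspective ray from the X-ray
source through a point of a regular grid in that plane, which makes fixed
and moving images magnification-free and directly comparable.

The registration search space is restricted to the three in-plane degrees
of freedom: horizontal translation ``tx``, vertical translation ``ty``
(both in mm, along the detector axes) and a rotation ``rz`` (degrees)
about the projection axis through the model centre.  Because the rotation
pivots at the model centre *after* the current translation, transform
parameters compose additively and the inverse is the parameter-wise
negation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "CArmGeometry",
    "InPlaneTransform",
    "CrossLandmark",
    "transform_distance",
    "apply_transform",
    "make_cross_landmark",
    "compute_tre",
    "angular_error",
]


def _rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class CArmGeometry:
    """C-arm pose and source geometry.

    Parameters
    ----------
    primary_angle_deg:
        LAO (positive) / RAO (negative) angulation, degrees.
    secondary_angle_deg:
        Cranial (positive) / caudal (negative) angulation, degrees.
    source_to_isocenter_mm:
        Distance from the X-ray source to the centre of projection.
    isocenter_to_detector_mm:
        Distance from the centre of projection to the physical detector
        (metadata only: images are sampled in the isocentre plane).
    center_of_projection:
        World point (mm) the central ray passes through; for the moving
        image this is the current model centre.
    """

    primary_angle_deg: float = 0.0
    secondary_angle_deg: float = 0.0
    source_to_isocenter_mm: float = 750.0
    isocenter_to_detector_mm: float = 450.0
    center_of_projection: np.ndarray = field(
        default_factory=lambda: np.zeros(3)
    )

    def __post_init__(self) -> None:
        if self.source_to_isocenter_mm <= 0:
            raise ValueError("source_to_isocenter_mm must be > 0")
        if self.isocenter_to_detector_mm < 0:
            raise ValueError("isocenter_to_detector_mm must be >= 0")
        object.__setattr__(
            self,
            "center_of_projection",
            np.asarray(self.center_of_projection, dtype=float).reshape(3),
        )

    @property
    def rotation(self) -> np.ndarray:
        """World rotation of the imaging chain (primary then secondary)."""
        return _rot_x(self.secondary_angle_deg) @ _rot_z(self.primary_angle_deg)

    @property
    def direction(self) -> np.ndarray:
        """Unit projection direction, source towards detector."""
        return self.rotation @ np.array([0.0, 1.0, 0.0])

    @property
    def axis_u(self) -> np.ndarray:
        """Unit in-plane horizontal axis of the detector."""
        return self.rotation @ np.array([1.0, 0.0, 0.0])

    @property
    def axis_v(self) -> np.ndarray:
        """Unit in-plane vertical axis of the detector."""
        return self.rotation @ np.array([0.0, 0.0, 1.0])

    @property
    def source(self) -> np.ndarray:
        """World position of the X-ray source."""
        return self.center_of_projection - self.source_to_isocenter_mm * self.direction

    def with_center(self, center: np.ndarray) -> "CArmGeometry":
        """Same pose with the centre of projection moved to ``center``."""
        return replace(self, center_of_projection=np.asarray(center, float))

    def plane_coords(self, points: np.ndarray) -> np.ndarray:
        """Perspective-project world points into isocentre-plane (x, y) mm.

        Each point is projected along the ray from the source onto the
        plane through the centre of projection perpendicular to the
        projection axis.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        s, d = self.source, self.direction
        denom = (pts - s) @ d
        lam = ((self.center_of_projection - s) @ d) / denom
        proj = s + lam[:, None] * (pts - s)
        rel = proj - self.center_of_projection
        return np.stack([rel @ self.axis_u, rel @ self.axis_v], axis=-1)

    def to_dict(self) -> dict:
        return {
            "primary_angle_deg": float(self.primary_angle_deg),
            "secondary_angle_deg": float(self.secondary_angle_deg),
            "source_to_isocenter_mm": float(self.source_to_isocenter_mm),
            "isocenter_to_detector_mm": float(self.isocenter_to_detector_mm),
            "center_of_projection": [float(v) for v in self.center_of_projection],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CArmGeometry":
        return cls(
            primary_angle_deg=d.get("primary_angle_deg", 0.0),
            secondary_angle_deg=d.get("secondary_angle_deg", 0.0),
            source_to_isocenter_mm=d.get("source_to_isocenter_mm", 750.0),
            isocenter_to_detector_mm=d.get("isocenter_to_detector_mm", 450.0),
            center_of_projection=np.asarray(
                d.get("center_of_projection", (0.0, 0.0, 0.0)), float
            ),
        )


@dataclass(frozen=True)
class InPlaneTransform:
    """The 3-DOF in-plane transform (tx mm, ty mm, rz degrees)."""

    tx_mm: float = 0.0
    ty_mm: float = 0.0
    rz_deg: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.tx_mm, self.ty_mm, self.rz_deg], dtype=float)

    def compose(self, other: "InPlaneTransform") -> "InPlaneTransform":
        """Apply ``other`` after ``self`` (parameters add; see module docs)."""
        return InPlaneTransform(
            self.tx_mm + other.tx_mm,
            self.ty_mm + other.ty_mm,
            self.rz_deg + other.rz_deg,
        )

    def inverse(self) -> "InPlaneTransform":
        return InPlaneTransform(-self.tx_mm, -self.ty_mm, -self.rz_deg)

    def step(self, dof: int, delta: float) -> "InPlaneTransform":
        """Return the transform with parameter ``dof`` (0=tx,1=ty,2=rz) offset."""
        p = self.as_array()
        p[dof] += delta
        return InPlaneTransform(*p)

    def to_dict(self) -> dict:
        return {
            "tx_mm": float(self.tx_mm),
            "ty_mm": float(self.ty_mm),
            "rz_deg": float(self.rz_deg),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InPlaneTransform":
        return cls(d.get("tx_mm", 0.0), d.get("ty_mm", 0.0), d.get("rz_deg", 0.0))

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load_json(cls, path: str | Path) -> "InPlaneTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class CrossLandmark:
    """Cross-shaped landmark: centre plus four in-plane arm endpoints."""

    points: np.ndarray  # (5, 3) mm; row 0 is the centre

    @property
    def center(self) -> np.ndarray:
        return self.points[0]


def transform_distance(
    t1: InPlaneTransform,
    t2: InPlaneTransform,
    rot_weight: float = 1.0,
) -> float:
    """Distance D between two in-plane transforms.

    The L2 norm of the parameter difference, with the rotation converted
    to millimetre-equivalent units by ``rot_weight`` (mm per degree).
    """
    if rot_weight <= 0:
        raise ValueError("rot_weight must be > 0")
    d = t1.as_array() - t2.as_array()
    d[2] *= rot_weight
    return float(np.sqrt(d @ d))


def _axis_rotation(axis: np.ndarray, deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    th = np.deg2rad(deg)
    k = np.array(
        [[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]]
    )
    return np.eye(3) + np.sin(th) * k + (1 - np.cos(th)) * (k @ k)


def apply_transform(
    t: InPlaneTransform,
    points: np.ndarray,
    center: np.ndarray,
    geometry: CArmGeometry,
) -> np.ndarray:
    """Apply an in-plane transform to 3D world points.

    Points are rotated by ``rz`` about the projection axis through
    ``center`` (the model centre), then translated by ``tx`` / ``ty``
    along the detector axes.  The map is rigid.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    c = np.asarray(center, dtype=float).reshape(3)
    # positive rz turns the horizontal axis u towards the vertical axis v
    # (counter-clockwise in the image); that is a rotation about -direction
    rot = _axis_rotation(-geometry.direction, t.rz_deg)
    shift = t.tx_mm * geometry.axis_u + t.ty_mm * geometry.axis_v
    out = (pts - c) @ rot.T + c + shift
    return out if np.asarray(points).ndim == 2 else out[0]


def make_cross_landmark(
    center: np.ndarray,
    arm_length_mm: float = 10.0,
    geometry: CArmGeometry | None = None,
) -> CrossLandmark:
    """Cross landmark at the model centre, arms along the detector axes.

    The four arm endpoints sit ``arm_length_mm`` from the centre along
    the in-plane horizontal and vertical axes (10 mm by default).
    """
    if arm_length_mm < 0:
        raise ValueError("arm_length_mm must be >= 0")
    geometry = geometry if geometry is not None else CArmGeometry()
    c = np.asarray(center, dtype=float).reshape(3)
    u, v = geometry.axis_u, geometry.axis_v
    pts = np.stack(
        [
            c,
            c + arm_length_mm * u,
            c - arm_length_mm * u,
            c + arm_length_mm * v,
            c - arm_length_mm * v,
        ]
    )
    return CrossLandmark(points=pts)


def compute_tre(
    t_est: InPlaneTransform,
    t_gt: InPlaneTransform,
    landmark: CrossLandmark,
    geometry: CArmGeometry,
) -> float:
    """Target registration error of the cross landmark, mm.

    Root-mean-square over the five landmark points of the displacement
    between their positions under the estimated and the ground-truth
    transform.  Both transforms pivot at the landmark centre; since the
    motion is in-plane the displacements lie in the isocentre plane and
    the RMS of the 3D distances equals the in-plane error.
    """
    c = landmark.center
    p_est = apply_transform(t_est, landmark.points, c, geometry)
    p_gt = apply_transform(t_gt, landmark.points, c, geometry)
    d = np.linalg.norm(p_est - p_gt, axis=1)
    return float(np.sqrt(np.mean(d**2)))


def angular_error(t_est: InPlaneTransform, t_gt: InPlaneTransform) -> float:
    """Absolute in-plane rotation error, wrapped to [0, 180] degrees."""
    d = abs(t_est.rz_deg - t_gt.rz_deg) % 360.0
    return float(min(d, 360.0 - d))
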