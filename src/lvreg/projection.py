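"""Rendering: DRR fixed images, LV-model moving images and ROI extraction.

The registration scheme uses two images per state:

* the **fixed** image — a digitally reconstructed radiograph (DRR) of the
  whole volume with a large field of view (300 mm x 300 mm by default),
  rendered once per case;
* the **moving** image — a projection of the binary LV model with a small
  field of view (120 mm x 120 mm), always rendered with the (transformed)
  model centre at the image centre and at the centre of projection.

Because the moving image stays LV-centred, in-plane translations of the
model do not change the moving image at all: they only shift which
subregion (**ROI**) of the fixed image corresponds to it.  Rotations
change the moving image content.  The agent therefore always compares the
moving image with the ROI extracted at the current transform.

All images are sampled on a regular grid in the isocentre plane (see
:mod:`lvreg.geometry`), so fixed and moving pixels are directly
commensurable in mm without magnification bookkeeping.  Pixel (row, col)
maps to in-plane coordinates ``x = (col - (n-1)/2) * spacing`` and
``y = ((n-1)/2 - row) * spacing`` (y up).

DRR intensities are raw attenuation line integrals (dimensionless);
no exponential film model is applied.  Only gradients and normalised
intensities are consumed downstream, so any monotone intensity
convention is equivalent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .geometry import CArmGeometry, InPlaneTransform, _axis_rotation
from .phantom import AnatomyModel, AttenuationVolume

__all__ = [
    "ProjectionImage",
    "CaptureRangeError",
    "render_drr",
    "render_model_projection",
    "extract_roi",
    "resample_to_input",
    "FIXED_FOV_MM",
    "MOVING_FOV_MM",
]

FIXED_FOV_MM = 300.0
MOVING_FOV_MM = 120.0


class CaptureRangeError(RuntimeError):
    """The requested ROI window leaves the fixed image's field of view."""


@dataclass
class ProjectionImage:
    """2D projection image with physical field-of-view metadata."""

    pixels: np.ndarray  # (n, n) float32, row-major, y down
    fov_mm: float
    role: str  # "fixed" | "moving" | "roi"
    geometry: CArmGeometry
    transform: InPlaneTransform | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    @property
    def pixel_spacing_mm(self) -> float:
        return self.fov_mm / self.size

    def pixel_centers_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """In-plane (x, y) coordinates of pixel centres, mm."""
        n = self.size
        s = self.pixel_spacing_mm
        cols = (np.arange(n) - (n - 1) / 2.0) * s
        rows = ((n - 1) / 2.0 - np.arange(n)) * s
        return cols, rows

    def save(self, path: str | Path) -> None:
        """Write as 16-bit PNG plus a JSON metadata sidecar."""
        path = Path(path)
        lo = float(self.pixels.min())
        hi = float(self.pixels.max())
        scale = (hi - lo) or 1.0
        q = np.round((self.pixels - lo) / scale * 65535).astype(np.uint16)
        iio.imwrite(path, q)
        sidecar = {
            "fov_mm": self.fov_mm,
            "pixel_spacing_mm": self.pixel_spacing_mm,
            "role": self.role,
            "intensity_min": lo,
            "intensity_scale": scale,
            "geometry": self.geometry.to_dict(),
            "transform": self.transform.to_dict() if self.transform else None,
            "meta": self.meta,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ProjectionImage":
        path = Path(path)
        q = iio.imread(path).astype(np.float32)
        side = json.loads(path.with_suffix(".json").read_text())
        pixels = q / 65535.0 * side["intensity_scale"] + side["intensity_min"]
        t = side.get("transform")
        return cls(
            pixels=pixels,
            fov_mm=side["fov_mm"],
            role=side["role"],
            geometry=CArmGeometry.from_dict(side["geometry"]),
            transform=InPlaneTransform.from_dict(t) if t else None,
            meta=side.get("meta", {}),
        )


def _plane_grid(geometry: CArmGeometry, fov_mm: float, size: int) -> np.ndarray:
    """World coordinates (size, size, 3) of the isocentre-plane pixel grid."""
    s = fov_mm / size
    cols = (np.arange(size) - (size - 1) / 2.0) * s
    rows = ((size - 1) / 2.0 - np.arange(size)) * s
    Xp = cols[None, :, None] * geometry.axis_u[None, None, :]
    Yp = rows[:, None, None] * geometry.axis_v[None, None, :]
    return geometry.center_of_projection + Xp + Yp


def _integrate_rays(
    voxels: np.ndarray,
    spacing: np.ndarray,
    origin: np.ndarray,
    source: np.ndarray,
    targets: np.ndarray,
    step_mm: float,
    affine_map: tuple[np.ndarray, np.ndarray] | None = None,
    chunk: int = 16384,
) -> np.ndarray:
    """Line integrals from ``source`` through each target plane point.

    Rays are clipped to the volume's axis-aligned bounding box and sampled
    uniformly at most every ``step_mm`` (composite trapezoid rule) with
    trilinear interpolation.  ``affine_map`` = (M, b) optionally maps each
    world sample point ``p`` to ``M @ p + b`` before lookup (used to
    render rigidly transformed volumes without resampling them).

    The fast path is an exact Siddon-style voxel traversal (numba); the
    NumPy + scipy fallback densely samples the trilinearly interpolated
    field and is approximate near voxel edges.
    """
    from . import _raycast

    tgt = np.ascontiguousarray(targets.reshape(-1, 3), dtype=np.float64)
    # Map the rays into the volume frame (rigid remap of sample points is
    # equivalent to remapping source and directions).
    if affine_map is not None:
        M, b = affine_map
        src = M @ source + b
        dirs = (tgt - source) @ M.T
    else:
        src = np.asarray(source, float)
        dirs = tgt - source
    lens = np.linalg.norm(dirs, axis=1)
    e = dirs / lens[:, None]
    lo = origin - 0.5 * spacing
    hi = origin + (np.array(voxels.shape) - 0.5) * spacing
    with np.errstate(divide="ignore"):
        inv = 1.0 / e
    t_lo = (lo - src) * inv
    t_hi = (hi - src) * inv
    t0 = np.maximum(np.nanmax(np.minimum(t_lo, t_hi), axis=1), 0.0)
    t1 = np.nanmin(np.maximum(t_lo, t_hi), axis=1)

    if _raycast.HAVE_NUMBA:
        out = _raycast.integrate_rays_exact(
            voxels, origin, spacing, src, e, t0, t1
        )
        return out.reshape(targets.shape[:-1])

    out = np.zeros(len(tgt), dtype=np.float64)
    for start in range(0, len(tgt), chunk):
        sl = slice(start, min(start + chunk, len(tgt)))
        t0c, t1c, ec = t0[sl], t1[sl], e[sl]
        seg = t1c - t0c
        hit = seg > 0
        if not hit.any():
            continue
        seg_max = float(seg[hit].max())
        n = max(int(np.ceil(seg_max / step_mm)) + 1, 2)
        frac = np.linspace(0.0, 1.0, n)
        tt = t0c[hit, None] + seg[hit, None] * frac[None, :]
        pts = src[None, None, :] + ec[hit, None, :] * tt[:, :, None]
        idx = (pts - origin) / spacing
        vals = ndimage.map_coordinates(
            voxels,
            np.ascontiguousarray(idx.reshape(-1, 3).T, dtype=np.float32),
            order=1,
            mode="constant",
            cval=0.0,
            prefilter=False,
        ).reshape(idx.shape[:2])
        dt = seg[hit] / (n - 1)
        integ = (vals.sum(axis=1) - 0.5 * (vals[:, 0] + vals[:, -1])) * dt
        res = np.zeros(int(sl.stop - sl.start))
        res[hit] = integ
        out[sl] = res
    return out.reshape(targets.shape[:-1])


def render_drr(
    volume: AttenuationVolume,
    geometry: CArmGeometry,
    fov_mm: float = FIXED_FOV_MM,
    size: int = 512,
    step_mm: float | None = None,
) -> ProjectionImage:
    """Digitally reconstructed radiograph of an attenuation volume.

    Each pixel is the perspective line integral of attenuation from the
    X-ray source through the corresponding isocentre-plane grid point —
    exact for the piecewise-constant voxel model on the fast path
    (Siddon voxel traversal).  ``step_mm`` controls only the
    dense-sampling fallback (default: half the smallest voxel spacing).

    Raises
    ------
    ValueError
        If the source lies inside the volume (degenerate geometry).
    """
    if step_mm is None:
        step_mm = 0.5 * float(volume.spacing.min())
    lo, hi = volume.world_bounds()
    if np.all(geometry.source >= lo) and np.all(geometry.source <= hi):
        raise ValueError("degenerate geometry: X-ray source inside the volume")
    targets = _plane_grid(geometry, fov_mm, size)
    img = _integrate_rays(
        volume.voxels,
        volume.spacing,
        volume.origin,
        geometry.source,
        targets,
        step_mm,
    )
    return ProjectionImage(
        pixels=img.astype(np.float32),
        fov_mm=fov_mm,
        role="fixed",
        geometry=geometry,
    )


def render_model_projection(
    model: AnatomyModel,
    t: InPlaneTransform,
    geometry: CArmGeometry,
    fov_mm: float = MOVING_FOV_MM,
    size: int = 128,
    step_mm: float | None = None,
    normalize: bool = True,
) -> ProjectionImage:
    """Moving image: projection of the transformed LV mask, LV-centred.

    The model centre after the current translation defines both the image
    centre and the centre of projection (the source follows the model),
    so pure translations leave the moving image bit-identical and only
    the in-plane rotation changes its content.  Pixel values are
    mask-thickness line integrals (mm), normalised to [0, 1] unless
    ``normalize=False``.
    """
    if step_mm is None:
        step_mm = 0.5 * float(model.spacing.min())
    c = model.center
    shift = t.tx_mm * geometry.axis_u + t.ty_mm * geometry.axis_v
    c_moved = c + shift
    geo_here = geometry.with_center(c_moved)
    # inverse rigid transform: sample the untransformed mask at M @ p + b
    # (in-plane rotation is about -direction; see geometry.apply_transform)
    rot_inv = _axis_rotation(-geometry.direction, -t.rz_deg)
    back_map = (rot_inv, c - rot_inv @ c_moved)

    targets = _plane_grid(geo_here, fov_mm, size)
    img = _integrate_rays(
        model.mask.astype(np.float32),
        model.spacing,
        model.origin,
        geo_here.source,
        targets,
        step_mm,
        affine_map=back_map,
    )
    max_thickness = float(img.max())
    if normalize and max_thickness > 0:
        img = img / max_thickness
    return ProjectionImage(
        pixels=img.astype(np.float32),
        fov_mm=fov_mm,
        role="moving",
        geometry=geo_here,
        transform=t,
        meta={"max_thickness_mm": max_thickness},
    )


def projected_center_mm(
    t: InPlaneTransform,
    model_center: np.ndarray,
    geometry: CArmGeometry,
) -> np.ndarray:
    """Fixed-image in-plane (x, y) of the transformed model centre, mm."""
    shift = t.tx_mm * geometry.axis_u + t.ty_mm * geometry.axis_v
    return geometry.plane_coords(np.asarray(model_center) + shift)[0]


def extract_roi(
    fixed: ProjectionImage,
    t: InPlaneTransform,
    geometry: CArmGeometry,
    model_center: np.ndarray | None = None,
    fov_mm: float = MOVING_FOV_MM,
    size: int = 128,
) -> ProjectionImage:
    """Resample the fixed-image window corresponding to the moving image.

    The window is ``fov_mm`` square, centred at the perspective projection
    of the transformed model centre, axis-aligned with the fixed image
    (the ROI does not rotate with ``rz``; only the model does).  Bilinear
    interpolation.

    Raises
    ------
    CaptureRangeError
        If any part of the window leaves the fixed field of view — the
        agent has left the image.
    """
    if model_center is None:
        model_center = geometry.center_of_projection
    cx, cy = projected_center_mm(t, model_center, fixed.geometry)
    half = fov_mm / 2.0
    half_fixed = fixed.fov_mm / 2.0
    if (
        cx - half < -half_fixed
        or cx + half > half_fixed
        or cy - half < -half_fixed
        or cy + half > half_fixed
    ):
        raise CaptureRangeError(
            f"ROI centred at ({cx:.1f}, {cy:.1f}) mm exceeds the "
            f"{fixed.fov_mm:.0f} mm fixed FOV"
        )
    s = fov_mm / size
    xs = cx + (np.arange(size) - (size - 1) / 2.0) * s
    ys = cy + ((size - 1) / 2.0 - np.arange(size)) * s
    # in-plane mm -> fixed pixel indices
    sf = fixed.pixel_spacing_mm
    n = fixed.size
    col = xs / sf + (n - 1) / 2.0
    row = (n - 1) / 2.0 - ys / sf
    rr, cc = np.meshgrid(row, col, indexing="ij")
    roi = ndimage.map_coordinates(
        fixed.pixels.astype(np.float64),
        [rr.ravel(), cc.ravel()],
        order=1,
        mode="nearest",
        prefilter=False,
    ).reshape(size, size)
    return ProjectionImage(
        pixels=roi.astype(np.float32),
        fov_mm=fov_mm,
        role="roi",
        geometry=fixed.geometry,
        transform=t,
        meta={"center_mm": [float(cx), float(cy)]},
    )


def resample_to_input(image: ProjectionImage | np.ndarray, side: int) -> np.ndarray:
    """Resample to the network input resolution and standardise.

    Bilinear resampling (area-weighted when reducing) to ``side x side``,
    then intensity normalisation to zero mean and unit variance.  Constant
    images map to all zeros.
    """
    if side < 8:
        raise ValueError("side must be >= 8")
    from skimage.transform import resize

    px = image.pixels if isinstance(image, ProjectionImage) else np.asarray(image)
    px = px.astype(np.float64)
    if px.shape != (side, side):
        px = resize(
            px,
            (side, side),
            order=1,
            anti_aliasing=px.shape[0] > side,
            preserve_range=True,
        )
    sd = px.std()
    if sd == 0:
        return np.zeros((side, side), dtype=np.float32)
    return ((px - px.mean()) / sd).astype(np.float32)
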