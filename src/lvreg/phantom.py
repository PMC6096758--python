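"""Synthetic chest-like attenuation phantoms with a known LV model.

The generator emulates the content a contrasted chest CT contributes to a
digitally reconstructed radiograph: a faint ellipsoidal "heart shadow"
(the contrasted left ventricle, which is also the registration model), a
high-attenuation spine-like cylinder, a liver-like dome and low-attenuation
lung background inside a soft-tissue thorax.  The spine and the liver dome
deliberately provide the strongest image gradients, so that gradient-based
registration baselines can exhibit their characteristic failure mode of
locking onto them instead of the heart shadow.

Attenuation values are linear attenuation coefficients in 1/mm at roughly
diagnostic energies (soft tissue ~0.019/mm, bone ~0.05/mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "AttenuationVolume",
    "AnatomyModel",
    "PhantomConfig",
    "generate_phantom",
    "mask_to_mesh",
    "perturb_mask",
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
]


@dataclass
class AttenuationVolume:
    """3D attenuation grid.  ``voxels[ix, iy, iz]``; world = origin + index*spacing."""

    voxels: np.ndarray  # (nx, ny, nz) float32, 1/mm
    spacing: np.ndarray  # (3,) mm
    origin: np.ndarray  # (3,) mm, world position of voxel (0,0,0) centre

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be > 0 on every axis")
        if np.any(self.voxels < 0):
            raise ValueError("attenuation must be >= 0 everywhere")

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical size of the grid (mm) measured across voxel centres."""
        return (np.array(self.voxels.shape) - 1) * self.spacing

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) world coordinates of the outer voxel faces."""
        lo = self.origin - 0.5 * self.spacing
        hi = self.origin + (np.array(self.voxels.shape) - 0.5) * self.spacing
        return lo, hi


@dataclass
class AnatomyModel:
    """Binary LV mask aligned to a parent volume, with its world centre."""

    mask: np.ndarray  # (nx, ny, nz) bool
    spacing: np.ndarray
    origin: np.ndarray
    center: np.ndarray = field(default=None)  # type: ignore[assignment]
    mesh: object | None = None  # optional trimesh.Trimesh

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if not self.mask.any():
            raise ValueError("mask is empty")
        if self.center is None:
            self.center = self.centroid()
        else:
            self.center = np.asarray(self.center, dtype=float).reshape(3)

    def centroid(self) -> np.ndarray:
        """World-space centroid of the mask voxels."""
        idx = np.argwhere(self.mask)
        return self.origin + idx.mean(axis=0) * self.spacing

    def volume_mm3(self) -> float:
        return float(self.mask.sum() * np.prod(self.spacing))


@dataclass
class PhantomConfig:
    """Parameters of the synthetic chest phantom.

    Defaults give a 96^3 grid at 2 mm spacing (192 mm cube) holding an
    LV-like ellipsoid of 20 x 25 x 35 mm semi-axes, a spine-like cylinder
    and a liver-like dome whose attenuations exceed the LV's contrast
    against the surrounding soft tissue.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: float = 2.0
    lv_semi_axes_mm: tuple[float, float, float] = (20.0, 25.0, 35.0)
    lv_attenuation: float = 0.023
    lv_center_jitter_mm: float = 8.0
    lv_tilt_max_deg: float = 15.0
    body_attenuation: float = 0.019
    lung_attenuation: float = 0.012
    spine_radius_mm: float = 14.0
    spine_attenuation: float = 0.060
    liver_attenuation: float = 0.030
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "lv_attenuation",
            "body_attenuation",
            "lung_attenuation",
            "spine_attenuation",
            "liver_attenuation",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be > 0")


def _ellipsoid(coords, center, semi, rot=None):
    """Boolean ellipsoid over a world-coordinate grid."""
    rel = [c - ctr for c, ctr in zip(coords, center)]
    if rot is not None:
        rel = [
            rot[0, 0] * rel[0] + rot[0, 1] * rel[1] + rot[0, 2] * rel[2],
            rot[1, 0] * rel[0] + rot[1, 1] * rel[1] + rot[1, 2] * rel[2],
            rot[2, 0] * rel[0] + rot[2, 1] * rel[1] + rot[2, 2] * rel[2],
        ]
    q = sum((r / s) ** 2 for r, s in zip(rel, semi))
    return q <= 1.0


def generate_phantom(config: PhantomConfig) -> tuple[AttenuationVolume, AnatomyModel]:
    """Generate a chest-like phantom and its LV model mask.

    Deterministic for a given ``config.seed``: the LV position and tilt,
    the confounder placements and the optional attenuation noise are all
    drawn from one seeded generator.

    Raises
    ------
    ValueError
        If the LV (with a safety margin of its largest semi-axis) would
        be clipped by the grid boundary.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(int(s) for s in config.shape)
    sp = float(config.spacing_mm)
    spacing = np.full(3, sp)
    extent = (np.array(shape) - 1) * sp
    origin = -extent / 2.0  # grid centred on the world origin

    ax = [origin[i] + sp * np.arange(shape[i]) for i in range(3)]
    X = ax[0][:, None, None]
    Y = ax[1][None, :, None]
    Z = ax[2][None, None, :]
    coords = (X, Y, Z)

    # LV placement: near the grid centre, seed-jittered, slightly tilted.
    jit = rng.uniform(-config.lv_center_jitter_mm, config.lv_center_jitter_mm, 3)
    lv_center = jit
    semi = np.asarray(config.lv_semi_axes_mm, float)
    max_semi = float(semi.max())
    lo, hi = origin, origin + extent
    clearance = np.minimum(lv_center - lo, hi - lv_center) - max_semi
    if np.any(clearance < max_semi):
        raise ValueError(
            "LV ellipsoid does not fit in the grid with a margin of its "
            f"largest semi-axis (clearance {clearance} mm)"
        )
    from .geometry import _rot_x, _rot_z  # local: avoid a public dependency

    tilt = rng.uniform(-config.lv_tilt_max_deg, config.lv_tilt_max_deg, 2)
    lv_rot = _rot_x(tilt[0]) @ _rot_z(tilt[1])
    lv_mask = _ellipsoid(coords, lv_center, semi, rot=lv_rot)

    vol = np.zeros(shape, dtype=np.float32)

    # Thorax: soft-tissue elliptic cylinder along z filling most of the grid.
    body_semi = (0.46 * extent[0], 0.40 * extent[1])
    body = ((X / body_semi[0]) ** 2 + (Y / body_semi[1]) ** 2) <= 1.0
    body = np.broadcast_to(body, shape)
    vol[body] = config.body_attenuation

    # Lungs: two low-attenuation ellipsoids flanking the LV.
    for side in (-1.0, 1.0):
        lung_c = np.array(
            [side * 0.26 * extent[0] + rng.uniform(-4, 4), -2.0, 0.0]
        )
        lung_semi = (0.17 * extent[0], 0.30 * extent[1], 0.42 * extent[2])
        lung = _ellipsoid(coords, lung_c, lung_semi)
        vol[lung & body] = config.lung_attenuation

    # Spine: high-attenuation cylinder along z, posterior midline.
    spine_c = np.array([rng.uniform(-3, 3), -0.30 * extent[1], 0.0])
    spine = ((X - spine_c[0]) ** 2 + (Y - spine_c[1]) ** 2) <= config.spine_radius_mm**2
    vol[np.broadcast_to(spine, shape) & body] = config.spine_attenuation

    # Liver: large dome in the caudal-right quadrant, partially in grid.
    liver_c = np.array(
        [
            -0.22 * extent[0] + rng.uniform(-5, 5),
            0.05 * extent[1],
            -0.45 * extent[2],
        ]
    )
    liver_semi = (0.30 * extent[0], 0.30 * extent[1], 0.32 * extent[2])
    liver = _ellipsoid(coords, liver_c, liver_semi)
    vol[liver & body] = config.liver_attenuation

    # Contrasted LV on top of everything.
    vol[lv_mask] = config.lv_attenuation

    if config.noise_sigma > 0:
        vol = vol + rng.normal(0.0, config.noise_sigma, shape).astype(np.float32)
        np.clip(vol, 0.0, None, out=vol)

    volume = AttenuationVolume(voxels=vol, spacing=spacing, origin=origin)
    model = AnatomyModel(mask=lv_mask, spacing=spacing, origin=origin)
    return volume, model


def mask_to_mesh(model: AnatomyModel, iso: float = 0.5):
    """Triangulated surface of the binary mask (marching cubes).

    Returns a ``trimesh.Trimesh`` in world coordinates; for smooth bodies
    of reasonable size its enclosed volume tracks the voxel-count volume.
    """
    import trimesh

    if not model.mask.any():
        raise ValueError("mask is empty")
    padded = np.pad(model.mask.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=iso)
    verts = (verts - 1.0) * model.spacing + model.origin
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:  # marching-cubes winding points inward
        mesh.invert()
    return mesh


def perturb_mask(
    model: AnatomyModel,
    radius_vox: int,
    mode: str = "dilate",
    seed: int | None = None,
) -> tuple[AnatomyModel, float]:
    """Morphologically perturb the mask, emulating segmentation error.

    Dilates or erodes by a ball of ``radius_vox`` voxels; with a seed,
    additionally flips a sparse random sprinkling of boundary voxels.
    Returns the perturbed model and its Dice overlap with the original.

    Raises
    ------
    ValueError
        If the perturbed mask is empty.
    """
    if radius_vox < 0:
        raise ValueError("radius_vox must be >= 0")
    mask = model.mask
    if radius_vox > 0:
        ball = _ball_structure(radius_vox)
        if mode == "dilate":
            mask = ndimage.binary_dilation(mask, structure=ball)
        elif mode == "erode":
            mask = ndimage.binary_erosion(mask, structure=ball)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    if seed is not None:
        rng = np.random.default_rng(seed)
        boundary = mask ^ ndimage.binary_erosion(mask)
        flip = boundary & (rng.random(mask.shape) < 0.2)
        mask = mask ^ flip
    if not mask.any():
        raise ValueError("perturbation produced an empty mask")
    inter = np.logical_and(mask, model.mask).sum()
    dice = 2.0 * inter / (mask.sum() + model.mask.sum())
    out = AnatomyModel(mask=mask, spacing=model.spacing, origin=model.origin)
    return out, float(dice)


def _ball_structure(radius: int) -> np.ndarray:
    r = int(radius)
    g = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (g**2).sum(axis=0) <= r**2


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def save_volume(volume: AttenuationVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.voxels, _affine(volume.spacing, volume.origin))
    nib.save(img, str(path))


def load_volume(path: str | Path) -> AttenuationVolume:
    img = nib.load(str(path))
    aff = img.affine
    return AttenuationVolume(
        voxels=np.asarray(img.dataobj, dtype=np.float32),
        spacing=np.diag(aff)[:3].copy(),
        origin=aff[:3, 3].copy(),
    )


def save_mask(model: AnatomyModel, path: str | Path) -> None:
    img = nib.Nifti1Image(
        model.mask.astype(np.uint8), _affine(model.spacing, model.origin)
    )
    nib.save(img, str(path))


def load_mask(path: str | Path) -> AnatomyModel:
    img = nib.load(str(path))
    aff = img.affine
    return AnatomyModel(
        mask=np.asarray(img.dataobj) > 0,
        spacing=np.diag(aff)[:3].copy(),
        origin=aff[:3, 3].copy(),
    )
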