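"""Brute-force reference computations used to validate the fast paths.

These are deliberately naive (per-voxel / per-pixel loops over exact
closed forms) and share no code with the production renderer or metrics.
They exist for verification on small inputs only.
"""

from __future__ import annotations

import numpy as np

from .geometry import CArmGeometry
from .phantom import AttenuationVolume

__all__ = ["drr_oracle", "gc_reference", "gi_reference", "go_reference"]


def drr_oracle(
    volume: AttenuationVolume,
    geometry: CArmGeometry,
    fov_mm: float,
    size: int,
) -> np.ndarray:
    """Exact DRR by per-voxel ray-box chord lengths.

    For every detector pixel the ray from the source through the
    isocentre-plane grid point is intersected with each voxel's box
    (slab method) and the attenuation is accumulated as
    ``mu * chord length``.  Exact for the piecewise-constant voxel model;
    O(pixels x voxels), intended for volumes of at most a few thousand
    voxels.
    """
    vox = volume.voxels
    nx, ny, nz = vox.shape
    idx = np.argwhere(vox != 0)
    mu = vox[idx[:, 0], idx[:, 1], idx[:, 2]].astype(np.float64)
    lo_all = volume.origin + (idx - 0.5) * volume.spacing
    hi_all = lo_all + volume.spacing

    s = geometry.source
    u, v = geometry.axis_u, geometry.axis_v
    cop = geometry.center_of_projection
    sp = fov_mm / size
    img = np.zeros((size, size), dtype=np.float64)
    for r in range(size):
        y = ((size - 1) / 2.0 - r) * sp
        for c_ in range(size):
            x = (c_ - (size - 1) / 2.0) * sp
            target = cop + x * u + y * v
            d = target - s
            d = d / np.linalg.norm(d)
            with np.errstate(divide="ignore"):
                inv = 1.0 / d
            t1 = (lo_all - s) * inv
            t2 = (hi_all - s) * inv
            tmin = np.minimum(t1, t2).max(axis=1)
            tmax = np.maximum(t1, t2).min(axis=1)
            chord = np.clip(tmax - np.maximum(tmin, 0.0), 0.0, None)
            img[r, c_] = float((mu * chord).sum())
    return img


def _grad_naive(img: np.ndarray, positive_only: bool):
    """Central differences by explicit loops (one-sided at borders)."""
    h, w = img.shape
    gx = np.zeros_like(img, dtype=float)
    gy = np.zeros_like(img, dtype=float)
    for r in range(h):
        for c in range(w):
            if 0 < c < w - 1:
                gx[r, c] = (img[r, c + 1] - img[r, c - 1]) / 2.0
            elif c == 0:
                gx[r, c] = img[r, 1] - img[r, 0]
            else:
                gx[r, c] = img[r, w - 1] - img[r, w - 2]
            if 0 < r < h - 1:
                gy[r, c] = (img[r + 1, c] - img[r - 1, c]) / 2.0
            elif r == 0:
                gy[r, c] = img[1, c] - img[0, c]
            else:
                gy[r, c] = img[h - 1, c] - img[h - 2, c]
    if positive_only:
        gx = np.maximum(gx, 0.0)
        gy = np.maximum(gy, 0.0)
    return gx, gy


def _w_angle(fx, fy, mx, my) -> float:
    mf = np.hypot(fx, fy)
    mm = np.hypot(mx, my)
    if mf == 0 or mm == 0:
        return 0.0
    cos_a = np.clip((fx * mx + fy * my) / (mf * mm), -1.0, 1.0)
    return float((np.cos(2 * np.arccos(cos_a)) + 1.0) / 2.0)


def gc_reference(fixed: np.ndarray, moving: np.ndarray, positive_only=False) -> float:
    """Gradient correlation by explicit double loops."""
    fgx, fgy = _grad_naive(np.asarray(fixed, float), positive_only)
    mgx, mgy = _grad_naive(np.asarray(moving, float), False)

    def ncc(a, b):
        am, bm = a - a.mean(), b - b.mean()
        den = np.sqrt((am**2).sum() * (bm**2).sum())
        return 0.0 if den == 0 else float((am * bm).sum() / den)

    return 0.5 * (ncc(fgx, mgx) + ncc(fgy, mgy))


def gi_reference(fixed: np.ndarray, moving: np.ndarray, positive_only=False) -> float:
    """Gradient information by explicit pixel loop."""
    fgx, fgy = _grad_naive(np.asarray(fixed, float), positive_only)
    mgx, mgy = _grad_naive(np.asarray(moving, float), False)
    total = 0.0
    for r in range(fixed.shape[0]):
        for c in range(fixed.shape[1]):
            w = _w_angle(fgx[r, c], fgy[r, c], mgx[r, c], mgy[r, c])
            total += w * min(
                np.hypot(fgx[r, c], fgy[r, c]), np.hypot(mgx[r, c], mgy[r, c])
            )
    return total


def go_reference(fixed: np.ndarray, moving: np.ndarray, positive_only=False) -> float:
    """Gradient orientation by explicit pixel loop."""
    fgx, fgy = _grad_naive(np.asarray(fixed, float), positive_only)
    mgx, mgy = _grad_naive(np.asarray(moving, float), False)
    mf = np.hypot(fgx, fgy)
    mm = np.hypot(mgx, mgy)
    if mf.max() == 0 or mm.max() == 0:
        return 0.0
    vals = []
    for r in range(fixed.shape[0]):
        for c in range(fixed.shape[1]):
            if mf[r, c] > 1e-6 * mf.max() and mm[r, c] > 1e-6 * mm.max():
                vals.append(_w_angle(fgx[r, c], fgy[r, c], mgx[r, c], mgy[r, c]))
    return float(np.mean(vals)) if vals else 0.0
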