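"""Accuracy statistics and robustness analysis.

Two evaluation styles:

* **Accuracy** (synthetic data, ground truth known): target registration
  error of the 10 mm cross landmark before and after registration,
  summarised as mean, standard deviation and the 50/60/70/80/90/100th
  percentiles per method, plus the angular error.

* **Robustness** (no ground truth): the model is perturbed on a regular
  translation grid (-30..30 mm in 5 mm steps, i.e. 169 perturbations)
  with random rotations, re-registered, and the scatter of the final
  landmark positions around their median is reported as the deviation

      e_f = || x_f - x_median ||_2 .

  Diverged runs are excluded from the median but counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    CArmGeometry,
    CrossLandmark,
    InPlaneTransform,
    compute_tre,
)
from .imitation import Trajectory
from .projection import projected_center_mm

__all__ = [
    "TRESummary",
    "RobustnessResult",
    "summarize_tre",
    "robustness_grid_spec",
    "robustness_analysis",
    "record_convergence",
]

PERCENTILES = (50, 60, 70, 80, 90, 100)


@dataclass(frozen=True)
class TRESummary:
    """One accuracy-table row."""

    method: str
    mean_mm: float
    std_mm: float
    percentiles_mm: dict[int, float]
    angular_mean_deg: float | None = None
    angular_std_deg: float | None = None
    n: int = 0

    def as_row(self) -> dict:
        row = {
            "method": self.method,
            "n": self.n,
            "mean_mm": self.mean_mm,
            "std_mm": self.std_mm,
        }
        row.update({f"p{p}_mm": v for p, v in self.percentiles_mm.items()})
        if self.angular_mean_deg is not None:
            row["angular_mean_deg"] = self.angular_mean_deg
            row["angular_std_deg"] = self.angular_std_deg
        return row


def summarize_tre(
    errors_mm: np.ndarray,
    angular_deg: np.ndarray | None = None,
    method: str = "",
) -> TRESummary:
    """Summarise a TRE sample: mean, population SD, percentiles.

    Percentiles use linear interpolation between order statistics; the
    100th percentile is the maximum.
    """
    e = np.asarray(errors_mm, dtype=float)
    if e.size == 0:
        raise ValueError("empty error list")
    pct = {p: float(np.percentile(e, p)) for p in PERCENTILES}
    ang_mean = ang_std = None
    if angular_deg is not None and len(angular_deg):
        a = np.asarray(angular_deg, dtype=float)
        ang_mean, ang_std = float(a.mean()), float(a.std())
    return TRESummary(
        method=method,
        mean_mm=float(e.mean()),
        std_mm=float(e.std()),
        percentiles_mm=pct,
        angular_mean_deg=ang_mean,
        angular_std_deg=ang_std,
        n=int(e.size),
    )


def robustness_grid_spec(
    t_range_mm: float = 30.0,
    t_step_mm: float = 5.0,
    r_range_deg: float = 15.0,
    seed: int = 0,
) -> list[InPlaneTransform]:
    """Regular perturbation grid with random rotations.

    All (tx, ty) combinations from -range to +range inclusive in steps of
    ``t_step_mm``, each paired with one uniform random rotation in
    [-r_range, +r_range].  The default grid has 13 x 13 = 169 entries.
    """
    if t_step_mm <= 0:
        raise ValueError("t_step_mm must be > 0")
    n_half = t_range_mm / t_step_mm
    if abs(n_half - round(n_half)) > 1e-9:
        raise ValueError("t_range_mm must be a multiple of t_step_mm")
    vals = np.arange(-round(n_half), round(n_half) + 1) * t_step_mm
    rng = np.random.default_rng(seed)
    out = []
    for tx in vals:
        for ty in vals:
            out.append(
                InPlaneTransform(
                    float(tx), float(ty), float(rng.uniform(-r_range_deg, r_range_deg))
                )
            )
    return out


@dataclass
class RobustnessResult:
    """Scatter of final landmark positions around their median."""

    final_positions_mm: np.ndarray  # (n, 2) non-diverged finals
    median_position_mm: np.ndarray  # (2,) component-wise median
    deviations_mm: np.ndarray  # (n,) e_f per non-diverged run
    n_diverged: int
    n_total: int

    @property
    def fraction_below_5mm(self) -> float:
        return float(np.mean(self.deviations_mm < 5.0))

    @property
    def deviation_p90_mm(self) -> float:
        return float(np.percentile(self.deviations_mm, 90))

    def summary(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_diverged": self.n_diverged,
            "median_deviation_mm": float(np.median(self.deviations_mm)),
            "fraction_below_5mm": self.fraction_below_5mm,
            "deviation_p90_mm": self.deviation_p90_mm,
        }


def robustness_analysis(
    finals: list[tuple[InPlaneTransform, bool]],
    model_center: np.ndarray,
    geometry: CArmGeometry,
) -> RobustnessResult:
    """Deviation of final landmark positions from their median reference.

    ``finals`` holds (final transform, diverged flag) per run.  Final
    landmark centre positions are taken in fixed-image in-plane mm; the
    reference is their component-wise median over non-diverged runs.

    Raises
    ------
    ValueError
        If every run diverged.
    """
    ok = [t for t, div in finals if not div]
    n_div = sum(1 for _, div in finals if div)
    if not ok:
        raise ValueError("all runs diverged")
    pos = np.array([projected_center_mm(t, model_center, geometry) for t in ok])
    med = np.median(pos, axis=0)
    dev = np.linalg.norm(pos - med, axis=1)
    return RobustnessResult(
        final_positions_mm=pos,
        median_position_mm=med,
        deviations_mm=dev,
        n_diverged=n_div,
        n_total=len(finals),
    )


@dataclass
class ConvergenceCurves:
    """Per-iteration registration diagnostics for one trajectory."""

    iterations: np.ndarray
    tre_mm: np.ndarray
    tx_error_mm: np.ndarray
    ty_error_mm: np.ndarray
    rz_error_deg: np.ndarray
    center_path_mm: np.ndarray  # (n, 2) projected model-centre path


def record_convergence(
    trajectory: Trajectory,
    t_g: InPlaneTransform,
    landmark: CrossLandmark,
    geometry: CArmGeometry,
) -> ConvergenceCurves:
    """TRE and per-parameter error curves along a trajectory."""
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    transforms = trajectory.transforms()
    tre = np.array(
        [compute_tre(t, t_g, landmark, geometry) for t in transforms]
    )
    p = np.array([t.as_array() for t in transforms])
    g = t_g.as_array()
    path = np.array(
        [projected_center_mm(t, landmark.center, geometry) for t in transforms]
    )
    return ConvergenceCurves(
        iterations=np.arange(len(transforms)),
        tre_mm=tre,
        tx_error_mm=p[:, 0] - g[0],
        ty_error_mm=p[:, 1] - g[1],
        rz_error_deg=p[:, 2] - g[2],
        center_path_mm=path,
    )
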