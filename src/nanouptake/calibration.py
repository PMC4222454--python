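"""Single-particle intensity calibration.

The counting rule needs the mean integrated fluorescence intensity I₁ of one
particle unit. It is measured from stacks of particles deposited and spread
on a coverslip, imaged with the same setup as the cell experiments: spots are
detected with the standard detection pipeline, their integrated intensities
collected, and a Gaussian is fitted to the sample with iterative trimming —
spots outside mean ± 2.5 sd are discarded (these are multi-particle spots at
≈ integer multiples of I₁) and the fit repeated until stable.

For strongly agglomerating particles the "single particle" on the coverslip
is really a single agglomerate; the unit is whatever object the calibration
field contains, and the counts downstream are in the same unit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .io_formats import VoxelGrid
from .particle_detection import DetectionParams, detect_objects, subtract_background

__all__ = [
    "CalibrationResult",
    "InsufficientSpotsError",
    "calibrate_single_particle",
    "fit_intensity_distribution",
    "plot_intensity_histogram",
]


class InsufficientSpotsError(RuntimeError):
    """Fewer calibration spots than the configured minimum."""


@dataclass
class CalibrationResult:
    """Fitted single-unit intensity I₁ (raw camera units)."""

    i1_mean: float
    i1_sd: float
    n_spots_used: int
    n_spots_rejected: int
    fit_ok: bool

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationResult":
        return cls(**json.loads(Path(path).read_text()))


def _trim_gaussian(
    intensities: np.ndarray, trim_sigmas: float, max_iter: int
) -> tuple[float, float, np.ndarray]:
    """Iteratively trimmed maximum-likelihood Gaussian fit.

    Returns (mean, sd, boolean keep-mask). The loop is a fixed point on an
    already-trimmed sample; sd uses the n−1 denominator (0 for n == 1).
    """
    keep = np.ones(intensities.size, dtype=bool)
    for _ in range(max_iter):
        sample = intensities[keep]
        mean = float(sample.mean())
        sd = float(sample.std(ddof=1)) if sample.size > 1 else 0.0
        new_keep = np.abs(intensities - mean) <= trim_sigmas * sd
        if sd == 0.0:
            new_keep = np.abs(intensities - mean) == 0.0
        if new_keep.sum() == 0 or np.array_equal(new_keep, keep):
            break
        keep = new_keep
    sample = intensities[keep]
    mean = float(sample.mean())
    sd = float(sample.std(ddof=1)) if sample.size > 1 else 0.0
    return mean, sd, keep


def calibrate_single_particle(
    stacks: list[VoxelGrid],
    det: DetectionParams | None = None,
    min_spots: int = 50,
    trim_sigmas: float = 2.5,
    max_iter: int = 10,
    cell_voxel_size: tuple[float, float, float] | None = None,
) -> CalibrationResult:
    """Measure I₁ from coverslip calibration stacks.

    Runs background subtraction + detection on every stack, pools the
    integrated spot intensities, and fits a trimmed Gaussian. ``fit_ok`` is
    False when trimming removed more than half of the spots (the field was
    dominated by agglomerates — the fitted unit is then unreliable).

    ``cell_voxel_size`` optionally declares the geometry of the cell-uptake
    stacks; calibration must use the same imaging parameters, so a mismatch
    triggers a warning.
    """
    if not stacks:
        raise InsufficientSpotsError("no calibration stacks given")
    det = det or DetectionParams()
    if cell_voxel_size is not None:
        for g in stacks:
            if not np.allclose(g.voxel_size, cell_voxel_size, rtol=1e-6):
                warnings.warn(
                    f"calibration stack voxel size {g.voxel_size} differs from the "
                    f"cell stacks {tuple(cell_voxel_size)}; calibration should use "
                    "the same imaging parameters",
                    stacklevel=2,
                )
    intensities = []
    for g in stacks:
        residual = subtract_background(g, det)
        for obj in detect_objects(residual, det):
            intensities.append(obj.integrated_intensity)
    return fit_intensity_distribution(
        np.asarray(intensities, dtype=np.float64),
        min_spots=min_spots,
        trim_sigmas=trim_sigmas,
        max_iter=max_iter,
    )


def fit_intensity_distribution(
    intensities: np.ndarray,
    min_spots: int = 50,
    trim_sigmas: float = 2.5,
    max_iter: int = 10,
) -> CalibrationResult:
    """Fit the trimmed Gaussian to already-measured spot intensities."""
    intensities = np.asarray(intensities, dtype=np.float64)
    if intensities.size < min_spots:
        raise InsufficientSpotsError(
            f"insufficient calibration spots: {intensities.size} < {min_spots}"
        )
    mean, sd, keep = _trim_gaussian(intensities, trim_sigmas, max_iter)
    n_used = int(keep.sum())
    n_rejected = int(intensities.size - n_used)
    fit_ok = n_used >= 0.5 * intensities.size and mean > 0
    return CalibrationResult(
        i1_mean=mean,
        i1_sd=sd,
        n_spots_used=n_used,
        n_spots_rejected=n_rejected,
        fit_ok=bool(fit_ok),
    )


def plot_intensity_histogram(
    intensities: np.ndarray, result: CalibrationResult, path: str | Path
) -> None:
    """Histogram of spot intensities with the fitted Gaussian overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy import stats

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(intensities, bins=40, density=True, color="0.7", label="spots")
    if result.i1_sd > 0:
        x = np.linspace(intensities.min(), intensities.max(), 400)
        ax.plot(
            x,
            stats.norm.pdf(x, result.i1_mean, result.i1_sd),
            "r-",
            label=f"fit: I₁ = {result.i1_mean:.0f}",
        )
    ax.set_xlabel("integrated spot intensity (camera units)")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
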