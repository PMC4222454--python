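"""Synthetic two-channel stacks with known ground truth.

The generator emulates the imaging regime the analysis is built for: an
adherent cell whose plasma membrane is imaged as a bright closed shell, and
dye-loaded nanoparticles appearing as diffraction-limited spots whose
integrated intensity is the per-particle unit intensity times the number of
particles in the spot (self-quenching negligible). Both channels get photon
(Poisson) noise and Gaussian camera read noise on top of a flat background,
on anisotropic voxels (coarser z than xy).

Geometry convention: ``cell_radius_um`` is the *outer* surface of the cell;
the optical membrane band of thickness ``membrane_thickness_um`` is drawn on
the inner side of that surface, so the thresholded cell mask's outer edge
coincides with the nominal radius.

All randomness flows through one seeded generator; a fixed seed gives
bit-identical stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_formats import VoxelGrid

__all__ = [
    "ParticleSpec",
    "ScenarioParams",
    "GroundTruth",
    "generate_cell_stack",
    "generate_calibration_field",
    "generate_kinetics_dataset",
    "render_spot_field",
]


@dataclass(frozen=True)
class ParticleSpec:
    """Request for one synthetic object: region class and multiplicity."""

    region: str  # "intra" | "shell" | "outside"
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.region not in ("intra", "shell", "outside"):
            raise ValueError(f"unknown region class {self.region!r}")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")


@dataclass
class ScenarioParams:
    """Synthetic cell scenario.

    Defaults reflect a spinning-disk confocal with a 63×/1.4 NA oil
    objective and an EMCCD: 250 nm z spacing, 110 nm pixels, Gaussian PSF
    σ = 0.15 µm lateral / 0.45 µm axial, unit spot intensity 48090 camera
    counts with 10% CV, flat background 100 counts, Poisson noise at
    0.5 photons per count and 30-count read noise.
    """

    cell_shape: str = "sphere"  # sphere | ellipsoid | hemisphere
    cell_radius_um: float = 6.0
    ellipsoid_axes_um: tuple[float, float, float] | None = None  # (z, y, x) semi-axes
    membrane_thickness_um: float = 0.4
    membrane_intensity: float = 3000.0
    voxel_size: tuple[float, float, float] = (0.25, 0.11, 0.11)
    psf_sigma_um: tuple[float, float] = (0.45, 0.15)  # (axial, lateral)
    particle_unit_intensity: float = 48090.0
    particle_intensity_cv: float = 0.10
    particles: list[ParticleSpec] = dc_field(default_factory=list)
    shell_width_um: float = 1.4
    placement_margin_um: float = 0.35
    min_particle_separation_um: float = 2.5
    field_margin_um: float = 2.0
    background_level: float = 100.0
    poisson_scale: float = 0.5  # photons per camera count; 0 disables shot noise
    read_noise_sd: float = 30.0
    seed: int = 0

    def grid_shape(self) -> tuple[int, int, int]:
        dz, dy, dx = self.voxel_size
        if self.cell_shape == "ellipsoid" and self.ellipsoid_axes_um is not None:
            az, ay, ax = self.ellipsoid_axes_um
        else:
            az = ay = ax = self.cell_radius_um
        m = self.field_margin_um
        if self.cell_shape == "hemisphere":
            ez = az + 2 * m  # dome + margin above, margin below the coverslip
        else:
            ez = 2 * (az + m)
        return (
            int(np.ceil(ez / dz)),
            int(np.ceil(2 * (ay + m) / dy)),
            int(np.ceil(2 * (ax + m) / dx)),
        )


@dataclass
class GroundTruth:
    """Everything the generator knows: true positions, classes, multiplicities."""

    particles: list[dict]  # position_um (x, y, z), region, multiplicity, intensity
    totals: dict  # per-region particle totals (sums of multiplicities)
    i1_true: float
    seed: int

    @classmethod
    def from_particles(cls, particles: list[dict], i1_true: float, seed: int) -> "GroundTruth":
        totals = {"intra": 0, "shell": 0, "outside": 0}
        for p in particles:
            totals[p["region"]] += p["multiplicity"]
        return cls(particles=particles, totals=totals, i1_true=i1_true, seed=seed)


def _signed_distance(params: ScenarioParams, pts_um: np.ndarray) -> np.ndarray:
    """Signed distance (µm) from points to the cell's outer surface (<0 inside).

    Exact for sphere and hemisphere; first-order approximation for the
    ellipsoid (adequate for placement and rasterization at these voxel sizes).
    """
    shape = params.grid_shape()
    extent = np.asarray(shape) * np.asarray(params.voxel_size)
    center = extent / 2.0
    if params.cell_shape == "hemisphere":
        center = np.array([params.field_margin_um, extent[1] / 2, extent[2] / 2])
    d = pts_um - center  # (z, y, x) offsets
    if params.cell_shape == "sphere":
        return np.linalg.norm(d, axis=-1) - params.cell_radius_um
    if params.cell_shape == "hemisphere":
        s_sphere = np.linalg.norm(d, axis=-1) - params.cell_radius_um
        s_plane = -d[..., 0]  # cell occupies z >= coverslip plane
        return np.maximum(s_sphere, s_plane)
    if params.cell_shape == "ellipsoid":
        axes = np.asarray(params.ellipsoid_axes_um or [params.cell_radius_um] * 3)
        u = d / axes
        r = np.linalg.norm(u, axis=-1)
        grad = np.linalg.norm(d / axes**2, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(grad > 0, r * (r - 1) / np.maximum(grad, 1e-12), -axes.min())
        return s
    raise ValueError(f"unknown cell_shape {params.cell_shape!r}")


def _voxel_center_grid(shape, voxel_size) -> np.ndarray:
    zz, yy, xx = np.meshgrid(
        np.arange(shape[0]) * voxel_size[0],
        np.arange(shape[1]) * voxel_size[1],
        np.arange(shape[2]) * voxel_size[2],
        indexing="ij",
    )
    return np.stack([zz, yy, xx], axis=-1)


def render_spot_field(
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    positions_um: np.ndarray,
    intensities: np.ndarray,
    psf_sigma_um: tuple[float, float],
) -> np.ndarray:
    """Noise-free particle channel: sub-voxel impulses blurred by the PSF.

    Each spot's total intensity is deposited at its continuous (z, y, x)
    position via trilinear splatting, then the whole field is convolved with
    the Gaussian PSF. The convolution conserves intensity for interior spots,
    so the integrated image intensity of a spot equals its requested total —
    the premise that makes counting by intensity ratio exact, and additive
    in multiplicity.
    """
    field = np.zeros(shape, dtype=np.float64)
    positions_um = np.atleast_2d(positions_um)
    for pos, q in zip(positions_um, np.atleast_1d(intensities)):
        f = np.asarray(pos) / np.asarray(voxel_size)
        i0 = np.floor(f).astype(int)
        frac = f - i0
        for dz_ in (0, 1):
            for dy_ in (0, 1):
                for dx_ in (0, 1):
                    idx = (i0[0] + dz_, i0[1] + dy_, i0[2] + dx_)
                    if not all(0 <= idx[k] < shape[k] for k in range(3)):
                        continue
                    w = (
                        (frac[0] if dz_ else 1 - frac[0])
                        * (frac[1] if dy_ else 1 - frac[1])
                        * (frac[2] if dx_ else 1 - frac[2])
                    )
                    field[idx] += q * w
    ax, lat = psf_sigma_um
    sigma_vox = (ax / voxel_size[0], lat / voxel_size[1], lat / voxel_size[2])
    return ndimage.gaussian_filter(field, sigma=sigma_vox)


def _apply_noise(
    clean: np.ndarray,
    background: float,
    poisson_scale: float,
    read_noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    img = clean + background
    if poisson_scale > 0:
        img = rng.poisson(img * poisson_scale) / poisson_scale
    if read_noise_sd > 0:
        img = img + rng.normal(0.0, read_noise_sd, size=img.shape)
    return np.clip(img, 0.0, None)


def _sample_positions(
    params: ScenarioParams,
    specs: list[ParticleSpec],
    rng: np.random.Generator,
    max_attempts: int = 20000,
) -> np.ndarray:
    """Uniform rejection sampling of particle positions within region classes.

    Positions stay ``placement_margin_um`` clear of the region borders (so
    ground-truth classes survive the ≲0.1 µm boundary error of the
    reconstruction) and ``min_particle_separation_um`` apart (so objects stay
    resolvable and their integration apertures independent).
    """
    shape = params.grid_shape()
    extent = np.asarray(shape) * np.asarray(params.voxel_size)
    half_w = params.shell_width_um / 2.0
    m = params.placement_margin_um
    pad = 1.0  # µm clearance from the stack border for PSF tails
    intervals = {
        "intra": (-np.inf, -(half_w + m)),
        "shell": (-(half_w - m), half_w - m),
        "outside": (half_w + m, np.inf),
    }
    if intervals["shell"][0] > intervals["shell"][1]:
        raise ValueError("placement margin exceeds the shell half-width")
    placed: list[np.ndarray] = []
    for spec in specs:
        lo, hi = intervals[spec.region]
        for attempt in range(max_attempts):
            p = rng.uniform(pad, extent - pad)
            s = float(_signed_distance(params, p))
            if not (lo <= s <= hi):
                continue
            if placed and np.min(
                np.linalg.norm(np.asarray(placed) - p, axis=1)
            ) < params.min_particle_separation_um:
                continue
            placed.append(p)
            break
        else:
            raise ValueError(
                f"could not place a {spec.region!r} particle: region too small for "
                "the requested count at the separation constraint (is the cell "
                "thick enough for an intracellular space?)"
            )
    return np.asarray(placed).reshape(len(specs), 3)


def generate_cell_stack(
    params: ScenarioParams,
) -> tuple[VoxelGrid, VoxelGrid, GroundTruth]:
    """Render one synthetic cell: (membrane channel, particle channel, truth)."""
    rng = np.random.default_rng(params.seed)
    shape = params.grid_shape()
    pts = _voxel_center_grid(shape, params.voxel_size)
    s = _signed_distance(params, pts)
    if params.particles:
        intra_needed = any(p.region == "intra" for p in params.particles)
        deepest = -float(s.min())
        if intra_needed and deepest <= params.shell_width_um / 2 + params.placement_margin_um:
            raise ValueError(
                "cell is too thin for intracellular particles at this shell width"
            )
    band = (s <= 0.0) & (s >= -params.membrane_thickness_um)
    membrane_clean = params.membrane_intensity * band.astype(np.float64)
    ax, lat = params.psf_sigma_um
    sigma_vox = (
        ax / params.voxel_size[0],
        lat / params.voxel_size[1],
        lat / params.voxel_size[2],
    )
    membrane_clean = ndimage.gaussian_filter(membrane_clean, sigma=sigma_vox)

    positions = _sample_positions(params, params.particles, rng)
    truth_particles = []
    intensities = np.zeros(len(params.particles))
    for i, spec in enumerate(params.particles):
        units = rng.normal(
            params.particle_unit_intensity,
            params.particle_intensity_cv * params.particle_unit_intensity,
            size=spec.multiplicity,
        )
        q = float(np.clip(units, 0.0, None).sum())
        intensities[i] = q
        z, y, x = positions[i]
        truth_particles.append(
            {
                "position_um": (float(x), float(y), float(z)),
                "region": spec.region,
                "multiplicity": spec.multiplicity,
                "intensity": q,
            }
        )
    particle_clean = render_spot_field(
        shape, params.voxel_size, positions, intensities, params.psf_sigma_um
    )

    membrane = _apply_noise(
        membrane_clean, params.background_level, params.poisson_scale,
        params.read_noise_sd, rng,
    )
    particle = _apply_noise(
        particle_clean, params.background_level, params.poisson_scale,
        params.read_noise_sd, rng,
    )
    truth = GroundTruth.from_particles(
        truth_particles, params.particle_unit_intensity, params.seed
    )
    return (
        VoxelGrid(membrane, params.voxel_size, "membrane"),
        VoxelGrid(particle, params.voxel_size, "particles"),
        truth,
    )


def generate_calibration_field(
    n_spots: int = 200,
    mean_intensity: float = 48090.0,
    cv: float = 0.10,
    doublet_fraction: float = 0.10,
    seed: int = 0,
    field_size_um: tuple[float, float] = (30.0, 30.0),
    n_z: int = 14,
    voxel_size: tuple[float, float, float] = (0.25, 0.11, 0.11),
    psf_sigma_um: tuple[float, float] = (0.45, 0.15),
    min_separation_um: float = 1.5,
    background_level: float = 100.0,
    poisson_scale: float = 0.5,
    read_noise_sd: float = 30.0,
    multiplicities: np.ndarray | None = None,
) -> tuple[VoxelGrid, GroundTruth]:
    """Coverslip calibration scene: isolated spots on a flat background.

    Spots sit on the mid plane (particles settled on the coverslip) with a
    hard minimum xy separation. ``doublet_fraction`` of them carry two units
    (agglomerated pairs); ``multiplicities`` overrides the per-spot unit
    counts entirely when given.
    """
    if n_spots < 1:
        raise ValueError("n_spots must be >= 1")
    rng = np.random.default_rng(seed)
    dz, dy, dx = voxel_size
    fy, fx = field_size_um
    shape = (n_z, int(np.ceil(fy / dy)), int(np.ceil(fx / dx)))
    pad = 1.0
    positions = []
    attempts = 0
    max_attempts = 200 * n_spots
    z0 = (n_z - 1) / 2.0 * dz
    while len(positions) < n_spots:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"field {field_size_um} µm too small for {n_spots} spots at "
                f"{min_separation_um} µm separation"
            )
        y = rng.uniform(pad, fy - pad)
        x = rng.uniform(pad, fx - pad)
        if positions:
            d = np.asarray(positions)
            if np.min(np.hypot(d[:, 1] - y, d[:, 2] - x)) < min_separation_um:
                continue
        positions.append((z0, y, x))
    positions = np.asarray(positions)

    if multiplicities is None:
        multiplicities = np.ones(n_spots, dtype=int)
        n_doublets = int(round(doublet_fraction * n_spots))
        doublet_idx = rng.permutation(n_spots)[:n_doublets]
        multiplicities[doublet_idx] = 2
    else:
        multiplicities = np.asarray(multiplicities, dtype=int)
        if multiplicities.size != n_spots:
            raise ValueError("multiplicities must have one entry per spot")

    intensities = np.empty(n_spots)
    truth_particles = []
    for i in range(n_spots):
        units = rng.normal(mean_intensity, cv * mean_intensity, size=multiplicities[i])
        q = float(np.clip(units, 0.0, None).sum())
        intensities[i] = q
        z, y, x = positions[i]
        truth_particles.append(
            {
                "position_um": (float(x), float(y), float(z)),
                "region": "outside",
                "multiplicity": int(multiplicities[i]),
                "intensity": q,
            }
        )
    clean = render_spot_field(shape, voxel_size, positions, intensities, psf_sigma_um)
    noisy = _apply_noise(clean, background_level, poisson_scale, read_noise_sd, rng)
    truth = GroundTruth.from_particles(truth_particles, mean_intensity, seed)
    return VoxelGrid(noisy, voxel_size, "calibration"), truth


def generate_kinetics_dataset(
    design: list[dict], seed: int = 0
) -> tuple[pd.DataFrame, list[dict]]:
    """Per-cell count tables for exercising the statistics layer.

    ``design`` rows: ``{"condition", "time_h", "n_cells", "distribution"}``
    where distribution is ``{"kind": "negative_binomial", "mean", "dispersion"}``
    (cell-to-cell uptake heterogeneity is strongly overdispersed),
    ``{"kind": "poisson", "mean"}`` or ``{"kind": "constant", "value"}``.

    Returns (table with cell_id/condition/time_h/count, echo of the design).
    """
    rng = np.random.default_rng(seed)
    rows = []
    cell_id = 0
    for entry in design:
        dist = entry["distribution"]
        n = int(entry["n_cells"])
        kind = dist["kind"]
        if kind == "constant":
            counts = np.full(n, int(dist["value"]))
        elif kind == "poisson":
            counts = rng.poisson(float(dist["mean"]), size=n)
        elif kind == "negative_binomial":
            mean, r = float(dist["mean"]), float(dist["dispersion"])
            p = r / (r + mean)
            counts = rng.negative_binomial(r, p, size=n)
        else:
            raise ValueError(f"unknown distribution kind {kind!r}")
        for c in counts:
            cell_id += 1
            rows.append(
                {
                    "cell_id": cell_id,
                    "condition": entry["condition"],
                    "time_h": entry["time_h"],
                    "count": int(c),
                }
            )
    return pd.DataFrame(rows), list(design)
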