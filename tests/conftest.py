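"""Shared fixtures: small synthetic scenes reused across test modules."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import nanouptake as nu


def match_objects_to_truth(objects, truth):
    """Index of the nearest ground-truth particle for each detected object."""
    op = np.array([[o.centroid_um[2], o.centroid_um[1], o.centroid_um[0]] for o in objects])
    tp = np.array(
        [[p["position_um"][2], p["position_um"][1], p["position_um"][0]]
         for p in truth.particles]
    )
    d = cdist(op, tp)
    return d.argmin(axis=1), d.min(axis=1)


@pytest.fixture(scope="session")
def default_detection():
    return nu.DetectionParams()


@pytest.fixture(scope="session")
def standard_cell():
    """One noisy synthetic cell with 10 intra / 5 shell / 8 outside singles."""
    specs = (
        [nu.ParticleSpec("intra")] * 10
        + [nu.ParticleSpec("shell")] * 5
        + [nu.ParticleSpec("outside")] * 8
    )
    params = nu.ScenarioParams(particles=specs, seed=42)
    membrane, particles, truth = nu.generate_cell_stack(params)
    return params, membrane, particles, truth


@pytest.fixture(scope="session")
def standard_cell_regions(standard_cell):
    _, membrane, _, _ = standard_cell
    return nu.reconstruct_cell(membrane)


@pytest.fixture(scope="session")
def small_calibration_field():
    """60 isolated single spots, noiseless — fast calibration fixture."""
    grid, truth = nu.generate_calibration_field(
        n_spots=60, cv=0.0, doublet_fraction=0.0, seed=5,
        field_size_um=(20.0, 20.0), poisson_scale=0.0, read_noise_sd=0.0,
    )
    return grid, truth


@pytest.fixture
def unit_calibration():
    """Exact calibration at the generator's default unit intensity."""
    return nu.CalibrationResult(
        i1_mean=48090.0, i1_sd=4809.0, n_spots_used=200, n_spots_rejected=0, fit_ok=True
    )
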