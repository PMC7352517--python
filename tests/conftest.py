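import numpy as np
import pytest

from stromascan import (
    PRWParams,
    SpotFieldParams,
    generate_cell_mask,
    generate_fiber_image,
    generate_spot_image,
    generate_trajectories,
    morphology_preset,
)
from stromascan.orientation import OrientationField


@pytest.fixture(scope="session")
def high_grade_phantom():
    """Aligned, crimped fiber phantom with ground-truth centerlines."""
    return generate_fiber_image(morphology_preset("high_grade"), seed=7)


@pytest.fixture(scope="session")
def single_fiber_image():
    """One straight fiber at a known angle, noise-free."""
    params = morphology_preset(
        "normal",
        n_fibers=1,
        orientation_kappa=1e9,
        orientation_mean_deg=37.0,
        fiber_length_um=150.0,
        noise_model="none",
        background_level=0.0,
    )
    return generate_fiber_image(params, seed=3)


@pytest.fixture(scope="session")
def cell_mask():
    """Moderately elongated cell mask for spot/CTCF fixtures."""
    return generate_cell_mask(
        aspect_ratio=1.5, area_um2=2000.0, angle_deg=0.0,
        pixel_size_um=0.25, seed=1,
    )


@pytest.fixture(scope="session")
def spot_phantom(cell_mask):
    """50-spot focal-adhesion phantom at amplitude/noise = 10."""
    params = SpotFieldParams(n_spots=50, spot_amplitude=100.0, noise_sd=10.0)
    image, truth = generate_spot_image(params, cell_mask, seed=2)
    return params, image, truth


@pytest.fixture(scope="session")
def prw_reference_tracks():
    """500 pure-PRW tracks at the reference motility conditions."""
    params = PRWParams(
        mu_um2_per_min=10.0, P_min=30.0, dt_min=30.0, n_frames=145, n_cells=500
    )
    return params, generate_trajectories(params, seed=1)


@pytest.fixture(scope="session")
def constant_axis_field():
    """Uniform 45-degree orientation field with full coherence."""
    shape = (50, 50)
    return OrientationField(
        angle_deg=np.full(shape, 45.0),
        coherence=np.ones(shape),
        sigma_um=1.0,
        pixel_size_um=1.0,
    )
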