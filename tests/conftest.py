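"""Shared fixtures: aperture movies, search grids, and simulation results.

Expensive artefacts (full 7,650-candidate grids, the 200-vertex recovery
simulation, the filtering-bias experiment) are session-scoped so the whole
suite builds each of them once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from prfpipe import (
    BarDesign,
    GridSpec,
    HRFSpec,
    build_grid,
    fit_map,
    generate_apertures,
)
from prfpipe.preprocess import preprocess_runs
from prfpipe.simulate import DriftSpec, make_truth_layout, simulate_runs

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def design50() -> BarDesign:
    """Default full-coverage bar design at test resolution."""
    return BarDesign(mask_resolution_px=50)


@pytest.fixture(scope="session")
def movie50(design50):
    return generate_apertures(design50, include_dummies=False)


@pytest.fixture(scope="session")
def hrf() -> HRFSpec:
    return HRFSpec()


@pytest.fixture(scope="session")
def grid50(movie50, hrf):
    """Full default search grid (7,650 candidates) on the test movie."""
    return build_grid(GridSpec(), movie50, hrf)


@pytest.fixture(scope="session")
def small_grid_spec() -> GridSpec:
    """A 120-candidate grid for brute-force cross-checks."""
    return GridSpec(
        n_angles=6,
        n_eccentricities=5,
        ecc_range=(0.5, 8.0),
        n_sigmas=4,
        sigma_range=(0.3, 3.0),
    )


@pytest.fixture(scope="session")
def recovery_results(movie50, hrf, grid50):
    """200-vertex parameter-recovery simulation at the study noise level.

    White noise only (no drift), σ spanning ~0.3–3° via the linear size law,
    eccentricity up to 8°, fitted R² on the six-run average near 0.3.
    """
    truth = make_truth_layout(
        200,
        ecc_range=(0.5, 8.0),
        sigma_law=(0.3, 0.3375),
        noise_sd=3.7,
        drift=DriftSpec(0.0, 0.0),
        seed=20240101,
    )
    dataset = simulate_runs(truth, movie50, hrf)
    data = preprocess_runs(dataset.runs)
    fits = fit_map(data, grid50, movie50, hrf)
    return truth, fits


@pytest.fixture(scope="session")
def filtering_results():
    """Packaged filtering-bias experiment at its default conditions."""
    from prfpipe.simulate import filtering_bias_experiment

    return filtering_bias_experiment(n_vertices=50, seed=20240202)
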