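"""Shared fixtures: small synthetic slides and a fitted registration.

Everything is generated programmatically at test time; fitting fixtures are
session-scoped because a registration run is the expensive step.
"""

import numpy as np
import pytest

import serialign as sa

SPACING = 16.0  # µm/px, the 1/32-downscaled working resolution


@pytest.fixture(scope="session")
def small_slide():
    """A small synthetic DAPI slide with its ground-truth cell table."""
    image, cells = sa.generate_synthetic_dapi(
        n_cells=1500, width=400, height=300, spacing=SPACING, seed=11)
    return image, cells


@pytest.fixture(scope="session")
def sim_pair(small_slide):
    """Simulated serial pair: bounded rigid + mesh-3 B-spline ground truth."""
    image, cells = small_slide
    rigid = sa.random_rigid(image, seed=12, max_rotation_deg=10.0, max_translation=500.0)
    return sa.simulate_serial_slide(image, max_displacement=300.0, mesh_size=3,
                                    rigid=rigid, seed=13, cells=cells)


@pytest.fixture(scope="session")
def fitted(sim_pair):
    """Two-step fit of the simulated pair (shared across QC/validation tests)."""
    settings = sa.OptimizerSettings(seed=21)
    rigid, rigid_report = sa.fit_rigid(sim_pair.original, sim_pair.deformed, settings)
    composite, bspline_report = sa.fit_bspline(
        sim_pair.original, sim_pair.deformed, rigid, mesh_size=6, settings=settings)
    return {"rigid": rigid, "composite": composite,
            "rigid_report": rigid_report, "bspline_report": bspline_report}


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
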