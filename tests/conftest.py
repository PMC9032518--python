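"""Shared fixtures: phantoms and the 40-year reference simulations.

The session-scoped healthy/AD runs use the default phantom geometry with a
coarser recording cadence (dt = 0.25 yr, outputs every 4 yr) so the whole
suite stays fast; the atrophy closed forms are exact for any dt.
"""
import numpy as np
import pytest

from atrophysim.mechanics import SimulationConfig, run_simulation
from atrophysim.phantom import PhantomParams, build_brain_phantom


SMALL = dict(outer_radius=40.0, fold_amplitude=5.0, n_folds=5,
             ventricle_semiaxes=(7.0, 5.0), hippocampus_radius=4.0,
             target_edge_length=2.2)


@pytest.fixture(scope="session")
def small_phantom():
    """Reduced phantom for cheap unit tests."""
    return build_brain_phantom(PhantomParams(seed=7, **SMALL))


@pytest.fixture(scope="session")
def study_phantom():
    """The default study phantom (full geometry, default mesh size)."""
    return build_brain_phantom(PhantomParams(seed=1))


@pytest.fixture(scope="session")
def healthy_result(study_phantom):
    cfg = SimulationConfig(mode="healthy", t_end=40.0, dt=0.25,
                           output_every=16)
    return run_simulation(study_phantom, config=cfg)


@pytest.fixture(scope="session")
def ad_result(study_phantom):
    cfg = SimulationConfig(mode="ad", t_end=40.0, dt=0.25, output_every=16)
    return run_simulation(study_phantom, config=cfg)


@pytest.fixture(scope="session")
def annulus_phantom():
    """Unfolded phantom with circular interfaces and analytic region areas."""
    return build_brain_phantom(PhantomParams(
        outer_radius=40.0, n_folds=0, fold_amplitude=0.0,
        ventricle_semiaxes=(7.0, 7.0), hippocampus_radius=4.0,
        hippocampus_center=(11.0, 0.0), target_edge_length=2.0, seed=0))


def tissue_mask(mesh):
    from atrophysim.phantom import GM, HIPPO, WM
    return np.isin(mesh.element_region, [WM, GM, HIPPO])
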