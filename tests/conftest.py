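"""Shared fixtures.

Heavy Monte Carlo runs are session-scoped and shared across test modules
so the default suite stays within a desk-scale runtime budget.
"""

import numpy as np
import pytest

from nirsim.head_model import PhantomSpec, make_layer_phantom
from nirsim.optics import OpticalCoefficientSet
from nirsim.transport import run_channel
from nirsim.workbench import ExperimentConfig


@pytest.fixture(scope="session")
def coefficients():
    return OpticalCoefficientSet.default()


@pytest.fixture(scope="session")
def slab_volume():
    """Default adult-forehead slab: scalp 4, skull 7, CSF 2 mm, 60 mm cube."""
    return make_layer_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def slab_optodes():
    """Emitter and detector 30 mm apart, centred on the slab surface."""
    return np.array([15.0, 30.0, 0.0]), np.array([45.0, 30.0, 0.0])


@pytest.fixture(scope="session")
def slab_run(slab_volume, coefficients, slab_optodes):
    """Reference reduced-isotropic channel run on the default slab.

    1200 detected photons: large enough for stable cumulative-profile
    quantiles and map statistics, small enough for the suite budget.
    """
    emitter, detector = slab_optodes
    return run_channel(slab_volume, coefficients, emitter, detector,
                       n_detected_target=1200, seed=20210)


@pytest.fixture(scope="session")
def small_slab():
    """Thin 30 mm slab for fast transport unit tests."""
    return make_layer_phantom(PhantomSpec(cube_edge=30.0, d_scalp=2.0,
                                          d_skull=3.0, d_csf=1.0,
                                          d_gray=4.0))


@pytest.fixture(scope="session")
def small_channel_run(small_slab, coefficients):
    """Fast channel run on the thin slab (10 mm separation)."""
    return run_channel(small_slab, coefficients,
                       np.array([10.0, 15.0, 0.0]),
                       np.array([20.0, 15.0, 0.0]),
                       n_detected_target=100, seed=99,
                       detector_radius=3.0)
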