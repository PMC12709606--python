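"""Shared fixtures.

The speckle stack (fully developed speckle at high scatterer density)
is expensive, so it is simulated once per session and shared between
the physics tests and the histogram-invariance tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from slscgcnr import ArrayGeometry
from slscgcnr.acquisition import simulate_channel_data
from slscgcnr.beamform import apply_receive_delays, das_bmode
from slscgcnr.phantom import make_phantom

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Scatterer density (per m^2) at which the simulated speckle is fully
#: developed (envelope SNR ~= 1.91); used for speckle-statistics tests.
FULLY_DEVELOPED_DENSITY = 1.5e9


@pytest.fixture(scope="session")
def geometry() -> ArrayGeometry:
    return ArrayGeometry()


def _speckle_realization(seed: int, geometry: ArrayGeometry):
    phantom = make_phantom(
        ((-6e-3, 6e-3), (15e-3, 25e-3)), FULLY_DEVELOPED_DENSITY, [], seed=seed
    )
    lines = np.linspace(-4.2e-3, 4.2e-3, 29)
    cd = simulate_channel_data(phantom, geometry, lines, seed=seed + 1000)
    return apply_receive_delays(cd, (16e-3, 24e-3))


@pytest.fixture(scope="session")
def speckle_stack(geometry):
    """Ten independent fully developed speckle realizations.

    Returns a list of ``(aligned, bmode_image)`` pairs on a 29-line,
    8 mm-deep grid around the transmit focus.
    """
    out = []
    for seed in range(1, 11):
        aligned = _speckle_realization(seed, geometry)
        out.append((aligned, das_bmode(aligned)))
    return out
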