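"""Shared fixtures: small phantoms and a cached tube posterior.

Expensive objects (fiber posteriors) are session-scoped so the tract and
skeleton tests share one computation.
"""

import numpy as np
import pytest

from hippoconn import experiments, fibermodel, phantom


@pytest.fixture(scope="session")
def desk_scheme():
    """32 directions + 4 b0 at b = 1000 s/mm² (desk-scale acquisition)."""
    return phantom.make_gradient_scheme(32, 4, 1000.0, rng_seed=0)


@pytest.fixture(scope="session")
def tube_geometry():
    return experiments.tube_phantom()


@pytest.fixture(scope="session")
def tube_posterior(tube_geometry, desk_scheme):
    """Ball-and-stick posterior over the noise-free straight-tube phantom."""
    tv = phantom.tissue_volume_from_geometry(tube_geometry)
    dwi = tv.simulate(desk_scheme)
    mask = tube_geometry.tracking_mask()
    return fibermodel.sample_posterior_volume(
        dwi, desk_scheme, mask, rng=np.random.default_rng(11)
    )
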