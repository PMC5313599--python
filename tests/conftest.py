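import numpy as np
import pytest

import localroi as lr


@pytest.fixture(scope="session")
def toy256():
    """Truncated 256-scale Shepp-Logan setup with a corrected reconstruction.

    Shared by the end-to-end tests: N0=256, N=136, N2=286, Np=400, known
    disk of radius N/10, 100 CG iterations.
    """
    phantom = lr.make_shepp_logan(256, supersample=4)
    setup = lr.make_local_setup(phantom, 136, 400)
    result = lr.correct_reconstruction(setup, sigma0=9.4, max_iters=100)
    return {"setup": setup, "result": result}


@pytest.fixture(scope="session")
def toy128():
    """Small truncated setup for the (slow per-iteration) pixel-domain baselines."""
    phantom = lr.make_shepp_logan(128, supersample=4)
    setup = lr.make_local_setup(phantom, 68, 200)
    x0, x0_ext = lr.padded_fbp(setup.sinogram, setup.geom)
    return {"setup": setup, "x0": x0, "x0_ext": x0_ext}


@pytest.fixture(scope="session")
def tv_baseline128(toy128):
    """TV-regularized pixel-domain exact reconstruction of the small setup."""
    setup = toy128["setup"]
    return lr.baseline_pixel_exact(
        setup.sinogram, setup.geom, setup.zone, lam=5.0, tv_weight=1.0, iters=800
    )


@pytest.fixture(scope="session")
def ls_baseline128(toy128):
    """Long unregularized least-squares run of the small setup."""
    setup = toy128["setup"]
    return lr.baseline_pixel_exact(
        setup.sinogram, setup.geom, setup.zone, lam=1.0, tv_weight=0.0, iters=600
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
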