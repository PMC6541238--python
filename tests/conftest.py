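import numpy as np
import pytest

import enamelsim as es


@pytest.fixture(scope="session")
def mesh65():
    return es.build_mesh(65)


@pytest.fixture(scope="session")
def mesh129():
    return es.build_mesh(129)


@pytest.fixture(scope="session")
def circle_contour():
    return es.make_shape(es.ShapeSpec(kind="circle", size=0.3), 256)


@pytest.fixture(scope="session")
def cusp_contour():
    return es.make_shape(
        es.ShapeSpec(kind="cusp_section", size=0.3, n_ridges=4,
                     ridge_amplitude=0.2), 256)


@pytest.fixture(scope="session")
def circle_levelset(mesh129):
    """Exact signed distance to a circle of radius 0.25 centred in the domain."""
    phi = np.hypot(mesh129.nodes[:, 0] - 0.5, mesh129.nodes[:, 1] - 0.5) - 0.25
    return es.LevelSetField(mesh129, phi)


@pytest.fixture(scope="session")
def short_run():
    """A short diffusion-limited run on a coarse mesh, shared by tests that
    only need a plausible FrontHistory."""
    edj = es.make_shape(es.ShapeSpec(kind="cusp_section", size=0.3, n_ridges=4,
                                     ridge_amplitude=0.3, noise_amplitude=0.02,
                                     seed=3), 192)
    params = es.GrowthParams(n_iter=60, record_every=4)
    conv = es.ConversionSpec(node_density=65)
    return es.run_simulation(edj, params, conv)
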