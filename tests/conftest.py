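import numpy as np
import pytest

import cercalsim as cs


@pytest.fixture(scope="session")
def domain():
    return cs.ConeDomain()


@pytest.fixture(scope="session")
def default_params():
    return cs.ModelParams()


@pytest.fixture(scope="session")
def random_pairs(domain):
    """200 seeded random point pairs, uniform per unit surface area."""
    from cercalsim.optimize import sample_positions

    rng = np.random.default_rng(12345)
    u = rng.random((400, 2))
    ax, ci = sample_positions(domain, u[:, 0], u[:, 1])
    return [
        (cs.SurfacePoint(ax[2 * i], ci[2 * i]), cs.SurfacePoint(ax[2 * i + 1], ci[2 * i + 1]))
        for i in range(200)
    ]


@pytest.fixture(scope="session")
def default_runs():
    """Twenty full default-parameter Monte Carlo runs (seeds 0-19).

    Shared by the acceptance checks on the ventral/dorsal ratio, hair count,
    body-frame peaks and Ripley segregation.
    """
    return [cs.run(cs.ModelParams(seed=s)) for s in range(20)]
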