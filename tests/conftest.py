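import numpy as np
import pytest

from iskit.simulate import make_catalog


@pytest.fixture(scope="session")
def catalog3():
    """Three-type synthetic catalog: IS5-like, IS256-like, IS110-like."""
    rng = np.random.default_rng(20240101)
    return make_catalog(rng, names=["ISTth7", "ISTth4", "IS1000A"])


@pytest.fixture(scope="session")
def istth7(catalog3):
    return next(r for r in catalog3 if r.name == "ISTth7")


@pytest.fixture(scope="session")
def is1000a(catalog3):
    return next(r for r in catalog3 if r.name == "IS1000A")
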