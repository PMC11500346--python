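import zlib

import numpy as np
import pytest

from meshcomp.bodymodel import build_synthetic_model


@pytest.fixture(scope="session")
def model():
    """The default synthetic body model (shared; treat as read-only)."""
    return build_synthetic_model(seed=0)


@pytest.fixture()
def rng(request):
    """Per-test deterministic generator, independent of execution order."""
    seed = zlib.adler32(request.node.nodeid.encode()) & 0x7FFFFFFF
    return np.random.default_rng(seed)
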