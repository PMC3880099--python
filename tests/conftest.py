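import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import divshift as ds

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def three_tip():
    """((A:1,B:1):1,C:2); root age 2, inner split at 1."""
    return ds.parse_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def five_two():
    """3-tip chronogram with branching times [5, 2]."""
    return ds.parse_tree("((A:2,B:2):3,C:5);")


@pytest.fixture
def balanced8():
    """Perfectly balanced 8-tip tree, node ages 3 / 2 / 1."""
    cherry = "({}:1,{}:1):1"
    quad = "(" + cherry.format("A", "B") + "," + cherry.format("C", "D") + "):1"
    quad2 = "(" + cherry.format("E", "F") + "," + cherry.format("G", "H") + "):1"
    return ds.parse_tree("(" + quad + "," + quad2 + ");")


def caterpillar(n, step=1.0):
    """Fully pectinate n-tip chronogram with equally spaced splits."""
    nwk = "x1:{:g}".format(step)
    for i in range(2, n):
        nwk = "({},x{}:{:g}):{:g}".format(nwk, i, i * step - step, step)
    nwk = "({},x{}:{:g});".format(nwk, n, (n - 1) * step)
    return ds.parse_tree(nwk)


@pytest.fixture
def caterpillar64():
    return caterpillar(64)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
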