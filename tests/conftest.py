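import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dfsvm.data_io import SyntheticSpec, make_synthetic

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

KEEL_TOY = """\
@relation toy
@attribute a1 real
@attribute a2 real
@attribute Class {positive, negative}
@inputs a1, a2
@outputs Class
@data
1.0, 2.0, positive
% a comment line

1.5, 2.5, positive
5.0, 6.0, negative
5.5, 6.5, negative
6.0, 7.0, negative
6.5, 7.5, negative
"""


@pytest.fixture
def toy_keel_text():
    return KEEL_TOY


@pytest.fixture
def separable_blobs():
    """Well-separated 2-class blobs, imbalance ratio 5."""
    return make_synthetic(
        SyntheticSpec(p=2, n_maj=50, ir=5, class_separation=8.0, seed=1)
    )


@pytest.fixture
def overlapping_blobs():
    """Moderately overlapping blobs, imbalance ratio 10."""
    return make_synthetic(
        SyntheticSpec(p=5, n_maj=100, ir=10, class_separation=2.5, seed=2)
    )
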