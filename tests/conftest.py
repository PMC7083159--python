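import numpy as np
import pytest

from crmloc.saliency import FeatureStack, GapLinearModel, LinearHead, RelevanceMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_head(rng, k, n_classes):
    return LinearHead(rng.normal(size=(k, n_classes)), rng.normal(size=n_classes))


def random_stack(rng, u, v, k):
    return FeatureStack(rng.normal(size=(u, v, k)))


def random_map(rng, shape=(4, 4)):
    return RelevanceMap(np.abs(rng.normal(size=shape)))


@pytest.fixture
def worked_example():
    """2x2 single-channel stack with a +1/-1 two-class GAP head.

    Hand enumeration: removing (0,0) changes both logits by 1/4, removing
    (1,1) by 2/4; the summed squared changes are 0.125 and 0.5.
    """
    stack = FeatureStack(np.array([[1.0, 0.0], [0.0, 2.0]])[:, :, None])
    head = LinearHead(np.array([[1.0, -1.0]]), np.zeros(2))
    expected = np.array([[0.125, 0.0], [0.0, 0.5]])
    return stack, head, GapLinearModel(head), expected
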