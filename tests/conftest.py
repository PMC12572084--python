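import numpy as np
import pytest

import contrastkit as ck

MARAVER_LABELS = ("imagine", "memorize", "pay attention")
AKAN_LABELS = ("testing", "restudying", "control")


@pytest.fixture
def hyp1():
    """Favored pattern: first condition above the average of the others."""
    return ck.validate_weights(MARAVER_LABELS, (1, -0.5, -0.5))


@pytest.fixture
def hyp2():
    """Rival pattern: strictly decreasing across the three conditions."""
    return ck.validate_weights(MARAVER_LABELS, (1, 0, -1))


@pytest.fixture
def maraver():
    return ck.load_fixture("maraver_summaries")


@pytest.fixture
def akan():
    return ck.load_fixture("akan_toy")


@pytest.fixture
def akan_hyp1():
    return ck.validate_weights(AKAN_LABELS, (1, -0.5, -0.5))


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
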