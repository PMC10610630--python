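import numpy as np
import pytest

import ecgunet as eu
from ecgunet.io import BeatAnnotation, BeatClass


@pytest.fixture(scope="session")
def default_model():
    """Untrained default network, shared (read-only forward use only)."""
    return eu.build_unet()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_beats(idx_cls):
    """[(index, 'N'|'V'), ...] -> sorted BeatAnnotation list."""
    cls = {"N": BeatClass.NORMAL, "V": BeatClass.PVC}
    return sorted(BeatAnnotation(i, cls[c]) for i, c in idx_cls)


@pytest.fixture()
def beats_factory():
    return make_beats
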