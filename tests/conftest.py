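import numpy as np
import pytest

from barrelquant import synthdata as sd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_widefield_spec():
    """Reduced-frame widefield spec: study timing/amplitudes, small field."""
    return sd.WidefieldSimSpec(
        raw_height=48, raw_width=48, response_sigma=16.0, n_trials=60, seed=0
    )


def center_roi(shape):
    """Boolean mask selecting the central pixel of a (h, w) frame."""
    m = np.zeros(shape, dtype=bool)
    m[shape[0] // 2, shape[1] // 2] = True
    return m
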