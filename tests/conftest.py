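import numpy as np
import pytest
from hypothesis import settings

from pslife.model import LifetimeParams

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")

# Table-2-style generative parameter sets (tau3 in ns, BR on the simplex)
TUBE_PARAMS = {
    "T1_dry": dict(tau3=2.52, br=(0.073, 0.716, 0.211)),
    "T2_wet": dict(tau3=2.37, br=(0.081, 0.702, 0.217)),
    "T3_gelatine": dict(tau3=2.27, br=(0.073, 0.705, 0.222)),
    "T4_water": dict(tau3=1.82, br=(0.088, 0.644, 0.268)),
}
VOXEL_T4 = dict(tau3=2.0, br=(0.062, 0.683, 0.255))


@pytest.fixture
def t4_params():
    return LifetimeParams(sigma=0.12, delta=0.0, **TUBE_PARAMS["T4_water"])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_tdd(params, n_signal, bg_frac=0.10, seed=0):
    """Background-annotated synthetic TDD from the direct sampler."""
    from pslife.histo import build_tdd, with_background
    from pslife.phantom import sample_tdd_direct

    n_bg = int(round(n_signal * bg_frac / (1.0 - bg_frac)))
    deltas = sample_tdd_direct(params, n_signal, n_bg, seed=seed)
    return with_background(build_tdd(deltas))
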