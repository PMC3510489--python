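import numpy as np
import pytest

from helimodal import BinormalSpec, HelicalEnsemble, sample_binormal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gaussian_ensemble():
    """5000 draws from a single Gaussian, as a CG-twist ensemble."""
    rng = np.random.default_rng(7)
    return HelicalEnsemble(step_type="CG", parameter="twist", origin="md",
                           values=rng.normal(34.0, 3.0, size=5000))


@pytest.fixture
def separated_mixture_ensemble():
    """Well-separated binormal sample (modes 4 SD apart, equal weights)."""
    return sample_binormal(BinormalSpec(0.0, 1.0, 4.0, 1.0, 0.5), 10000, seed=11)


def make_ensemble(values, step_type="CG", parameter="twist", origin="md",
                  times=None):
    return HelicalEnsemble(step_type=step_type, parameter=parameter,
                           origin=origin, values=np.asarray(values, float),
                           times=times)
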