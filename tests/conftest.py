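import numpy as np
import pytest

from gcxquant import IntensityProfile, ProfileSpec, generate_profile_pair


@pytest.fixture
def default_spec():
    return ProfileSpec()


@pytest.fixture
def noisefree_pair(default_spec):
    return generate_profile_pair(default_spec, seed=0)


def make_logistic_profile(x0=1.2, s=0.1, lower=0.0, upper=100.0,
                          length=5.0, step=0.05, label="marker"):
    """Exact (noise-free, unblurred) rising logistic profile."""
    x = np.arange(0.0, length + step / 2, step)
    y = lower + (upper - lower) / (1.0 + np.exp(-(x - x0) / s))
    return IntensityProfile(x, y, channel_label=label)


def scaled_differences(mean, sd, n, seed=None):
    """A vector with exactly the requested sample mean and SD (ddof=1)."""
    if seed is None:
        z = np.arange(n, dtype=float)
    else:
        z = np.random.default_rng(seed).normal(size=n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z
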