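import numpy as np
import pytest

from fric import (AnalysisConfig, ChannelMap, SyntheticParams,
                  generate_nucleus_pair)


@pytest.fixture(scope="session")
def channel_map() -> ChannelMap:
    return ChannelMap(euchromatin="euchromatin", total="total")


@pytest.fixture()
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def clean_pair():
    """One default noisy nucleus with a 0.2 peripheral depression."""
    params = SyntheticParams(peripheral_depression=0.2)
    return generate_nucleus_pair(params, seed=12345)


@pytest.fixture(scope="session")
def flat_pair():
    """Ideal uniform nucleus: no depression, no noise, no texture."""
    params = SyntheticParams(peripheral_depression=0.0, poisson_noise=False,
                             read_noise_sd=0.0, background=0.0,
                             texture_amplitude=0.0, quantize=False)
    return generate_nucleus_pair(params, seed=7)


def disc_mask(radius: int, pad: int = 3) -> np.ndarray:
    """Boolean disc of the given pixel radius, centred in a padded frame."""
    n = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[0:n, 0:n]
    c = radius + pad
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2
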