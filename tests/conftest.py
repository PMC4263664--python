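import numpy as np
import pytest

from lvseg.config import PipelineConfig
from lvseg.phantom import PhantomSpec, generate_phantom_study
from lvseg.pipeline import segment_study


@pytest.fixture(scope="session")
def phantom_default():
    """Default 8-slice two-phase phantom (no LVOT), seed 0."""
    return generate_phantom_study(PhantomSpec())


@pytest.fixture(scope="session")
def phantom_lvot():
    """Same phantom with the basal LVOT channel open."""
    return generate_phantom_study(PhantomSpec(lvot=True))


@pytest.fixture(scope="session")
def seg_default(phantom_default):
    study, _ = phantom_default
    return segment_study(study, PipelineConfig())


@pytest.fixture(scope="session")
def seg_default_rerun():
    """Independent regeneration + second run of the identical study."""
    study, _ = generate_phantom_study(PhantomSpec())
    return segment_study(study, PipelineConfig())


@pytest.fixture(scope="session")
def seg_lvot(phantom_lvot):
    study, _ = phantom_lvot
    return segment_study(study, PipelineConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def noisy_disk(seed: int, shape=(80, 80), radius=20.0, inside=100.0,
               outside=20.0, noise_sd=8.0, bias_amplitude=0.1):
    """Noisy biased disk fixture at SNR = contrast / noise_sd = 10.

    Returns (image, true disk mask, overlapping init mask).
    """
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    c = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    disk = (rr - c[0]) ** 2 + (cc - c[1]) ** 2 <= radius ** 2
    init = (rr - c[0] + 5) ** 2 + (cc - c[1] + 5) ** 2 <= (0.6 * radius) ** 2
    xn = 2.0 * cc / (shape[1] - 1) - 1.0
    yn = 2.0 * rr / (shape[0] - 1) - 1.0
    bias = 1.0 + bias_amplitude * (0.5 * xn + 0.3 * yn + 0.2 * xn * yn)
    g = np.random.default_rng(seed)
    img = np.where(disk, inside, outside) * bias + g.normal(0.0, noise_sd, shape)
    return np.clip(img, 0.0, None), disk, init
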