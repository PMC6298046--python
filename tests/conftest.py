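import numpy as np
import pytest

from msifilter import MSIDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(intensities, mz=None, shape=None, **kwargs) -> MSIDataset:
    """Build a small dataset from a (pixels x peaks) array."""
    intensities = np.asarray(intensities, dtype=float)
    n_pixels, n_peaks = intensities.shape
    if mz is None:
        mz = 500.0 + 10.0 * np.arange(n_peaks)
    if shape is None:
        # prefer a roughly square factorisation
        n_rows = int(np.sqrt(n_pixels))
        while n_pixels % n_rows:
            n_rows -= 1
        shape = (n_rows, n_pixels // n_rows)
    return MSIDataset(intensities, np.asarray(mz, float), shape, **kwargs)


@pytest.fixture
def blob_image():
    """10x10 image: solid 4x4 blob of value 10 on zero background."""
    img = np.zeros((10, 10))
    img[3:7, 3:7] = 10.0
    return img


@pytest.fixture
def synthetic_small():
    from msifilter import generate

    return generate(shape=(32, 32), n_structured=6, n_off_tissue=4, n_noise=4, seed=3)
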