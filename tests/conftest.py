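import numpy as np
import pytest

from histofuse.imaging_io import RasterImage


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_gray(rng):
    return RasterImage(pixels=rng.uniform(0, 1, size=(8, 8)))


@pytest.fixture
def random_rgb(rng):
    return RasterImage(pixels=rng.uniform(0, 1, size=(8, 8, 3)), color_mode="rgb")


@pytest.fixture
def tiny_dataset_dir(tmp_path):
    """5 class folders x 3 small images, written as PNGs."""
    from histofuse.imaging_io import write_image
    gen = np.random.default_rng(7)
    root = tmp_path / "data"
    for c in range(5):
        for i in range(3):
            img = RasterImage(pixels=gen.uniform(0, 1, size=(16, 16, 3)),
                              color_mode="rgb")
            write_image(img, root / f"class_{c}" / f"img_{i}.png")
    return root
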