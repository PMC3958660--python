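import numpy as np
import pytest
from PIL import Image

from cottoncover import RGBImage


@pytest.fixture
def write_png(tmp_path):
    """Write an arbitrary uint8 array as a PNG and return its path."""

    def _write(arr, name="img.png", mode=None):
        path = tmp_path / name
        Image.fromarray(np.asarray(arr, dtype=np.uint8), mode=mode).save(path)
        return path

    return _write


@pytest.fixture
def uniform_image():
    """Factory for constant-color images."""

    def _make(rgb, h=4, w=5):
        return RGBImage(np.full((h, w, 3), rgb, dtype=np.uint8), source_id="uniform")

    return _make
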