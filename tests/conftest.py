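import numpy as np
import pytest
from hypothesis import settings

from condquant.io import Image2D

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def disk_field():
    """64x64 field: background 10, one hard-edged disk (r=5) at 100.

    Returns the image plus the brute-force rasterized disk pixel set used
    as the segmentation oracle.
    """
    pixels = np.full((64, 64), 10.0)
    cy, cx = 30, 28
    disk = {
        (cy + dy, cx + dx)
        for dy in range(-5, 6)
        for dx in range(-5, 6)
        if dy * dy + dx * dx <= 25
    }
    for r, c in disk:
        pixels[r, c] = 100.0
    return Image2D(pixels, channel_name="test"), disk
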