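import numpy as np
import pytest

from icmq.types import CellAnnotation, Micrograph


def rect(x0, y0, x1, y1):
    return [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]


@pytest.fixture
def flat_image():
    """10x12 brightfield image uniformly at 50 a.u."""
    return Micrograph(pixels=np.full((10, 12), 50.0), bit_depth=8)


@pytest.fixture
def cell_3x3():
    """3x3 cell with a 1-pixel nucleus, axis top-to-bottom, on an 8x8 frame."""
    return CellAnnotation(
        cell_id="c1",
        polygon=rect(1, 1, 4, 4),
        nucleus=rect(2, 2, 3, 3),
        axis=((2.5, 1.0), (2.5, 4.0)),
        animal_id="m1",
        group="g1",
    )
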