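import numpy as np
import pytest

from mitoquant.image_core import BinaryMask, Image2D, LabeledMask
from mitoquant.segmentation import CellSegmentation
from mitoquant.synthetic import FieldParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """A compact 4-cell field for fast pipeline tests."""
    return FieldParams(field_size_px=(250, 250), n_cells=4)


def make_image(pixels, px=1.0):
    return Image2D(np.asarray(pixels, dtype=float), px)


def make_mask(pixels, px=1.0):
    return BinaryMask(np.asarray(pixels, dtype=bool), px)


def make_labels(pixels, px=1.0):
    arr = np.asarray(pixels, dtype=np.int32)
    n = int(arr.max())
    return LabeledMask(arr, px, n)


def grid_cells(n=10, cell=6, px=1.0):
    """A CellSegmentation of n square cells on one row, with square nuclei."""
    H = cell + 4
    W = n * (cell + 2) + 2
    cells = np.zeros((H, W), dtype=np.int32)
    nuclei = np.zeros((H, W), dtype=np.int32)
    for i in range(n):
        x0 = 2 + i * (cell + 2)
        cells[2 : 2 + cell, x0 : x0 + cell] = i + 1
        nuclei[3 : 3 + cell // 2, x0 + 1 : x0 + 1 + cell // 2] = i + 1
    return CellSegmentation(
        nuclei=LabeledMask(nuclei, px, n), cells=LabeledMask(cells, px, n)
    )
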