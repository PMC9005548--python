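import numpy as np
import pytest

from gliomavote.embedding import HistogramEmbedding, embed
from gliomavote.sampling import Tile
from gliomavote.synthetic import DEFAULT_RECIPES, generate_tile


def make_tile(pixels, slide_id="t", origin=(0, 0), size_px=None, label=None):
    pixels = np.asarray(pixels)
    return Tile(pixels=pixels, slide_id=slide_id, origin=origin,
                size_px=size_px or pixels.shape[0], label=label)


def class_tiles(label, n, size_px=224, seed0=0):
    return [
        make_tile(generate_tile(DEFAULT_RECIPES[label], size_px, seed0 + s),
                  slide_id=label, origin=(s, 0))
        for s in range(n)
    ]


@pytest.fixture(scope="session")
def model():
    return HistogramEmbedding()


@pytest.fixture(scope="session")
def class_features(model):
    """20 embedded default tiles per subtype plus the irrelevant recipe."""
    out = {}
    for label in ("A", "O", "G", "I"):
        tiles = class_tiles(label, 20)
        out[label] = embed(tiles, model)
    return out
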