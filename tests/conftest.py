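import json
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ct2bmd import load_sample_dataset
from ct2bmd.imaging import CTSlice, quantize


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def sample_table():
    return load_sample_dataset()


@pytest.fixture
def checkerboard_qroi():
    """4x4 two-level checkerboard, already quantized."""
    levels = np.indices((4, 4)).sum(axis=0) % 2
    return quantize(levels.astype(float), 2)


@pytest.fixture
def fixture_image(tmp_path):
    """Write a small raster fixture (PNG + sidecar) and return its path with
    the expected HU grid."""

    def _make(stored, slope=1.0, intercept=0.0, name="slice.png"):
        import imageio.v3 as iio

        stored = np.asarray(stored, dtype=np.uint16)
        path = tmp_path / name
        iio.imwrite(path, stored)
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump({"rescale_slope": slope, "rescale_intercept": intercept}, fh)
        return path, stored.astype(float) * slope + intercept

    return _make


@pytest.fixture
def reference_model_path():
    return Path(__file__).parent / "data" / "reference_model.json"
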