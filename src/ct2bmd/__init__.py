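"""ct2bmd: bone mineral density regression from CT texture features."""

from importlib.resources import files

import pandas as pd

from . import calibration, imaging, neuralnet, pipeline, synthetic, texture  # noqa: F401
from .errors import CT2BMDError  # noqa: F401

__version__ = "0.1.0"


def load_sample_dataset() -> pd.DataFrame:
    """Packaged nine-row sample feature/BMD table (columns: contrast,
    correlation, energy, homogeneity, entropy, bmd)."""
    with files("ct2bmd.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)
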