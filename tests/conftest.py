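import numpy as np
import pandas as pd
import pytest

from nucleopol.io import rectangle_roi


@pytest.fixture
def square_roi():
    """10 × 10 µm square ROI (nm units)."""
    return rectangle_roi(10_000.0, 10_000.0)


@pytest.fixture
def unit_square_roi():
    return rectangle_roi(1.0, 1.0)


def make_table(xy, channel="A", precision=20.0):
    xy = np.asarray(xy, float).reshape(-1, 2)
    return pd.DataFrame(
        {
            "x_nm": xy[:, 0],
            "y_nm": xy[:, 1],
            "frame": np.arange(len(xy), dtype=int),
            "precision_nm": float(precision),
            "channel": channel,
        }
    )


@pytest.fixture
def table_factory():
    return make_table
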