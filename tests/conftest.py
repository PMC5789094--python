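import numpy as np
import pandas as pd
import pytest

import nanocal as nc
from nanocal.tables import LocalizationTable


@pytest.fixture(scope="session")
def default_config():
    return nc.SimConfig(seed=1)


@pytest.fixture(scope="session")
def small_field(default_config):
    """50-ruler DNA-PAINT field at 60 nm nominal distance, with truth."""
    table, truth = nc.generate_nanoruler_field(default_config, 50,
                                               (20_000.0, 20_000.0))
    return table, truth


@pytest.fixture(scope="session")
def measured_small_field(small_field):
    table, truth = small_field
    fits, accepted = nc.measure_field(table)
    return table, truth, fits, accepted


def make_table(xy, pixel_size=100.0, frame_time=0.1, frames=None,
               field_size=None):
    """Wrap raw coordinates into a LocalizationTable for unit tests."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    df = pd.DataFrame({
        "frame": np.zeros(n, dtype=np.int64) if frames is None
                 else np.asarray(frames, dtype=np.int64),
        "x_nm": xy[:, 0], "y_nm": xy[:, 1],
        "photons": np.full(n, 400.0),
        "sigma_nm": np.full(n, 5.0),
    })
    return LocalizationTable(df=df, pixel_size=pixel_size,
                             frame_time=frame_time, field_size=field_size)
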