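import datetime

import numpy as np
import pandas as pd
import pytest

from planacast import synthetic, zonal
from planacast.zonal import COUNT_COLUMN, LaggedDataset

START = datetime.date(2014, 3, 1)


@pytest.fixture(scope="session")
def layout():
    return synthetic.default_layout()


@pytest.fixture(scope="session")
def block_rh_table(layout):
    """Two years of daily block RH plus the six-week lag lead-in."""
    return synthetic.generate_block_rh(
        layout,
        START - datetime.timedelta(days=56),
        START + datetime.timedelta(days=14 * 47),
        seed=11,
    )


@pytest.fixture(scope="session")
def lagged_dataset(layout, block_rh_table):
    """Full-size lagged dataset with the default nonlinear T1-T3 response."""
    census = synthetic.generate_census(
        layout, block_rh_table, synthetic.ResponseSpec(seed=5), start_date=START
    )
    series = zonal.block_series_from_table(block_rh_table)
    return zonal.clean_dataset(zonal.assemble_lagged(series, census))


def make_dataset(columns: dict, n: int | None = None) -> LaggedDataset:
    """LaggedDataset from raw column arrays (lags default to zeros)."""
    n = n if n is not None else len(next(iter(columns.values())))
    frame = pd.DataFrame(
        {
            "block_id": ["A01"] * n,
            "cycle_index": np.arange(n),
            "census_date": [START + datetime.timedelta(days=14 * i) for i in range(n)],
            COUNT_COLUMN: np.zeros(n),
            **{f"rh_T{k}": np.zeros(n) for k in range(1, 7)},
        }
    )
    for name, vals in columns.items():
        frame[name] = np.asarray(vals, dtype=float)
    return LaggedDataset(frame=frame)
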