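import numpy as np
import pandas as pd
import pytest

from msmiss import DGMConfig, PanelData, simulate_full_data
from msmiss.panel import mask_columns, wide_columns


@pytest.fixture(scope="session")
def dgm():
    return DGMConfig()


@pytest.fixture(scope="session")
def small_panel(dgm):
    """A complete panel of 400 subjects from the default DGM."""
    return simulate_full_data(dgm, 400, 12345)


@pytest.fixture(scope="session")
def big_panel(dgm):
    """A complete panel of 50,000 subjects for Monte Carlo checks."""
    return simulate_full_data(dgm, 50_000, 999)


def make_panel(rows, n_times=3, mask_cells=(), dgm=None):
    """Hand-build a panel from a list of dicts; mask_cells = [(row, 'L1_1'), ...]."""
    df = pd.DataFrame(rows)
    if "id" not in df.columns:
        df.insert(0, "id", np.arange(len(df)))
    if "V" not in df.columns:
        df.insert(1, "V", 0.0)
    df = df.loc[:, wide_columns(n_times)]
    mask = pd.DataFrame(False, index=df.index, columns=mask_columns(n_times))
    for row, cell in mask_cells:
        mask.loc[row, f"M_{cell}"] = True
    return PanelData(df, mask, n_times, dgm)
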