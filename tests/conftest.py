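import numpy as np
import pandas as pd
import pytest

import maxhab as mh
from maxhab.stack import SampleMatrix


@pytest.fixture(scope="session")
def world():
    """Compact synthetic study system with known ground truth."""
    stack, model, suit = mh.default_world(seed=11, n_rows=50, n_cols=50)
    return stack, model, suit


@pytest.fixture(scope="session")
def fitted_matrix(world):
    """Thinned presences + background sample on the synthetic world."""
    stack, _, suit = world
    occ = mh.sample_occurrences(stack, suit, 200, seed=21)
    thinned, _ = mh.thin(occ, stack.grid, seed=22)
    matrix, _ = mh.make_sample_matrix(stack, thinned, n_background=800, seed=23)
    return matrix


def toy_matrix(pres: dict, bg: dict) -> SampleMatrix:
    """SampleMatrix from raw columns; cells are made artificially distinct."""
    dp = pd.DataFrame(pres)
    db = pd.DataFrame(bg)
    data = pd.concat([dp, db], ignore_index=True)
    n = len(data)
    cells = np.column_stack([np.zeros(n, dtype=int), np.arange(n)])
    is_pres = np.r_[np.ones(len(dp), bool), np.zeros(len(db), bool)]
    return SampleMatrix(data, is_pres, cells)
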