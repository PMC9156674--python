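import numpy as np
import pytest
from shapely.geometry import box

from sandsheet import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_scar_scenario():
    """Noiseless landscape with disjoint early (30%) and late (20%) scars in 2005.

    On a 100-cell-wide strip the early scar covers columns 0-29 and the late
    scar columns 40-59 of every row, so the true burnt proportions are 0.30
    and 0.50 for the union.
    """
    cell = 30.0
    nrows, ncols = 10, 100
    early = box(0, 0, 30 * cell, nrows * cell)
    late = box(40 * cell, 0, 60 * cell, nrows * cell)
    events = [
        sd.FireEvent(2005, "early", early, amplitude=1.0),
        sd.FireEvent(2005, "late", late, amplitude=1.0),
    ]
    return sd.FireScenario(
        nrows=nrows,
        ncols=ncols,
        cell_size=cell,
        year_start=2000,
        year_end=2010,
        events=events,
        static_sd=0.05,
        noise_sd=0.0,
        seed=7,
    )


@pytest.fixture
def small_domain():
    return box(0, 0, 200, 200)
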