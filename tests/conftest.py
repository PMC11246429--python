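import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from nmrbind.core import DecayTable, DispersionTable, ItcTable, TitrationDesign


@pytest.fixture
def study_design():
    """100 uM labeled protein, partner admixtures 0/50/100/150 %."""
    return TitrationDesign(
        100.0,
        (("0%", 0.0), ("50%", 50.0), ("100%", 100.0), ("150%", 150.0)),
        partner_id="partner",
    )


@pytest.fixture
def decay_table():
    """Noiseless mono-exponential decay, R = 5 s^-1, at the 7-delay scheme."""
    delays = np.linspace(0.010, 0.230, 7)
    rows = [(1, t, 100.0 * np.exp(-5.0 * t), 1.0) for t in delays]
    return DecayTable(pd.DataFrame(rows, columns=DecayTable.COLUMNS))


def make_dispersion_frame(rows):
    return DispersionTable(pd.DataFrame(rows, columns=DispersionTable.COLUMNS))


@pytest.fixture
def itc_design():
    """Study-design ITC: 30 uM cell, 300 uM syringe, 19 x 2 uL."""
    inj = pd.DataFrame({"volume_ul": [2.0] * 19, "heat_ucal": [0.0] * 19})
    return ItcTable(30.0, 300.0, 200.0, inj)
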