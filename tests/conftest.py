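"""Shared fixtures: synthetic datasets and (expensive) inversions.

Inversions are session-scoped so acceptance tests and diagnostics share them.
"""

import warnings

import numpy as np
import pytest

from cabayes import (InversionOptions, default_parameters, make_fixture)
from cabayes.events import EventSet
from cabayes.pipeline import invert_trace

warnings.filterwarnings("ignore", category=RuntimeWarning)

SEED = 1


@pytest.fixture(scope="session")
def qgif_fast():
    return make_fixture("qgif_fast_rise", SEED)


@pytest.fixture(scope="session")
def fhn_low():
    return make_fixture("fhn_low_snr", SEED)


@pytest.fixture(scope="session")
def qgif_slow():
    return make_fixture("qgif_slow_rise", SEED)


def run_inversion(fx, match_window=None, max_iter=40, lockout=None):
    truth = EventSet(fx["sim"].spike_times, source="true")
    return invert_trace(fx["noisy"], model=fx["inv_set"].model,
                        inv_set=fx["inv_set"], truth=truth,
                        match_window=match_window, lockout=lockout,
                        options=InversionOptions(max_iter=max_iter))


@pytest.fixture(scope="session")
def qgif_fast_inverted(qgif_fast):
    return run_inversion(qgif_fast)


@pytest.fixture(scope="session")
def fhn_low_inverted(fhn_low):
    return run_inversion(fhn_low)
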