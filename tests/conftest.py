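"""Shared simulation fixtures.

The heavier coupled simulations (entrained baseline, constant-routine
deprivation, jet lag, chronic restriction) are session-scoped so each
protocol is integrated once for the whole suite.
"""

import pytest

import circapain as ca
from circapain import validate


@pytest.fixture(scope="session")
def baseline_result():
    """Entrained 14:10 light:dark run at 600:0 lux, spin-up included."""
    return ca.simulate(ca.baseline_protocol((14.0, 10.0), 600.0, 0.0, 15.0))


@pytest.fixture(scope="session")
def baseline_exp(baseline_result):
    return baseline_result.experiment()


@pytest.fixture(scope="session")
def dark_run():
    """Free-running clock: 15 days of constant darkness."""
    return ca.simulate(ca.baseline_protocol((14.0, 10.0), 0.0, 0.0, 15.0)).experiment()


@pytest.fixture(scope="session")
def cr_exp():
    """The 34 h constant-routine deprivation run with recovery tail."""
    return ca.simulate(ca.daguet_cr_protocol()).experiment()


@pytest.fixture(scope="session")
def cr_calibration():
    return validate.cr_calibration()


@pytest.fixture(scope="session")
def cr_recovery():
    return validate.cr_recovery()


@pytest.fixture(scope="session")
def east_summary():
    return validate.jetlag_summary("east")


@pytest.fixture(scope="session")
def west_summary():
    return validate.jetlag_summary("west")


@pytest.fixture(scope="session")
def chronic():
    return validate.chronic_summary()


@pytest.fixture(scope="session")
def sweep():
    return validate.sweep_summary((24.0, 30.0, 40.0, 48.0))
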