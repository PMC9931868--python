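import numpy as np
import pytest

from petkin.core import FrameSchedule
from petkin.input_function import InputFunction, feng_input
from petkin.kinetic import Params2T

FENG = {"A1": 800.0, "A2": 20.0, "A3": 10.0, "lam1": 4.0, "lam2": 0.5,
        "lam3": 0.008}


@pytest.fixture(scope="session")
def sch60():
    return FrameSchedule.paper_schedule(60)


@pytest.fixture(scope="session")
def sch90():
    return FrameSchedule.paper_schedule(90)


@pytest.fixture(scope="session")
def inp60(sch60):
    return feng_input(FENG, sch60)


@pytest.fixture(scope="session")
def inp90(sch90):
    return feng_input(FENG, sch90)


@pytest.fixture(scope="session")
def constant_input():
    """C_p identically 1 out to 120 min."""
    return InputFunction([0.0, 120.0], [1.0, 1.0])


@pytest.fixture(scope="session")
def tumor_rhpsma():
    """Reported PSMA-tracer tumor truth; k2 solved from VT = 0.24."""
    return Params2T.from_vt(K1=0.34, k3=0.6, k4=0.47, VT=0.24)


@pytest.fixture(scope="session")
def brain_rhpsma():
    """Reported brain truth; k2 solved from VT = 0.1, k4 shared with tumor."""
    return Params2T.from_vt(K1=0.08, k3=0.15, k4=0.47, VT=0.1)
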