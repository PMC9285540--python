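import pytest

from tundracn.calibration import calibrate


@pytest.fixture(scope="session")
def cal_I():
    return calibrate("I")


@pytest.fixture(scope="session")
def cal_II():
    return calibrate("II")


@pytest.fixture(scope="session")
def cal_III():
    return calibrate("III")


@pytest.fixture(scope="session")
def calibrations(cal_I, cal_II, cal_III):
    return {"I": cal_I, "II": cal_II, "III": cal_III}
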