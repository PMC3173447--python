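import numpy as np
import pytest

import dcekinet as dk


@pytest.fixture(scope="session")
def frame_times():
    return dk.STANDARD_FRAME_TIMES


@pytest.fixture(scope="session")
def weinmann():
    """Population AIF on a dense time axis (t = 0 at injection)."""
    return dk.weinmann_aif(dose=0.1, times=np.linspace(0.0, 10.0, 201))


@pytest.fixture(scope="session")
def table3():
    return dk.load_table3()


@pytest.fixture(scope="session")
def table3_split(table3):
    """(changes-by-column, non-responder mask, grade array) helper tuple."""
    nonresp = table3["sataloff"].isin(["C", "D"]).to_numpy()
    grade = table3["sataloff"].to_numpy()
    return table3, nonresp, grade


@pytest.fixture(scope="session")
def clean_phantom():
    """Default noise-free phantom with a single (0.2, 0.3) lesion."""
    return dk.generate_phantom()
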