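import pytest

from ionphase import fixtures, seqcharge


@pytest.fixture(scope="session")
def caprin1_wt():
    return fixtures.builtin_sequence("caprin1_wt")


@pytest.fixture(scope="session")
def py_caprin1():
    return fixtures.builtin_sequence("py_caprin1")


@pytest.fixture(scope="session")
def cs_wt(caprin1_wt):
    return seqcharge.charge_sequence(caprin1_wt)


@pytest.fixture(scope="session")
def cs_py(py_caprin1):
    return seqcharge.charge_sequence(py_caprin1)
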