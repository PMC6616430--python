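import pytest

import trnacode as tc


@pytest.fixture(scope="session")
def type1_model():
    return tc.build_trna_pri("I")


@pytest.fixture(scope="session")
def type2_model():
    return tc.build_trna_pri("II")


@pytest.fixture(scope="session")
def precursor():
    return tc.assemble_precursor_sequence()


@pytest.fixture(scope="session")
def class1_matrix():
    return tc.packaged_matrix("class1")


@pytest.fixture(scope="session")
def class2_matrix():
    return tc.packaged_matrix("class2")


@pytest.fixture(scope="session")
def trajectory():
    return tc.run_full_trajectory()


@pytest.fixture(scope="session")
def standard_state():
    return tc.standard_code_state()
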