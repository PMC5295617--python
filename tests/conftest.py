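import pytest

from onesnpaway import appio
from onesnpaway.seqcore import standard_code


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture(scope="session")
def lambda_rz():
    return appio.lambda_rz_cds()


@pytest.fixture(scope="session")
def lambda_arch():
    return appio.lambda_architecture()


@pytest.fixture(scope="session")
def lambda_rz1(lambda_arch):
    return lambda_arch.embedded_cds()


@pytest.fixture(scope="session")
def rz_records():
    return appio.table3_records("Rz")


@pytest.fixture(scope="session")
def rz1_records():
    return appio.table3_records("Rz1")
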