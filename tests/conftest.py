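import pytest

from gabaflux import build_core_model, build_mini_model
from gabaflux.synthetic import CoreModelParams


@pytest.fixture(scope="session")
def core_model():
    return build_core_model()


@pytest.fixture(scope="session")
def core_no_shunt():
    """Core variant without the GABA shunt or uptake (no alpha-KG bypass)."""
    return build_core_model(
        CoreModelParams(include_gaba_shunt=False, include_gaba_uptake=False)
    )


@pytest.fixture(scope="session")
def m1():
    return build_mini_model("M1")


@pytest.fixture(scope="session")
def m1_product():
    return build_mini_model("M1_product")


@pytest.fixture(scope="session")
def cycle_model():
    return build_mini_model("cycle")


@pytest.fixture(scope="session")
def akg_node():
    return build_mini_model("akg_node")


@pytest.fixture(scope="session")
def shunt_leak():
    return build_mini_model("shunt_leak")
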