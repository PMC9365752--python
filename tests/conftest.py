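import pytest

from acinusim import build_constants, build_model_spec, discretize


@pytest.fixture(scope="session")
def constants():
    return build_constants()


@pytest.fixture(scope="session")
def symmetric_small_spec(constants):
    """Smallest symmetric study geometry (both daughters 5.76e-4 ml)."""
    return build_model_spec(
        constants, v_bru1=5.76e-4, v_bru2=5.76e-4, convection_enabled=True
    )


@pytest.fixture(scope="session")
def asym_spec(constants):
    """The fixed asymmetric geometry (BrU1 half of BrU2)."""
    return build_model_spec(
        constants, v_bru1=3.88e-3, v_bru2=7.76e-3, convection_enabled=True
    )


@pytest.fixture(scope="session")
def reference_spec(constants):
    """Symmetric reference geometry (both daughters at V_ref = 7.76e-3 ml)."""
    return build_model_spec(
        constants, v_bru1=7.76e-3, v_bru2=7.76e-3, convection_enabled=True
    )


@pytest.fixture(scope="session")
def default_mesh(symmetric_small_spec):
    return discretize(symmetric_small_spec)
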