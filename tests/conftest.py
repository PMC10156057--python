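import numpy as np
import pytest

from filacycle import AncestorModel, Environment, LifeCycle


@pytest.fixture(scope="session")
def env_b() -> Environment:
    return Environment.preset("E_B")


@pytest.fixture(scope="session")
def env_c() -> Environment:
    return Environment.preset("E_C")


@pytest.fixture(scope="session")
def env_flat() -> Environment:
    """Effectively flat selection: a saturated sigmoid with p_s(x) = c - d
    = 0.8 for every daughter size x >= 1."""
    return Environment(a=5.0, b=-10.0)


@pytest.fixture(scope="session")
def env_sure() -> Environment:
    """Survival identically 1 (linear ramp clamped at 1 from x = 1 on)."""
    return Environment(a=1.0, b=0.0, variant="linear")


@pytest.fixture(scope="session")
def binary_fission() -> LifeCycle:
    return LifeCycle(16, 2)


@pytest.fixture(scope="session")
def complete_dissociation() -> LifeCycle:
    return LifeCycle(16, 16)


@pytest.fixture(scope="session")
def ancestor_b(binary_fission, env_b) -> AncestorModel:
    return AncestorModel(binary_fission, env_b)


@pytest.fixture(scope="session")
def ancestor_c(complete_dissociation, env_c) -> AncestorModel:
    return AncestorModel(complete_dissociation, env_c)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20230421)
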