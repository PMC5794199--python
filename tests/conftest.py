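import pytest

from speechadapt import Perturbation, build_normal_state, default_grid


@pytest.fixture(scope="session")
def normal():
    """Symmetric pre-adaptation state: centers 0/1/2, all sd = 1/8."""
    return build_normal_state()


@pytest.fixture()
def grid():
    return default_grid()


@pytest.fixture()
def pert():
    """Reference perturbation: +0.4 D toward /a/."""
    return Perturbation(delta=0.4)
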