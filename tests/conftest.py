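import pytest

import upfinder as uf


@pytest.fixture
def branch():
    """Canonical branch network: glucose -> A -> {B, P}, biomass 0.8B + 0.2P."""
    return uf.make_branch_model()


@pytest.fixture
def lin3():
    return uf.make_linear_model(3)


@pytest.fixture
def degradation():
    return uf.make_degradation_model()


@pytest.fixture
def branch_sbml(tmp_path, branch):
    path = tmp_path / "branch1.xml"
    uf.write_sbml(branch, path)
    return path
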