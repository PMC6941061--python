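import numpy as np
import pytest

from rcm import ParameterSet, TissueGrid, TissueSpec, build_tissue, preset_parameters


@pytest.fixture(scope="session")
def params0() -> ParameterSet:
    return preset_parameters("rcm0")


@pytest.fixture(scope="session")
def paramsstar() -> ParameterSet:
    return preset_parameters("rcmstar")


@pytest.fixture(scope="session")
def grid1540(params0) -> TissueGrid:
    return build_tissue(TissueSpec.from_name("1540"), params0)


def mini_grid(map_text: str, params: ParameterSet, **kwargs) -> TissueGrid:
    """Small hand-drawn lattice for operator-level oracle tests."""
    return TissueGrid.from_text_map(map_text, params=params, **kwargs)


@pytest.fixture
def two_epi(params0) -> TissueGrid:
    return mini_grid("EE", params0)
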