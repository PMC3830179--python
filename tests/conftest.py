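import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from nirqc.config import RunConfig
from nirqc.design import hgc_formulation, make_blend_design
from nirqc.pipeline import run_full_study
from nirqc.simulate import default_grid, default_library


@pytest.fixture(scope="session")
def formulation():
    return hgc_formulation()


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def az_design(formulation):
    return make_blend_design(formulation, "AZ")


@pytest.fixture(scope="session")
def study_report():
    """One full default-configuration study, shared across tests."""
    return run_full_study(RunConfig(seed=17))
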