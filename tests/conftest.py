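import numpy as np
import pandas as pd
import pytest

from nitroclim.gam import TermSpec, fit_loading_model
from nitroclim.synth import GeneratorConfig, make_training_table

NINE_COVARIATES = (
    "P_annual",
    "P_MAM_p95",
    "T_annual",
    "ln_Nsurplus",
    "ln_Nsurplus_lag12",
    "LU_D",
    "LU_C",
    "LU_FSH",
    "L_TD",
)


def nine_term_specs(basis_size: int = 10) -> list[TermSpec]:
    """Default model structure: saturating precip smooth, the rest linear."""
    return [TermSpec("P_annual", "smooth", basis_size)] + [
        TermSpec(c, "linear") for c in NINE_COVARIATES[1:]
    ]


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(n_catchments=60)


@pytest.fixture(scope="session")
def training_table(small_config):
    table, specs = make_training_table(small_config, seed=7)
    return table, specs


@pytest.fixture(scope="session")
def fitted_model(training_table):
    table, _ = training_table
    return fit_loading_model(table, nine_term_specs())
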