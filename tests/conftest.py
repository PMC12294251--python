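import numpy as np
import pandas as pd
import pytest

from sparsegblup import (
    GenerativeParams,
    TrialDesign,
    compute_grm,
    filter_markers,
    impute_mean,
    simulate_markers,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def small_markers() -> pd.DataFrame:
    """40 lines x 200 markers, no missing calls."""
    return simulate_markers(40, 200, maf_range=(0.1, 0.5), missing_rate=0.0, seed=42)


@pytest.fixture(scope="session")
def small_grm(small_markers) -> pd.DataFrame:
    return compute_grm(impute_mean(filter_markers(small_markers)))


@pytest.fixture(scope="session")
def small_pheno(small_grm) -> pd.DataFrame:
    """40 lines x 3 target environments, one season."""
    design = TrialDesign(
        "TPE_T", "Y1", 40,
        [("E1", "target"), ("E2", "target"), ("E3", "target")],
    )
    params = GenerativeParams(var_env=0.5, seed=7)
    pheno, _ = simulate_phenotypes(design, small_grm, params)
    return pheno
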