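import numpy as np
import pandas as pd
import pytest

from markergain import run_family

# reduced factorial grid used by the simulation-property suites: crosses of
# base-covariate OR {1, 2, 4} and SD {0.5, 2} with all five marker ORs and
# all three prevalences, 200 replicates of 1000 subjects per scenario
REDUCED_OR_C = [1.0, 2.0, 4.0]
REDUCED_SIGMA_C = [0.5, 2.0]
PROPERTY_SEED = 20260
PROPERTY_REPLICATES = 200


@pytest.fixture(scope="session")
def reduced_binary_results() -> pd.DataFrame:
    """Reduced-grid run of the independent binary-marker family (90 scenarios)."""
    return run_family(
        "binary_independent",
        master_seed=PROPERTY_SEED,
        n_replicates=PROPERTY_REPLICATES,
        n_subjects=1000,
        grid_kwargs=dict(or_c_values=REDUCED_OR_C, sigma_c_values=REDUCED_SIGMA_C),
    )


@pytest.fixture(scope="session")
def correlated_binary_results() -> dict:
    """Matched reduced-grid runs of the correlated binary-marker families.

    Restricted to marker OR >= 2 (where correlation attenuation is a real
    effect); keys are the correlation values 0.5 and 0.8.
    """
    kwargs = dict(
        or_c_values=REDUCED_OR_C,
        sigma_c_values=REDUCED_SIGMA_C,
        or_rf_values=[2.0, 3.0, 5.0],
    )
    return {
        0.5: run_family(
            "binary_rho05",
            master_seed=PROPERTY_SEED,
            n_replicates=PROPERTY_REPLICATES,
            grid_kwargs=kwargs,
        ),
        0.8: run_family(
            "binary_rho08",
            master_seed=PROPERTY_SEED,
            n_replicates=PROPERTY_REPLICATES,
            grid_kwargs=kwargs,
        ),
    }


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
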