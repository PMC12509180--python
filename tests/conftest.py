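import numpy as np
import pandas as pd
import pytest

import exclosim as ex


@pytest.fixture(scope="session")
def design_1site() -> pd.DataFrame:
    return ex.build_design(ex.DesignSpec(n_sites=1, rng_seed=11))


@pytest.fixture(scope="session")
def design_10sites() -> pd.DataFrame:
    return ex.build_design(ex.DesignSpec(n_sites=10, rng_seed=11))


@pytest.fixture(scope="session")
def noisy_data_10sites(design_10sites) -> pd.DataFrame:
    """One realization under a 10% main-effect scenario with the default
    variance components."""
    scenario = ex.scenario_from_preset("main_only", 10.0)
    return ex.simulate_experiment(design_10sites, scenario, ex.PAPER_VC, seed=21)


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent ordinary-least-squares oracle: solve X'X b = X'y."""
    return np.linalg.solve(X.T @ X, X.T @ y)
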