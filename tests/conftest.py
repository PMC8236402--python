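import numpy as np
import pandas as pd
import pytest

from crosslagmed import child_two_wave_config, child_mediation_config, simulate_cohort


@pytest.fixture(scope="session")
def child_cohort():
    """Medium two-wave children-scale cohort shared across read-only tests."""
    return simulate_cohort(child_two_wave_config(n_subjects=2000, seed=1234))


@pytest.fixture(scope="session")
def mediation_cohort():
    """Cross-sectional children-scale cohort with the default mediation structure."""
    return simulate_cohort(child_mediation_config(n_subjects=4000, seed=4321))


@pytest.fixture()
def toy_panel():
    """Tiny (n=8) unstructured panel for algebraic identities."""
    rng = np.random.default_rng(5)
    n = 8
    return pd.DataFrame({
        "bmi_z_base": rng.standard_normal(n),
        "ua_z_base": rng.standard_normal(n),
        "bmi_z_fu": rng.standard_normal(n),
        "ua_z_fu": rng.standard_normal(n),
        "followup_years": rng.uniform(5, 14, n),
    })
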