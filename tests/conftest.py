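import numpy as np
import pandas as pd
import pytest

from radcatch import SimConfig, generate_cohort_like, generate_model_exact
from radcatch.tensorize import tensorize_table


@pytest.fixture(scope="session")
def small_model_exact():
    """Moderate-signal model-exact cohort on a 6x5 grid (no padding)."""
    config = SimConfig(
        n=200, p1=6, p2=5, n_features=30, q=3, g_total=20, g_de=3,
        s_true=3, b_scale=0.8, alpha_scale=0.3, alpha_links=6,
        gamma_scale=1.0, prevalence=0.4, exact_prevalence=True, seed=42,
    )
    bundle, truth = generate_model_exact(config)
    stack = tensorize_table(bundle.radiomics, config.p1, config.p2)
    return config, bundle, truth, stack


@pytest.fixture(scope="session")
def small_cohort_like():
    """Study-shaped but miniature cohort (24 patients, 4x3 grid)."""
    config = SimConfig(
        n=24, p1=4, p2=3, n_features=10, q=4, g_total=30, g_de=4,
        s_true=2, b_scale=1.0, gamma_scale=1.0, prevalence=1 / 3,
        exact_prevalence=True, hazard_beta=0.5, seed=7,
    )
    bundle, truth = generate_cohort_like(config)
    return config, bundle, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def tiny_radiomic_table():
    return pd.DataFrame(
        {"f_a": [2.0, 4.0, 6.0], "f_b": [5.0, 5.0, 5.0], "f_c": [1.0, 0.0, 3.0]},
        index=pd.Index(["P1", "P2", "P3"], name="patient_id"),
    )
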