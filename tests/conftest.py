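import numpy as np
import pandas as pd
import pytest

import jointglmm as jg

#: two lightweight covariates used by most simulation-based tests
TWO_COV_MARGINALS = {
    "x1": {"dist": "bernoulli", "p": 0.5},
    "x2": {"dist": "truncnorm_int", "mean": 0, "sd": 1.5, "low": -4, "high": 4},
}


def make_two_cov_data(n_div, clusters, women, params, seed):
    cfg = jg.SimConfig(n_div, clusters, women,
                       covariate_marginals=TWO_COV_MARGINALS, seed=seed)
    struct = jg.generate_structure(cfg)
    return jg.simulate_outcomes(struct, params, seed=(seed + 1) % (2 ** 31))


@pytest.fixture(scope="session")
def two_cov_params():
    return jg.TrueParameters(
        covariates=("x1", "x2"),
        beta_cuc=np.array([0.4, -0.3, 0.5]),
        beta_hiv=np.array([-0.2, 0.4, 0.3]),
    )


@pytest.fixture(scope="session")
def toy_df():
    """Three women in two divisions, outcomes fixed by hand."""
    return pd.DataFrame({
        "division_id": ["A", "A", "B"],
        "cluster_id": ["A_c1", "A_c2", "B_c1"],
        "woman_id": [1, 2, 3],
        "age": [25, 40, 30],
        "tv": [1, 0, 1],
        "y_cuc": [1, 0, 1],
        "y_hiv": [0, 1, 1],
    })


@pytest.fixture(scope="session")
def toy_beta():
    return np.array([[0.2, -0.02, 0.3], [-0.1, 0.01, 0.2]])


@pytest.fixture(scope="session")
def small_dataset():
    """Complete standard-schema dataset, 2 divisions x 3 clusters x 15 women."""
    cfg = jg.SimConfig(n_divisions=2, clusters_per_division=3,
                       women_per_cluster=15, seed=7)
    return jg.generate_dataset(cfg)
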