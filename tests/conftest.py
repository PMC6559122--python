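import numpy as np
import pytest
from hypothesis import settings

import fusionval as fv
from fusionval import leadership as ld
from fusionval.synthetic import mini_scenario, sample_cov, true_sigma

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mini_true():
    """Fusion-true mini scenario with its exactly-implied covariance."""
    sc = mini_scenario("fusion_true", n_obs=1000, seed=7)
    sigma = true_sigma(sc)
    labels = [v.name for v in sc.spec.variables]
    return sc, sigma, labels


@pytest.fixture(scope="session")
def mini_fit(mini_true):
    """Baseline fit of the mini model to one sampled covariance (N=1000)."""
    sc, sigma, labels = mini_true
    mom = sample_cov(sigma, 1000, 7, labels=labels)
    model = fv.build_baseline(sc.spec, mom)
    return fv.fit(model, mom)


@pytest.fixture(scope="session")
def alberta_moments():
    """Synthetic covariance with the amended-Alberta structure, N=2000."""
    return ld.synthetic_alberta_moments(n_obs=2000)


@pytest.fixture(scope="session")
def alberta_fits(alberta_moments):
    """Baseline and (six-amendment) amended fits on the synthetic matrix."""
    spec = ld.alberta_spec()
    model = fv.build_baseline(spec, alberta_moments)
    baseline = fv.fit(model, alberta_moments)
    amended_model = model
    for p in ld.alberta_amendments():
        amended_model = fv.add_amendment(amended_model, p)
    amended = fv.fit(amended_model, alberta_moments)
    return baseline, amended


def toy_two_item_config():
    """Two equal-weight items, one downstream variable, no controls."""
    return {
        "scale": {"name": "S", "items": ["i1", "i2"]},
        "variables": [
            {"name": "i1", "role": "scale_item", "error_fraction": 0.0},
            {"name": "i2", "role": "scale_item", "error_fraction": 0.0},
            {"name": "d", "role": "downstream", "error_fraction": 0.0},
        ],
        "paths": [{"source": "S", "target": "d"}],
    }


def random_pd(p: int, rng: np.random.Generator) -> np.ndarray:
    a = rng.standard_normal((p, 2 * p))
    return a @ a.T / (2 * p) + 0.1 * np.eye(p)
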