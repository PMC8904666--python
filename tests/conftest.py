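import numpy as np
import pytest
from hypothesis import settings

from burnlink.irt import ItemParams
from burnlink.scales import ScaleDef
from burnlink.synthetic import default_study_fixture, simulate_responses

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def draw_well_separated_params(rng, item_ids, n_categories=5, a_range=(1.2, 2.2)):
    """Known GRM truths with clearly separated thresholds (for recovery oracles)."""
    out = {}
    for item in item_ids:
        b1 = rng.uniform(-2.2, -1.2)
        gaps = rng.uniform(0.5, 1.1, n_categories - 2)
        b = b1 + np.concatenate([[0.0], np.cumsum(gaps)])
        out[item] = ItemParams(item, rng.uniform(*a_range), tuple(b))
    return out


@pytest.fixture(scope="session")
def toy_scale():
    return ScaleDef("toy", ["it0", "it1", "it2"], 3, 0)


@pytest.fixture(scope="session")
def toy_params(toy_scale):
    rng = np.random.default_rng(42)
    return draw_well_separated_params(rng, toy_scale.item_ids, n_categories=3)


@pytest.fixture(scope="session")
def toy_matrix(toy_scale, toy_params):
    rng = np.random.default_rng(7)
    return simulate_responses(rng.standard_normal(200), toy_scale, toy_params, seed=8)


@pytest.fixture(scope="session")
def study_fixture():
    """Shared mid-size synthetic study (one generation per session)."""
    return default_study_fixture(seed=1, n_respondents=1500)
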