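import numpy as np
import pytest

from fwaging import ha_criteria, synthetic_data


@pytest.fixture(scope="session")
def default_cohort():
    """A moderately sized generated cohort shared across read-only tests."""
    records = synthetic_data.generate_micro(
        synthetic_data.MicroGenConfig(n_respondents=3000, seed=42)
    )
    profiles = [ha_criteria.score_profile(r) for r in records]
    return records, profiles


@pytest.fixture(scope="session")
def big_cohort():
    """n=50,000 cohort for convergence-style checks (generated once)."""
    records = synthetic_data.generate_micro(
        synthetic_data.MicroGenConfig(n_respondents=50_000, seed=7)
    )
    return records


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_record(rid, *, y1=True, y2=True, y3=True, y4=True, x=None):
    return synthetic_data.record_from_statuses(rid, y1=y1, y2=y2, y3=y3, y4=y4, x=x)


@pytest.fixture
def record_builder():
    return make_record
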