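import numpy as np
import pytest

from pmrisk import risk as rk
from pmrisk import synthetic as syn


@pytest.fixture(scope="session")
def age_groups():
    return rk.default_age_groups()


@pytest.fixture(scope="session")
def adult(age_groups):
    """The 18-44 years reference adult used by most worked examples."""
    return next(g for g in age_groups if g.label == "18-44 years")


@pytest.fixture(scope="session")
def default_campaign():
    """One seeded 104-day synthetic campaign, shared across read-only tests."""
    return syn.generate_campaign(syn.default_config(seed=1))


@pytest.fixture(scope="session")
def campaign_frame(default_campaign):
    return syn.campaign_frame(default_campaign)
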