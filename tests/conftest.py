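"""Shared fixtures: one default synthetic transect reused across the suite."""

import pytest
from hypothesis import settings

from oceanmg import profiles, synthetic

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

CANONICAL_SEED = 1


@pytest.fixture(scope="session")
def transect():
    """Default-scale transect (22 stations, 50 taxa, 40 KOs, 8 variants/pair,
    2e5 reads/station) at the canonical seed."""
    stations, catalog, counts, truth = synthetic.make_transect(seed=CANONICAL_SEED)
    return stations, catalog, counts, truth


@pytest.fixture(scope="session")
def transect_profiles(transect):
    _, catalog, counts, _ = transect
    return profiles.build_profiles(counts, catalog)
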