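import pytest
from hypothesis import HealthCheck, settings

from qolbws import DEFAULT_ATTRIBUTES, DEFAULT_SCHEMA, Dataset, RespondentRecord

settings.register_profile(
    "repro", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("repro")

ATTR_IDS = DEFAULT_ATTRIBUTES.ids


def make_record(rid, best, worst, **demo):
    full = {name: demo.get(name, "PNR") for name in DEFAULT_SCHEMA.names}
    return RespondentRecord(str(rid), best, worst, full)


def make_dataset(records, provenance="test"):
    return Dataset(DEFAULT_ATTRIBUTES, DEFAULT_SCHEMA, tuple(records), provenance)


@pytest.fixture(scope="session")
def preset_dataset():
    """One clean paper-like simulated dataset at the published sample size."""
    from qolbws import generate, preset_paper_like
    dataset, _ = generate(preset_paper_like(n_respondents=213, seed=11))
    return dataset


@pytest.fixture(scope="session")
def large_dataset():
    """A paper-like dataset large enough that every persona cell has
    hundreds of respondents and sampling noise cannot reorder them."""
    from qolbws import generate, preset_paper_like
    dataset, _ = generate(preset_paper_like(n_respondents=60000, seed=5))
    return dataset
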