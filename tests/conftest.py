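import pytest
from hypothesis import HealthCheck, settings

from pepgraph import DigestConfig, ProteinRecord, components_from_map, digest_database

settings.register_profile(
    "repro",
    deadline=None,
    derandomize=True,
    database=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")

# digest at 0 missed cleavages used by the canonical small fixtures
MIN5_NOMISS = DigestConfig(min_len=5, max_len=50, max_missed=0)


def single_component(records, config=MIN5_NOMISS):
    comps = components_from_map(digest_database(records, config))
    assert len(comps) == 1
    return comps[0]


@pytest.fixture
def m_records():
    """Two proteins with one unique peptide each plus one shared peptide."""
    return [
        ProteinRecord("A", "AAAAKVVVVK"),
        ProteinRecord("B", "CCCCKVVVVK"),
    ]


@pytest.fixture
def m_component(m_records):
    return single_component(m_records)


@pytest.fixture
def n_records():
    """Protein B is a sub-sequence of A and has no unique peptide."""
    return [
        ProteinRecord("A", "AAAAKVVVVK"),
        ProteinRecord("B", "VVVVK"),
    ]


@pytest.fixture
def n_component(n_records):
    return single_component(n_records)


@pytest.fixture
def w_records():
    """Three proteins, no unique peptide anywhere (two shared nodes)."""
    return [
        ProteinRecord("A", "AAAAK"),
        ProteinRecord("B", "AAAAKCCCCK"),
        ProteinRecord("C", "CCCCK"),
    ]


@pytest.fixture
def w_component(w_records):
    return single_component(w_records)


@pytest.fixture
def smallest_component():
    return single_component([ProteinRecord("S", "DDDDKEEEEK")])
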