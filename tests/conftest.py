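import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def table2():
    from consig.fixtures import load_table2_fixture

    return load_table2_fixture()


@pytest.fixture
def table3():
    from consig.fixtures import load_table3_fixture

    return load_table3_fixture()


@pytest.fixture
def narrative():
    from consig.fixtures import load_narrative_counts

    return load_narrative_counts()


@pytest.fixture
def toy_dag():
    """Small hand-built ontology: T0 <- T1 <- T2, T0 <- T3 (part_of)."""
    from consig.enrichment import OntologyDAG

    return OntologyDAG(
        terms={
            "T0": ("root", "proc"),
            "T1": ("middle", "proc"),
            "T2": ("leaf", "proc"),
            "T3": ("side", "proc"),
        },
        edges=(("T1", "T0", "is_a"), ("T2", "T1", "is_a"), ("T3", "T0", "part_of")),
    )
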