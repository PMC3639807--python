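import pytest

from mhbi import DEFAULT_NAMESPACES, build_reference_schema, ingest
from mhbi.fixtures import worked_example_fixture


@pytest.fixture(scope="session")
def ns():
    return DEFAULT_NAMESPACES


@pytest.fixture(scope="session")
def reference_schema():
    return build_reference_schema()


@pytest.fixture(scope="session")
def worked_example():
    return worked_example_fixture()


@pytest.fixture(scope="session")
def worked_graph(worked_example):
    """The worked-example tables ingested onto the reference schema."""
    return ingest(
        worked_example.specimens,
        worked_example.taxa,
        worked_example.publications,
        schema=worked_example.schema,
    )


@pytest.fixture()
def schema_copy(reference_schema):
    return reference_schema.copy()
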