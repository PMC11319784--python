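import pytest

from sectionid.schema import SectionSchema, SectionType, bundled_schema


@pytest.fixture(scope="session")
def discharge_schema() -> SectionSchema:
    return bundled_schema("discharge")


@pytest.fixture()
def tiny_schema() -> SectionSchema:
    """Two-type schema small enough to reason about by hand."""
    return SectionSchema(
        types=(
            SectionType("Allergies", "drug allergies", ("ALLERGIES",)),
            SectionType("Social history", "social circumstances", ("SOCIAL HISTORY",)),
        ),
        label_map={},
        name="tiny",
    )
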