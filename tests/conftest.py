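import pytest

from disorderscape.synthetic_data import linker_demo_cohort


@pytest.fixture(scope="session")
def demo_cohort():
    """The fixed 12-protein cohort with hand-constructed domain architectures."""
    return linker_demo_cohort()


@pytest.fixture(scope="session")
def demo_domains_by_protein(demo_cohort):
    _, _, annotations = demo_cohort
    by: dict[str, list] = {}
    for ann in annotations:
        by.setdefault(ann.protein_id, []).append(ann)
    return by
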