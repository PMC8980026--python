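import pytest

from mitocomp.synthetic import GeneratorSpec, drusselli_layout, generate_mitogenome


@pytest.fixture(scope="session")
def table1_record():
    """The shipped 38-feature annotation layout (no sequence)."""
    return drusselli_layout()


@pytest.fixture(scope="session")
def synthetic_genome():
    """One deterministic synthetic mitogenome with its ground truth."""
    return generate_mitogenome(GeneratorSpec(seed=42))
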