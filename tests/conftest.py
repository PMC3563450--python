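import pytest

from ribodiv import (
    build_reference,
    derive_ribotypes,
    map_reads,
    model_454,
    simulate_reads,
)

PANEL3_SPEC = [("ITS1", 0, 0, 0.70), ("ITS1", 1, 0, 0.20), ("ITS1", 3, 0, 0.10)]


@pytest.fixture(scope="session")
def template():
    return build_reference(seed=1, gc=0.5, lengths=(313, 240, 97))


@pytest.fixture(scope="session")
def panel3(template):
    """Three ITS1 ribotypes (0/1/3 substitutions) at 0.70/0.20/0.10."""
    return derive_ribotypes(template, PANEL3_SPEC, seed=7)


@pytest.fixture(scope="session")
def mapped_454(template, panel3):
    """A small 454-like ITS1-spanning read set, already mapped."""
    reads, truth = simulate_reads(panel3, model_454(), 300, seed=3, origin="three_prime")
    mapped, rejected = map_reads(reads, template)
    return reads, truth, mapped, rejected
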