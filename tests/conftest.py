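import pytest

from intronless import EseSet, GeneRecord, ToyGeneSpec, make_toy_gene


@pytest.fixture
def toy_ese_set() -> EseSet:
    return EseSet("toy", frozenset(["GAAGAA", "AAGAAG", "GAAGAT"]))


@pytest.fixture
def two_exon_gene() -> GeneRecord:
    """120 + 120 nt exons, one 40 nt intron, balanced GC3."""
    return make_toy_gene(
        ToyGeneSpec(exon_lengths=[120, 120], intron_lengths=[40], seed=11)
    )


@pytest.fixture
def three_exon_gene() -> GeneRecord:
    return make_toy_gene(
        ToyGeneSpec(exon_lengths=[90, 60, 90], intron_lengths=[30, 25], seed=7)
    )
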