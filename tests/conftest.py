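import pytest

import codonpatterns as cp


def make_cds(codon_string: str, seq_id: str = "g", **kw) -> cp.CodingSequence:
    """Build a CodingSequence from a space-separated codon string."""
    return cp.CodingSequence(id=seq_id, codons=tuple(codon_string.split()), **kw)


@pytest.fixture(scope="session")
def null_dataset():
    """A moderate dataset with no planted structure (uniform usage)."""
    return cp.generate(
        cp.GeneratorConfig(n_genes=300, min_codons=80, max_codons=200, seed=7)
    )


@pytest.fixture(scope="session")
def null_reference(null_dataset):
    table = cp.count_codons(null_dataset.cds)
    return table, cp.cai_weights(table, reference_name="pooled-null")
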