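import numpy as np
import pytest

from cubkit.composition import CodonCountTable, codon_counts
from cubkit.sequence_io import STANDARD_CODE, CodingSequence


@pytest.fixture(scope="session")
def code():
    return STANDARD_CODE


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_cds(codons, gene_id="g", stop="TAA"):
    """Build a CodingSequence from body codons (ATG prepended, stop appended)."""
    return CodingSequence(id=gene_id, sequence="ATG" + "".join(codons) + stop)


@pytest.fixture
def one_codon_per_family_counts(code):
    """Counts using exactly one codon per degenerate family (ENc = 20 case)."""
    counts = {}
    for aa, fam in code.degenerate_families.items():
        counts[fam[0]] = 5
    return CodonCountTable(gene_id="one_per_family", counts=counts)


@pytest.fixture
def uniform_counts(code):
    """Equal counts for every codon of every degenerate family (ENc = 61 case)."""
    return CodonCountTable(
        gene_id="uniform", counts={c: 12 for c in code.degenerate_codons}
    )


@pytest.fixture
def small_gene_set():
    """A tiny deterministic mixed-regime gene set with count tables."""
    from cubkit.synthetic_data import RegimeSpec, generate

    gs = generate(RegimeSpec(n_genes=12, length_range=(150, 300),
                             regime="mixed", seed=11))
    tables = [codon_counts(g) for g in gs.genes]
    return gs, tables
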