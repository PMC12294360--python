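import numpy as np
import pytest

from cubkit.cds_io import CodonCounts
from cubkit.genetic_code import CODON_INDEX, build_standard_code


@pytest.fixture(scope="session")
def code():
    return build_standard_code()


def make_counts(d: dict[str, int], gene_id: str = "g") -> CodonCounts:
    """Build a CodonCounts from a codon -> count dict (RNA or DNA codons)."""
    v = np.zeros(64, dtype=np.int64)
    for codon, n in d.items():
        v[CODON_INDEX[codon.upper().replace("T", "U")]] += n
    return CodonCounts(gene_id=gene_id, counts=v, total_codons=int(v.sum()))


@pytest.fixture(scope="session")
def uniform_counts(code):
    """60 of every sense codon: exactly uniform synonymous usage."""
    return make_counts({c: 60 for c in code.sense_codons}, "uniform")


@pytest.fixture(scope="session")
def one_per_family_counts(code):
    """100 copies of a single codon per amino-acid family: extreme bias."""
    return make_counts(
        {fam[0]: 100 for aa, fam in code.families.items() if aa != "*"},
        "one_per_family",
    )


def random_counts(rng: np.random.Generator, max_count: int = 20) -> CodonCounts:
    """A random small codon-count table over sense codons."""
    code = build_standard_code()
    d = {}
    for c in code.sense_codons:
        if rng.random() < 0.7:
            d[c] = int(rng.integers(0, max_count + 1))
    return make_counts(d, "random")
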