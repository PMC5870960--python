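import numpy as np
import pandas as pd
import pytest

from cubkit import CODONS, STANDARD_CODE, GeneRecord, count_codons


@pytest.fixture(scope="session")
def code():
    return STANDARD_CODE


def counts_from_dict(d: dict[str, float]) -> np.ndarray:
    """64-vector in standard codon order from a sparse codon->count dict."""
    arr = np.zeros(64)
    for codon, n in d.items():
        arr[CODONS.index(codon)] = n
    return arr


def random_count_dicts(n_tables: int, seed: int, low: int = 2, high: int = 50):
    """Random count tables with every synonymous family populated (n >= 2)."""
    rng = np.random.default_rng(seed)
    tables = []
    for _ in range(n_tables):
        d = {
            c: int(rng.integers(low, high))
            for c in STANDARD_CODE.synonymous_codons
        }
        tables.append(d)
    return tables


@pytest.fixture(scope="session")
def uniform_counts():
    """Every synonymous codon with the same large count."""
    return counts_from_dict({c: 1000 for c in STANDARD_CODE.synonymous_codons})


@pytest.fixture(scope="session")
def one_codon_per_aa_counts():
    """Exactly one codon per multi-codon amino acid, used heavily."""
    return counts_from_dict(
        {fam[0]: 1000 for fam in STANDARD_CODE.families.values() if len(fam) >= 2}
    )


def make_records(seqs: dict[str, str]) -> list[GeneRecord]:
    return [GeneRecord(gid, gid, seq) for gid, seq in seqs.items()]


@pytest.fixture(scope="session")
def small_gene_table():
    recs = make_records(
        {
            "g1": "ATGTTTTTCGAAGAGTAA",
            "g2": "ATGGAAGAGGGAGGCTAG",
            "g3": "ATGTTTTTTTTTGAATGA",
        }
    )
    return count_codons(recs)
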