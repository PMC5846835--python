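import itertools

import numpy as np
import pytest

from codonopt.code_tables import ALL_CODONS, standard_code
from codonopt.impact_metrics import CodonMDProfile


@pytest.fixture(scope="session")
def canonical():
    return standard_code()


@pytest.fixture(scope="session")
def literal_codon_table():
    """Independent literal standard-code dict (via biopython), used as oracle."""
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[1]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    assert len(mapping) == 64
    return mapping


@pytest.fixture(scope="session")
def three_letter():
    """1-letter -> 3-letter amino acid code map for oracle comparisons."""
    return {
        "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
        "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
        "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
        "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
        "*": "STOP",
    }


def make_profiles(scalars, n_atoms=4, corr_value=0.0):
    """Constant-per-codon profiles with a given flux scalar per codon."""
    profiles = {}
    for codon in ALL_CODONS:
        corr = np.full((n_atoms, n_atoms), corr_value)
        np.fill_diagonal(corr, 1.0)
        profiles[codon] = CodonMDProfile(
            codon=codon,
            flux=np.full(n_atoms, float(scalars[codon])),
            corr=corr,
        )
    return profiles


@pytest.fixture
def constant_profiles():
    return make_profiles({c: 1.0 for c in ALL_CODONS})
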