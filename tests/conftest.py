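import numpy as np
import pytest

from isosip.synthetic import default_marker_references


@pytest.fixture(scope="session")
def marker_refs():
    return default_marker_references()


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_601)


AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, length):
    return "".join(rng.choice(list(AA20), size=length))


# a simple deterministic codon per amino acid (table 11 compatible),
# used to embed exact protein substrings into reads
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


def encode_peptide(peptide: str) -> str:
    return "".join(_CODON[aa] for aa in peptide)
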