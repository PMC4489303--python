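import pytest

from pseqfeat import Alphabet, Sequence, load_builtin, validate_alphabet
from pseqfeat.property_store import resolve_properties


@pytest.fixture
def dna(request):
    def make(residues: str, seq_id: str = "t") -> Sequence:
        return validate_alphabet(Sequence(seq_id, residues), Alphabet.DNA)

    return make


@pytest.fixture
def rna():
    def make(residues: str, seq_id: str = "t") -> Sequence:
        return validate_alphabet(Sequence(seq_id, residues), Alphabet.RNA)

    return make


@pytest.fixture
def protein():
    def make(residues: str, seq_id: str = "t") -> Sequence:
        return validate_alphabet(Sequence(seq_id, residues), Alphabet.PROTEIN)

    return make


@pytest.fixture(scope="session")
def structural6():
    """The six dinucleotide structural properties (PseDNC defaults)."""
    return resolve_properties(
        ["Twist", "Tilt", "Roll", "Shift", "Slide", "Rise"], Alphabet.DNA, 2
    )


@pytest.fixture(scope="session")
def aa3():
    """Hydrophobicity, hydrophilicity and side-chain mass."""
    return resolve_properties(
        ["Hydrophobicity", "Hydrophilicity", "SideChainMass"], Alphabet.PROTEIN, 1
    )


@pytest.fixture(scope="session")
def builtin_dna_di():
    return load_builtin(Alphabet.DNA, 2)
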