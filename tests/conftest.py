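import numpy as np
import pytest

from varstruct import (EngineeredContact, FixtureSpec, StructureModel,
                       make_engineered_pair_fixture, make_ideal_helix,
                       make_protein_rna_fixture)
from varstruct.model import Atom, Chain, Residue


@pytest.fixture(scope="session")
def helix12():
    """Ideal poly-alanine alpha-helix, 12 residues."""
    return make_ideal_helix(FixtureSpec(sequence="A" * 12))


@pytest.fixture(scope="session")
def mixed_helix():
    """Ideal helix with a spread of side-chain chemistries."""
    return make_ideal_helix(FixtureSpec(sequence="AILKNQTVSA"))


@pytest.fixture(scope="session")
def pair_fixture():
    """Two chains with one engineered Ser OG <-> backbone O bond at 2.8 A."""
    return make_engineered_pair_fixture(FixtureSpec(
        sequence="AASAA", sequence_b="AAAA",
        contacts=(EngineeredContact(3, "OG", 2, "O", 2.8),)))


@pytest.fixture(scope="session")
def rna_fixture():
    """Protein helix plus one uridine 5'-phosphate, Asn ND2 <-> OP1 at 3.0 A."""
    return make_protein_rna_fixture(FixtureSpec(
        sequence="AANAA", nucleotide="U",
        contacts=(EngineeredContact(3, "ND2", 1, "OP1", 3.0),)))


def random_cloud_model(rng: np.random.Generator, n_atoms: int,
                       box: float = 30.0) -> StructureModel:
    """A chain of single-CA residues at uniform random positions (for
    neighbor-search equivalence checks; no chemistry implied)."""
    residues = [
        Residue(name="ALA", auth_number=i + 1,
                atoms=[Atom("CA", "C", rng.uniform(0.0, box, 3))])
        for i in range(n_atoms)
    ]
    return StructureModel(id="cloud", chains=[Chain(id="A", residues=residues)])
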