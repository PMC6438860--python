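"""Synthetic structure generators: geometry ground truth and determinism."""

import numpy as np
import pytest

from varstruct import (EngineeredContact, FixtureSpec, build_nucleotide,
                       make_engineered_pair_fixture, make_ideal_helix,
                       validate_fixture)
from varstruct.geometry import dihedral, distance
from varstruct.synthetic import FixtureConstructionError


def _atom(model, chain, num, name):
    return model.chain(chain).residue(num).atom(name).pos


class TestIdealHelix:
    def test_backbone_hbond_ladder_distances(self):
        m = make_ideal_helix(FixtureSpec(sequence="A" * 12))
        for i in range(1, 9):
            d = distance(_atom(m, "A", i, "O"), _atom(m, "A", i + 4, "N"))
            assert 2.8 <= d <= 3.2

    def test_requested_dihedrals_are_realized(self):
        m = make_ideal_helix(FixtureSpec(sequence="A" * 6))
        ch = m.chain("A")
        phi = dihedral(ch.residue(1).atom("C").pos,
                       ch.residue(2).atom("N").pos, ch.residue(2).atom("CA").pos,
                       ch.residue(2).atom("C").pos)
        psi = dihedral(ch.residue(2).atom("N").pos, ch.residue(2).atom("CA").pos,
                       ch.residue(2).atom("C").pos, ch.residue(3).atom("N").pos)
        assert phi == pytest.approx(-57.0, abs=1e-6)
        assert psi == pytest.approx(-47.0, abs=1e-6)

    def test_extended_chain_has_no_helical_ladder(self):
        m = make_ideal_helix(FixtureSpec(sequence="A" * 12, phi=180.0, psi=180.0))
        for i in range(1, 9):
            assert distance(_atom(m, "A", i, "O"), _atom(m, "A", i + 4, "N")) > 4.0

    def test_determinism_and_seeded_jitter(self):
        a = make_ideal_helix(FixtureSpec(sequence="AILK"))
        b = make_ideal_helix(FixtureSpec(sequence="AILK"))
        for (_, _, x), (_, _, y) in zip(a.iter_atoms(), b.iter_atoms()):
            assert np.array_equal(x.pos, y.pos)
        j1 = make_ideal_helix(FixtureSpec(sequence="AILK", jitter_sigma=0.2, seed=11))
        j2 = make_ideal_helix(FixtureSpec(sequence="AILK", jitter_sigma=0.2, seed=11))
        j3 = make_ideal_helix(FixtureSpec(sequence="AILK", jitter_sigma=0.2, seed=12))
        moved = same = False
        for (_, _, x), (_, _, y), (_, _, z) in zip(j1.iter_atoms(), j2.iter_atoms(),
                                                   j3.iter_atoms()):
            assert np.array_equal(x.pos, y.pos)
            if not np.allclose(x.pos, z.pos):
                moved = True
        assert moved

    def test_non_protein_letter_rejected(self):
        with pytest.raises(FixtureConstructionError):
            make_ideal_helix(FixtureSpec(sequence="AAZ"))

    def test_fixture_validates_no_short_nonbonded_contacts(self, mixed_helix):
        validate_fixture(mixed_helix)


class TestSidechainGeometry:
    """Rebuilt side chains must reproduce reference ideal-residue geometry.

    The CCD idealized residues (via biotite) are the independent oracle:
    growing each side chain on the reference backbone at the reference chi
    angles must land every heavy atom close to its reference position.
    """

    @pytest.mark.parametrize("resname", [
        "ALA", "SER", "CYS", "THR", "VAL", "LEU", "ILE", "MET", "PHE", "TYR",
        "TRP", "PRO", "ASP", "ASN", "GLU", "GLN", "LYS", "ARG", "HIS",
    ])
    def test_against_ccd_ideal_residues(self, resname):
        info = pytest.importorskip("biotite.structure.info")
        from varstruct.build import build_sidechain
        from varstruct.chemistry import CHI_DEFINITIONS, N_CHI

        ref = info.residue(resname)
        ref = ref[ref.element != "H"]

        def pos(name):
            sel = ref.coord[ref.atom_name == name]
            assert len(sel) == 1
            return sel[0]

        chis = tuple(dihedral(pos(a), pos(b), pos(c), pos(d))
                     for a, b, c, d in CHI_DEFINITIONS[resname][:N_CHI[resname]])
        built = build_sidechain(resname, pos("N"), pos("CA"), pos("C"), chis)
        assert set(built) == {a for a in ref.atom_name
                              if a not in ("N", "CA", "C", "O", "OXT")}
        for name, p in built.items():
            assert distance(p, pos(name)) < 0.8, name
        # chirality: the CB improper must match the L-configuration
        if "CB" in built:
            improper = dihedral(pos("C"), pos("N"), pos("CA"), built["CB"])
            assert improper == pytest.approx(-120.0, abs=5.0)


class TestEngineeredPair:
    @pytest.mark.parametrize("target", [2.8, 3.5, 4.5])
    def test_exact_engineered_distance(self, target):
        m = make_engineered_pair_fixture(FixtureSpec(
            sequence="AASAA", sequence_b="AAAA",
            contacts=(EngineeredContact(3, "OG", 2, "O", target),)))
        d = distance(_atom(m, "A", 3, "OG"), _atom(m, "B", 2, "O"))
        assert d == pytest.approx(target, abs=0.01)

    def test_no_spurious_interchain_polar_contacts(self, pair_fixture):
        from varstruct.chemistry import NONE, polar_role
        a_sites = [(r.name, a.name, a.pos) for c, r, a
                   in pair_fixture.iter_atoms(heavy_only=True) if c.id == "A"]
        b_sites = [(r.name, a.name, a.pos) for c, r, a
                   in pair_fixture.iter_atoms(heavy_only=True) if c.id == "B"]
        close_polar = []
        for rna, na, pa in a_sites:
            for rnb, nb, pb in b_sites:
                if distance(pa, pb) < 4.0 and polar_role(rna, na) != NONE \
                        and polar_role(rnb, nb) != NONE:
                    close_polar.append((na, nb))
        assert close_polar == [("OG", "O")]

    def test_entity_labels(self, pair_fixture):
        assert pair_fixture.chain("A").entity_label == "PROT1"
        assert pair_fixture.chain("B").entity_label == "PROT2"

    def test_unsatisfiable_spec_raises(self):
        with pytest.raises((FixtureConstructionError, Exception)):
            make_engineered_pair_fixture(FixtureSpec(
                sequence="AASAA", sequence_b="AAAA", contacts=()))


class TestProteinRnaFixture:
    def test_contact_and_atom_set(self, rna_fixture):
        nuc = rna_fixture.chain("R").residues[0]
        names = {a.name for a in nuc.atoms}
        assert {"P", "OP1", "OP2", "O2'", "O3'", "O4'", "O5'",
                "C1'", "N1", "C2", "O2", "N3", "C4", "O4"} <= names
        d = distance(_atom(rna_fixture, "A", 3, "ND2"),
                     rna_fixture.chain("R").residues[0].atom("OP1").pos)
        assert d == pytest.approx(3.0, abs=0.01)
        assert rna_fixture.chain("R").entity_label == "RNA1"
        assert rna_fixture.chain("R").polymer_type == "rna"

    def test_round_trips_through_both_formats(self, rna_fixture, tmp_path):
        from varstruct import models_equal, parse_structure, write_structure
        for fmt, ext in (("pdb", "pdb"), ("mmcif", "cif")):
            p = tmp_path / f"rna.{ext}"
            write_structure(rna_fixture, str(p), fmt)
            assert models_equal(rna_fixture, parse_structure(str(p), "auto"),
                                tol=1e-3)

    @pytest.mark.parametrize("base", ["A", "C", "G", "U"])
    def test_nucleotide_bond_network_sane(self, base):
        coords = build_nucleotide(base)
        names = list(coords)
        ring_pairs = 0
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                d = distance(coords[a], coords[b])
                assert d > 1.2
                if d <= 1.8:
                    ring_pairs += 1
        # a connected molecule of n atoms needs >= n-1 bonds; rings add more
        assert ring_pairs >= len(names) - 1
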