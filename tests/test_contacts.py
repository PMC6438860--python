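"""Contact shells, hydrogen-bond detection/banding, and WT-vs-mutant diffs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varstruct import (ContactConfig, EngineeredContact, FixtureSpec,
                       atom_polar_role, classify_hbond_distance, detect_hbonds,
                       detect_polar_contacts, diff_contacts,
                       make_engineered_pair_fixture, make_ideal_helix,
                       mutate_residue, neighbors_within, residue_contacts)
from varstruct.contacts import UnknownChemistryError, _sites
from conftest import random_cloud_model


def brute_force_pairs(model, query_atoms, radius):
    env = _sites(model, include_waters=False)
    qset = set(query_atoms)
    out = set()
    for q in query_atoms:
        for e in env:
            if e in qset or e == q:
                continue
            d = float(np.linalg.norm(np.array(q.pos) - np.array(e.pos)))
            if d <= radius:
                out.add((q, e, d))
    return out


class TestNeighborSearch:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_clouds(self, seed):
        rng = np.random.default_rng(seed)
        model = random_cloud_model(rng, 500)
        sites = _sites(model, include_waters=False)
        query = [sites[i] for i in rng.choice(500, size=20, replace=False)]
        radius = float(rng.uniform(2.0, 8.0))
        assert neighbors_within(model, query, radius) == \
            brute_force_pairs(model, query, radius)

    def test_boundary_is_closed(self):
        from varstruct.model import Atom, Chain, Residue, StructureModel
        for gap, included in ((3.99, True), (4.0, True), (4.01, False)):
            res = [Residue(name="ALA", auth_number=i + 1,
                           atoms=[Atom("CA", "C", (gap * i, 0.0, 0.0))])
                   for i in range(2)]
            m = StructureModel(id="pair", chains=[Chain(id="A", residues=res)])
            sites = _sites(m, include_waters=False)
            pairs = neighbors_within(m, [sites[0]], 4.0)
            assert bool(pairs) is included

    def test_empty_query_is_empty_result(self, helix12):
        assert neighbors_within(helix12, [], 4.0) == set()

    def test_role_symmetry_of_pairs(self, helix12):
        sites = _sites(helix12, include_waters=False)
        a, b = [s for s in sites if s.res_number in (2, 6) and s.atom_name == "CA"]
        fwd = neighbors_within(helix12, [a], 8.0)
        rev = neighbors_within(helix12, [b], 8.0)
        assert any(e == b for _, e, _ in fwd) == any(e == a for _, e, _ in rev)


class TestBandClassifier:
    @pytest.mark.parametrize("d,label", [
        (1.8, "too-close"),
        (2.2, "strong"), (2.4999, "strong"),
        (2.5, "moderate"), (2.9, "moderate"), (3.1999, "moderate"),
        (3.2, "weak"), (4.0, "weak"),
        (4.0001, "none"), (4.5, "none"),
    ])
    def test_band_assignment(self, d, label):
        assert classify_hbond_distance(d) == label

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            classify_hbond_distance(0.0)
        with pytest.raises(ValueError):
            classify_hbond_distance(-1.0)

    @given(st.floats(min_value=0.01, max_value=10.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_total_and_monotone_in_severity(self, d):
        order = ["too-close", "strong", "moderate", "weak", "none"]
        label = classify_hbond_distance(d)
        assert label in order
        # monotone: a slightly larger distance never gets a more severe label
        bigger = classify_hbond_distance(d + 0.01)
        assert order.index(bigger) >= order.index(label)


class TestPolarRoles:
    @pytest.mark.parametrize("res,atom,role", [
        ("ASN", "OD1", "acceptor"), ("ASN", "ND2", "donor"),
        ("SER", "OG", "both"), ("LYS", "NZ", "donor"),
        ("ASP", "OD2", "acceptor"), ("HIS", "NE2", "both"),
        ("ALA", "CA", "none"), ("ALA", "N", "donor"), ("ALA", "O", "acceptor"),
        ("PRO", "N", "none"),
        ("U", "OP1", "acceptor"), ("U", "O2'", "both"), ("U", "N3", "donor"),
        ("G", "O6", "acceptor"), ("A", "N6", "donor"), ("C", "N4", "donor"),
        ("U", "C1'", "none"),
    ])
    def test_role_table(self, res, atom, role):
        assert atom_polar_role(res, atom) == role

    def test_sulfur_roles_off_by_default(self):
        assert atom_polar_role("CYS", "SG") == "none"
        assert atom_polar_role("MET", "SD") == "none"
        cfg = ContactConfig(include_sulfur=True)
        assert atom_polar_role("CYS", "SG", cfg) == "both"
        assert atom_polar_role("MET", "SD", cfg) == "acceptor"

    def test_unknown_combination_is_none(self):
        assert atom_polar_role("ALA", "XX9") == "none"


class TestHBondDetection:
    def test_helix_ladder_count_and_band(self):
        n = 12
        m = make_ideal_helix(FixtureSpec(sequence="A" * n))
        ladder = []
        for i in range(1, n + 1):
            for hb in detect_hbonds(m, "A", i):
                if (hb.atom.atom_name, hb.partner.atom_name) == ("O", "N") \
                        and hb.partner.res_number == i + 4:
                    ladder.append(hb)
        assert len(ladder) == n - 4
        assert all(hb.band == "moderate" for hb in ladder)

    def test_engineered_interchain_bond(self, pair_fixture):
        inter = [h for h in detect_hbonds(pair_fixture, "A", 3)
                 if not h.same_chain]
        assert len(inter) == 1
        hb = inter[0]
        assert (hb.atom.atom_name, hb.partner.atom_name) == ("OG", "O")
        assert hb.band == "moderate"
        assert hb.partner_entity == "PROT2"

    @pytest.mark.parametrize("d,expect_bands", [(3.5, ["weak"]), (4.5, [])])
    def test_band_follows_engineered_distance(self, d, expect_bands):
        m = make_engineered_pair_fixture(FixtureSpec(
            sequence="AASAA", sequence_b="AAAA",
            contacts=(EngineeredContact(3, "OG", 2, "O", d),)))
        inter = [h.band for h in detect_hbonds(m, "A", 3) if not h.same_chain]
        assert inter == expect_bands

    def test_rna_partner_entity(self, rna_fixture):
        inter = [h for h in detect_hbonds(rna_fixture, "A", 3) if not h.same_chain]
        assert [(h.atom.atom_name, h.partner.atom_name, h.band,
                 h.partner_entity) for h in inter] == \
            [("ND2", "OP1", "moderate", "RNA1")]

    def test_hbonds_subset_of_polar_contacts(self, mixed_helix, pair_fixture,
                                             rna_fixture):
        for model, chain, nums in ((mixed_helix, "A", range(1, 11)),
                                   (pair_fixture, "A", range(1, 6)),
                                   (rna_fixture, "A", range(1, 6))):
            for i in nums:
                hb_pairs = {(h.atom, h.partner) for h in
                            detect_hbonds(model, chain, i)}
                pc_pairs = {(p.atom, p.partner) for p in
                            detect_polar_contacts(model, chain, i)}
                assert hb_pairs <= pc_pairs

    def test_carbon_pairs_are_not_polar_contacts(self, helix12):
        for p in detect_polar_contacts(helix12, "A", 6):
            assert atom_polar_role(p.atom.res_name, p.atom.atom_name) != "none"
            assert atom_polar_role(p.partner.res_name, p.partner.atom_name) != "none"

    def test_unknown_residue_chemistry_raises(self):
        from varstruct.model import Atom, Chain, Residue, StructureModel
        res = Residue(name="XYZ", auth_number=1,
                      atoms=[Atom("C1", "C", (0.0, 0.0, 0.0))])
        m = StructureModel(id="x", chains=[Chain(id="A", residues=[res])])
        with pytest.raises(UnknownChemistryError):
            detect_hbonds(m, "A", 1)

    def test_peptide_bonded_neighbors_excluded(self, helix12):
        # O(i) and N(i+1) sit ~2.25 A apart across the peptide bond: a 1-3
        # pair, never a hydrogen bond
        for i in range(1, 12):
            for hb in detect_hbonds(helix12, "A", i):
                assert not (hb.atom.atom_name == "O"
                            and hb.partner.atom_name == "N"
                            and hb.partner.res_number == i + 1)


class TestDiff:
    def test_diff_of_identical_sets_is_empty(self, pair_fixture):
        c = residue_contacts(pair_fixture, "A", 3)
        d = diff_contacts(c, c)
        assert not (d.gained_hbonds or d.lost_hbonds or d.gained_polar
                    or d.lost_polar)
        assert (d.affects_hbond_within, d.affects_hbond_other,
                d.affects_polar_contacts) == ("N", "N", "N")

    def test_gained_and_lost_swap_with_arguments(self, pair_fixture):
        wt = residue_contacts(pair_fixture, "A", 3)
        mut_model = mutate_residue(pair_fixture, "A", 3, "A").model
        mut = residue_contacts(mut_model, "A", 3)
        fwd = diff_contacts(wt, mut)
        rev = diff_contacts(mut, wt)
        assert set(fwd.gained_hbonds) == set(rev.lost_hbonds)
        assert set(fwd.lost_hbonds) == set(rev.gained_hbonds)
        assert set(fwd.gained_polar) == set(rev.lost_polar)

    def test_lost_interchain_bond_detected(self, pair_fixture):
        # Ser -> Ala removes OG: the engineered inter-chain bond disappears
        wt = residue_contacts(pair_fixture, "A", 3)
        mut = residue_contacts(mutate_residue(pair_fixture, "A", 3, "A").model,
                               "A", 3)
        d = diff_contacts(wt, mut)
        inter = [h for h in d.lost_hbonds.values() if not h.same_chain]
        assert len(inter) == 1
        assert d.affects_hbond_other == "Y"
        assert d.interchain_partners == ("PROT2",)

    def test_gained_interchain_bond_detected(self, pair_fixture):
        # reverse construction: alanine "wild type" gains the bond on Ala->Ser
        wt_model = mutate_residue(pair_fixture, "A", 3, "A").model
        wt = residue_contacts(wt_model, "A", 3)
        mut = residue_contacts(pair_fixture, "A", 3)
        d = diff_contacts(wt, mut)
        inter = [h for h in d.gained_hbonds.values() if not h.same_chain]
        assert len(inter) == 1
        assert d.affects_hbond_other == "Y"
        assert d.interchain_partners == ("PROT2",)

    def test_mismatched_residues_rejected(self, pair_fixture):
        with pytest.raises(ValueError):
            diff_contacts(residue_contacts(pair_fixture, "A", 3),
                          residue_contacts(pair_fixture, "A", 2))

    def test_pure_polar_loss_flagged_separately(self):
        # an acceptor-acceptor pair is a polar contact but not a hydrogen
        # bond; losing it flips only the polar-contact flag
        m = make_ideal_helix(FixtureSpec(sequence="DAAAAA", phi=180.0, psi=180.0))
        res1 = m.chain("A").residue(1)
        o5 = m.chain("A").residue(5).atom("O").pos
        od1 = res1.atom("OD1")
        od1.pos = o5 + np.array([0.0, 0.0, 3.0])
        wt = residue_contacts(m, "A", 1)
        lost_key = next(p.key for p in wt.polar
                        if p.atom.atom_name == "OD1" and p.partner.atom_name == "O"
                        and p.partner.res_number == 5)
        mut_model = mutate_residue(m, "A", 1, "A").model
        mut = residue_contacts(mut_model, "A", 1)
        d = diff_contacts(wt, mut)
        assert lost_key in d.lost_polar
        assert lost_key not in d.lost_hbonds
        assert d.affects_polar_contacts == "Y"
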