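"""Model one missense variant and diff its polar interactions.

On the engineered two-chain fixture, mutating Ser3 -> Ala removes the
hydroxyl that carries an inter-chain hydrogen bond; the contact diff reports
it as lost and raises the "affects H bonding with other chains" flag with
the partner molecule's name.
"""

from varstruct import (EngineeredContact, FixtureSpec, diff_contacts,
                       make_engineered_pair_fixture, mutate_residue,
                       residue_contacts)

fixture = make_engineered_pair_fixture(FixtureSpec(
    sequence="AASAA", sequence_b="AAAA",
    contacts=(EngineeredContact(3, "OG", 2, "O", 2.8),)))
fixture.apply_entity_map({"A": "PROT1", "B": "PROT2"})

mutant = mutate_residue(fixture, "A", 3, "Ala", expected_ref="Ser")
print(f"mutated Ser3 -> {mutant.alt_aa}, rotamer chis {mutant.chis}, "
      f"clashes {mutant.clash_count}")

wt = residue_contacts(fixture, "A", 3)
mu = residue_contacts(mutant.model, "A", 3)
print(f"wild type: {len(wt.hbonds)} H-bonds, {len(wt.polar)} polar contacts")
print(f"mutant:    {len(mu.hbonds)} H-bonds, {len(mu.polar)} polar contacts")

diff = diff_contacts(wt, mu)
for key, hb in diff.lost_hbonds.items():
    where = "intra-chain" if hb.same_chain else f"inter-chain ({hb.partner_entity})"
    print(f"lost H-bond: {hb.atom.atom_name} .. {hb.partner.label()} "
          f"{hb.distance:.2f} A [{hb.band}, {where}]")
print(f"flags: within={diff.affects_hbond_within} "
      f"other={diff.affects_hbond_other} partners={diff.interchain_partners} "
      f"polar={diff.affects_polar_contacts}")

# A "Y" in the inter-chain column with a partner name is the same kind of
# evidence the summary table reports for variants that create or break
# contacts with neighboring subunits of a complex.
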