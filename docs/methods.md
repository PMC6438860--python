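# Methods

## Scope and model

`varstruct` evaluates what a single amino-acid substitution does to the polar
interaction network around one residue of a resolved macromolecular complex.
The analysis is deliberately geometric: at the 3–4 Å resolution of the
cryo-EM structures it targets, side-chain hydrogens are absent, B-factors are
high, and an energy function would suggest precision the coordinates cannot
support. Every step is deterministic; two runs on the same inputs are
byte-identical.

### Structure model

Structures are read with gemmi from PDB or mmCIF into a chain → residue →
atom hierarchy. Author residue numbering (`auth_seq_id`) is authoritative for
all lookups, because positions quoted in the clinical literature (e.g.
"Ile114") are protein-sequence positions; `label_seq_id` is retained but
never used. Only the first coordinate model of multi-model files is kept
(with a logged warning). Alternate locations are collapsed to the
highest-occupancy conformer, ties broken by lexicographically first altloc
id — the collapse is idempotent and occupancy-monotone. Hydrogens and waters
are kept in the model but flagged, and excluded from all geometry by
default (waters can be re-included via `ContactConfig(include_waters=True)`).
No symmetry expansion is performed; the deposited asymmetric unit is taken
as-is. Units are Å throughout.

### Side-chain mutagenesis

The variant side chain is grown from embedded z-matrix templates
(Engh/Huber-type bond lengths and angles; CB placed on the N/CA/C frame with
the −120° improper that fixes the L-configuration). Backbone atoms are never
moved — the substitution is modeled as a side-chain swap on the observed
backbone, which is exactly what a distance-banded contact analysis can
resolve and no more.

Rotamer choice: each rotatable chi takes values from the grid
(180°, −60°, 60°), searched in that order via the cartesian product; for
Asn/Asp/Gln/Glu the final chi grid is extended with 180°-flipped values
(0°, −120°, 120°) so terminal amide/carboxyl flips are reachable. The
selected rotamer minimizes the clash count — the number of (placed side-chain
heavy atom, environment heavy atom) pairs closer than 2.5 Å, excluding the
mutated residue's own atoms and the covalently adjacent C/N of the flanking
residues. The 2.5 Å cutoff is below any credible hydrogen bond, so it flags
only physically impossible overlap without needing element-specific van der
Waals radii. Ties are broken by smallest angular distance of chi1 from the
observed wild-type chi1 (staying closest to the experimental density), then
by grid order. When the variant type matches the observed residue, the
observed chi vector is prepended as a seed candidate, so self-mutation
reproduces the wild-type side chain on idealized fixtures.

Proline as the variant residue is built as a fixed-pucker ring
(chi = −28°, 35°, tuned once so CD closes to ~1.47 Å from N) and the result
carries an explicit note that the backbone strain a proline would introduce
(the "new kink") is not modeled — it is reported, not simulated.

### Contact shells and hydrogen bonds

Neighbor enumeration uses a k-d tree (scipy) with a closed radius (d ≤ r) and
is exact: property tests assert set equality against an all-pairs brute force
on random clouds. The default shell is 4.0 Å.

Hydrogen bonds are donor–acceptor heavy-atom pairs with
2.2 Å ≤ d ≤ 4.0 Å, banded half-open-left/closed-top:
[2.2, 2.5) strong, [2.5, 3.2) moderate, [3.2, 4.0] weak; below 2.2 Å is
"too-close" (shorter than a credible hydrogen bond). The shared endpoints of
the printed bands are ambiguous in prose; this convention keeps the
classification total and is asserted in tests. Donor/acceptor identity comes
from a per-(residue, atom) role table covering the 20 amino acids (backbone N
donor except proline, backbone O/OXT acceptor, side-chain N/O per chemistry)
and the four ribonucleotides (phosphate OP1/OP2/OP3 and ribose ethers as
acceptors, O2′ both, base N/O per base). Sulfur (Cys SG, Met SD) has only
marginal hydrogen-bonding character and is excluded from roles by default
(`include_sulfur=True` restores weak roles). Covalently bonded and 1-3 pairs
are excluded using a bond graph derived from heavy-atom distances
(< 1.85 Å = bond), which uniformly covers intra-residue bonds, the peptide
link, and RNA without per-residue topology tables. An optional donor-angle
screen (D–A–antecedent ≥ 90°) exists but is off by default, matching the
distance-only criterion appropriate to hydrogen-free models.

Polar contacts are the superset: any pair of role-bearing heavy atoms within
the radius, with the same exclusions, unbanded. Every hydrogen bond's atom
pair is also a polar contact (tested as a subset property).

### Diffing and evidence flags

Wild-type and mutant contact sets for the mutated residue are keyed by
(partner residue identity, partner atom name, own atom name); backbone and
shared atoms (CB) therefore compare stably, while atoms present on only one
side count as gained/lost, never "moved". The flags are:

* **affects H-bonding within the chain**: any gained or lost same-chain
  hydrogen bond;
* **affects H-bonding with other chains**: any gained or lost inter-chain
  hydrogen bond, with the partner chains' molecule names listed (supplied via
  a chain → entity map, since deposited chain ids are assembly-specific);
* **affects polar contacts**: any *lost* polar contact not already counted as
  a hydrogen-bond change — kept separate because summary tables in this field
  report hydrogen-bond changes and residual polar-contact losses as distinct
  columns.

Batch analysis never aborts on a single variant: an unresolved position or a
reference mismatch yields a row with status "unmodelled"/"error" and all
flags "unknown". Flags are "unknown" unless a structural analysis actually
ran. No "pathogenic/benign" verdict is computed.

### Grantham distance

D(a,b) = ρ·[α(c_a−c_b)² + β(p_a−p_b)² + γ(v_a−v_b)²]^½ over the published
composition/polarity/volume triples, α = 1.833, β = 0.1018, γ = 0.000399,
rounded to integers. The scale ρ is computed at import by normalizing the
mean over all 190 unordered pairs to 100 (ρ = 50.7899…). This choice is
load-bearing: the commonly quoted constant 50.723 fails to reproduce the
published Gln↔Leu value of 113 (it gives 112), while the normalization-derived
ρ reproduces every published pair value the test suite asserts. Banding is
≤50 conservative, 51–100 moderately conservative, 101–150 moderately radical,
≥151 radical; the published band edges leave exactly the score 150
unassigned, and it is classed moderately radical so the partition is total.

The catalogued Ala194Glu illustrates why scores are recomputed rather than
copied: the published table prints 91, which is the Ala↔Gln value; the
Ala↔Glu distance is 107. The package ships the computed 107 and retains the
printed 91 in `grantham_as_published`.

### Domain table

Only the flexible loop has published residue boundaries (256–265, inclusive).
Every other entry of the packaged domain table records the localization
printed for a catalogued variant position (e.g. 288/291/299 → "Nop domain
alpha helix 12"); residues between catalogued positions are deliberately
"unassigned" rather than inventing domain boundaries the sources do not
state.

## Synthetic structures: what they emulate, and what they do not

The generator builds three fixture families, all deterministic given their
spec (optional Gaussian coordinate jitter is seeded and reproducible):

* **Ideal helices** — backbone chained by the NeRF construction at uniform
  (φ, ψ, ω), default (−57°, −47°, 180°), giving the classic
  O(i)…N(i+4) ≈ 3.09 Å ladder: ground truth for hydrogen-bond detection
  (a length-n helix yields exactly n−4 ladder bonds, all moderate).
* **Engineered pair fixtures** — two chains rigidly posed so a chosen
  donor–acceptor pair sits at its target distance ±0.01 Å with no other
  inter-chain polar contact inside 4 Å (closed-form placement plus a
  deterministic tilt/roll sweep; construction fails loudly if unsatisfiable):
  ground truth for banding and gained/lost-contact recovery.
* **Protein–RNA fixtures** — a full idealized ribonucleotide (phosphate,
  ribose with O2′, base; pyrimidines and purines) posed with one engineered
  polar contact: exercises RNA roles and inter-entity partner naming.

Fixture chains carry entity labels PROT1/PROT2/RNA1, so partner naming is
exercised without assuming any particular deposited structure. The fixtures
are geometric objects, not biology: they contain no real fold, no packing
environment, no solvent, no experimental noise beyond optional jitter.
Passing tests therefore demonstrate that the machinery — parsing,
mutagenesis, search, banding, diffing, reporting — is exact on known
geometry; they do not validate rotamer realism or flag concordance on real
complexes. For that, an optional concordance script runs the built-in
catalogue against a user-supplied copy of the deposited spliceosome
structure and checks the two inter-chain findings qualitatively.

## Numerical choices

* Radius comparisons are closed (≤); band edges half-open-left, closed-top.
* Internal-coordinate placement (NeRF) realizes torsions exactly (tested to
  1e-6°); side chains rebuilt at reference chis match CCD idealized residues
  to < 0.8 Å per atom (the residual is the difference between dictionary
  value sets, largest for the proline ring).
* Bond detection for exclusion lists: heavy-atom pairs < 1.85 Å. Engineered
  fixture distances are constrained to (1.5, 10) Å and hydrogen-bond
  detection starts at 2.2 Å, so no engineered contact can be misread as a
  bond.
* The structure writer round-trips coordinates to the 0.001 Å precision of
  both formats; strict PDB field widths (1-char chain id, 4-char atom name)
  are enforced with explicit errors, mmCIF is unrestricted.
* Rotamer search order, tie-breaks, and report row ordering (position, then
  variant residue) are all fixed — there is no randomness anywhere in the
  analysis path.

## Known limitations

* No backbone relaxation, energy minimization, or dynamics: a substitution
  whose effect is mediated by backbone rearrangement (notably proline
  insertion) is flagged qualitatively, not modeled.
* Distance-only hydrogen bonds over-count relative to angle-aware criteria
  on high-resolution structures; this is intentional at cryo-EM resolution
  but the optional donor-angle filter exists for sharper models.
* The coarse chi grid (3 values per dihedral) spans rotamer space cheaply
  but cannot represent strained conformers; clash-count ties are resolved by
  proximity to the observed chi1, which presumes the wild-type density is
  informative.
* Chain-to-molecule identity must be supplied by the user (entity map);
  deposited chain ids vary between assemblies and are never guessed.
* Sulfur-mediated and C–H···O interactions, pi-stacking, cation-pi and
  solvation effects are out of scope, as is any stability (ΔΔG) estimate.
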