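# Methods

This note documents the models, surrogate scores, numerical choices and
known limitations behind `dsbdesign`.

## Scope and model of a disulfide bridge

A disulfide bond is treated as a purely geometric/energetic object: two Sγ
atoms, each attached to a Cβ at 1.81 Å with a CA–CB–SG angle of 114.0°, with
ideal bridge stereochemistry d(Sγ–Sγ) = 2.05 Å, CB–S–S angles of 104.15° and
a disulfide torsion χ3 = CB–S–S–CB of ±87° (the torsion is two-fold, so
−93° ≡ +87°). These are standard cystine values from small-molecule and
high-resolution protein stereochemistry. The classic feasibility screen —
Cβ–Cβ within 5 Å, Cα for glycine — is used for enumeration; glycine gets an
ideal virtual Cβ (N–CA–CB 110.6°, C–N–CA–CB −122.6°) when a bridge must be
modeled on it.

Candidate modelling is a grid search: χ1 (N–CA–CB–SG) is swept in steps of
5° (configurable; 72×72 conformer pairs per candidate, vectorized) and the
conformer minimizing the strain energy is kept. Grid search rather than
continuous minimization keeps results deterministic and exactly reproducible;
refining the grid can only lower the reported minimum (a tested invariant).
Ties in the grid are broken by first occurrence in row-major order, which is
deterministic for a fixed grid.

## Surrogate energies

Published commercial implementations of this screen score candidates with
proprietary interaction (ΔEi) and strain (ΔE) energies and classify them
Good / Medium / Bad via fixed cutoffs (Good: ΔEi < 0 and ΔE < 20; Bad:
ΔEi > 40, ΔE > 40, or both > 20; Medium otherwise). The cutoff rule is
implemented verbatim; the energies behind it are this package's own
documented surrogates, in arbitrary units with their zero point at ideal
geometry:

* strain: `k_ss (d_SS − 2.05)² + k_ang [(θ_i − 104.15)² + (θ_j − 104.15)²] +
  k_tor (1 − cos 2(χ3 − 87°))` with k_ss = 100 units/Å², k_ang = 0.02
  units/deg², k_tor = 2 units. The constants are scaled so that geometrically
  hopeless bridges (e.g. d_SS off by > 0.6 Å) exceed the rule's 20/40
  cutoffs while near-ideal bridges stay in single digits.
* interaction: for each Sγ and every heavy atom of all *other* residues,
  `50·max(0, 3.0 − d)²` (clash) minus `0.1` per contact with
  3.5 Å ≤ d ≤ 6.0 Å. Negative totals mean favourable packing. The environment
  is the unmutated structure: no side-chain repacking is attempted.

All constants live in `DesignConfig` and are echoed into every report for
provenance. Surrogate magnitudes are comparable to the rule's cutoffs by
construction, but absolute values should not be compared against any other
scoring function.

## Filters and ranking

Filters annotate, never delete: proximity to configured catalytic residues
(any candidate atom within 10 Å of a catalytic side-chain atom, by default),
membership in a detected native disulfide (Sγ–Sγ ≤ 2.3 Å, greedy
closest-first pairing so each cysteine joins at most one bond), burial
(more than 16 Cβ neighbours within 10 Å — a cheap SASA proxy, documented and
swappable), and adjacency (±2 residues) to a crystallographically disordered
region. Ranking sorts by quality class, then demotes candidates flagged
near-active-site or native-cysteine within their class, then by
`ΔE + max(ΔEi, 0)`, then by Cβ–Cβ distance; the sort is stable. Proline is
excluded as a mutation target (its backbone nitrogen cannot accommodate the
substitution); the 4-residue minimum sequence separation excludes i, i±1..3
pairs that cannot form unstrained bridges.

## Structure I/O policies

Author (auth) residue numbering is canonical throughout, because published
residue labels are author numbers. Alternate locations collapse to the
highest-occupancy conformer (ties by altloc character order); hydrogens are
dropped (all criteria are heavy-atom); waters and HETATM ligands are
stripped on read by default with a flag to keep ligands. Missing-region
detection reports maximal runs of expected-but-absent residue numbers, with
the expected range given explicitly or taken from SEQRES under the
assumption that author numbering starts at 1 — when using a downloaded
entry, verify that assumption rather than renumbering silently. Multi-model
files become ensembles with uniform frame times (default 500 ps per frame,
configurable), since the PDB format carries no time records. Writing uses
fixed-width PDB fields; coordinates outside −999.999..9999.999 are an error.

## Ensemble metrics

* RMSD: backbone selection {N, CA, C} (carbonyl O excluded; the convention is
  configurable), Kabsch superposition per frame with reflections excluded
  (determinant +1), reference = first frame by default or an external
  structure. In published workflows the reference is typically an
  energy-minimized crystal structure; minimization is an MD-engine step
  outside this package's scope, so the external-reference mode accepts
  whatever minimized model the user provides.
* R_g: mass-weighted by standard atomic masses (uniform weighting available),
  centre of mass subtracted, no superposition.
* S–S distances: plain Euclidean Sγ–Sγ per frame — internal coordinates need
  no superposition. Retention is the fraction of frames at or below 2.15 Å
  (the conventional upper bound for an intact disulfide); "stable" is
  reserved for retention exactly 1.0.
* Instability flag: mean RMSD over the final 20 % of frames > 1.5× the mean
  over the first 20 % (window at least one frame). This is a deliberately
  simple trend heuristic for distinguishing drifting from fluctuating
  ensembles; it is not a folding/unfolding classifier. A single-frame
  ensemble reports zero standard deviations and no flag.

The Kabsch implementation is cross-checked in the tests against an
independent quaternion-eigenvalue (Horn) RMSD oracle on 1000 random point
sets to 1e-8; R_g against the direct formula to 1e-9.

## Primer verification

Strand consistency of a mutagenic pair is defined as the reverse primer
matching the reverse complement of the forward primer exactly, or as a
terminal-aligned substring of it (one primer extends past the other by a
short single-stranded overhang — a normal design for overlap-extension
mutagenesis, and two of the six packaged pairs have a one-base 3′ overhang).
Both the strict (`is_exact_revcomp`) and tolerant (`is_revcomp_consistent`)
verdicts are reported, always recomputed from the sequences. The cysteine
codon check (TGT/TGC) is substring-based: the gene sequence, and hence the
reading frame, is not distributed with the primer table, so a frame-aware
check is impossible; a spanning-codon false positive is the accepted cost.
Input is case-insensitive DNA over {A, C, G, T}; U is rejected.

## Synthetic data: what it emulates, and what it does not

Scaffolds are built by sequential ideal-internal-coordinate chain extension
(N–CA 1.458, CA–C 1.525, C–N 1.329 Å; standard angles; ω = 180°) with
fold-level torsions: α-helix (−57, −47) or a two-stranded hairpin. The
hairpin's strand torsions (−110.2, 106.0) and 2-residue turn
((59.6, −109.8), (−94.1, 6.5)) were tuned numerically, once, so that every
cross-strand mirrored pair lands at Cβ–Cβ 4.0–4.7 Å with the side-chain
frames facing, i.e. a modeled bridge reaches d_SS ≈ 2.05 Å with low strain —
a deliberately idealized geometry that a real β-hairpin only approximates.
Requested planted pairs are verified after construction; registries failing
verification are rejected and the next variant from a fixed list is tried
(deterministic re-registration), and an explicit error is raised when no
registry satisfies the request. Planted disulfides refine the grid optimum
by continuous (Nelder–Mead) minimization of the strain surrogate and must
reach 2.05 ± 0.02 Å or fail loudly.

Ensembles are `frame_t = RigidTransform_t(ref + N(0, σ²) noise + t·rate·field)`:
per-atom isotropic Gaussian noise, an optional drift field that grows
linearly with frame index — either a global stretch along the first
principal axis of the reference (normalized to 1 Å at the most-displaced
atom per unit rate) or a targeted pull separating one residue pair along
their Sγ–Sγ axis — and an optional uniform random rotation plus N(0, 5 Å)
translation per frame, which any correct analysis must cancel. Atom names in
`exclude_atoms` follow the rigid frame only; excluding SG emulates the
covalent S–S constraint (independent Gaussian noise of σ = 0.3 Å on both
sulfurs would give the S–S distance a spread of ~0.4 Å, which no intact
covalent bond exhibits). Temperature presets map condition labels to recipes
— 26.85 °C → σ = 0.10 Å, 70 °C → σ = 0.18 Å, 80 °C → σ = 0.22 Å with drift
0.02 Å/frame only when the structure is not disulfide-stabilized. These are
generator conventions chosen to reproduce the qualitative contrast between
cross-linked and unprotected structures, not force laws: the generator has
no solvent, no secondary-structure cooperativity, no temperature physics.
Passing tests therefore demonstrate correctness of the *analysis machinery*
and of the planted ground truth, not the thermodynamics of any real protein.

Default problem sizes — 20-residue scaffolds and 200-frame ensembles —
match the scale at which the reference analyses report their observables
(200 saved frames per trajectory) while keeping the full suite interactive.

## Known limitations

* No side-chain repacking or backbone relaxation around a modeled bridge;
  ΔEi is computed against the rigid unmutated environment.
* Burial uses a Cβ-neighbour count, not SASA.
* Quality cutoffs are applied to surrogate energies; agreement with any
  proprietary screen is qualitative (same rule, different energy scale).
* mmCIF and binary trajectory formats are out of scope; ensembles must be
  multi-model PDB.
* The missing-region detector assumes SEQRES position 1 ↔ author residue 1
  unless an explicit range is given.
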