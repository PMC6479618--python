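# dsbdesign

Structure-based **disulfide-bond (DSB) engineering** for protein
thermostabilization: scan a protein structure for residue pairs that can be
mutated to cysteine to form a stabilizing S–S bridge, model and score each
candidate bridge, and quantify the conformational stability of wild-type
versus engineered variants from coordinate ensembles.

The package is aimed at protein engineers doing rational thermostability
design — the motivating system is an endoglucanase (glycoside hydrolase
family 5) whose industrial use requires surviving a pelletizing step near
80 °C — but every operation is generic over any single-domain protein
structure in PDB format.

## What it computes

**Cysteine scanning.** Two residues are a candidate disulfide when their
Cβ atoms are within 5 Å (Cα for glycine) and they are at least 4 residues
apart in sequence. For each candidate the Sγ atoms are placed explicitly
from each residue's N/CA/CB frame at ideal cystine stereochemistry
(CB–SG = 1.81 Å, ∠CA–CB–SG = 114°) over a grid of χ1 rotamers, keeping the
conformer that minimizes a strain energy

```
ΔE = k_ss (d_SS − 2.05)² + k_ang [(θ_i − 104.15)² + (θ_j − 104.15)²]
     + k_tor (1 − cos 2(χ3 − 87°))
```

where d_SS is the modeled Sγ–Sγ distance, θ the CB–S–S angles and
χ3 = CB–S–S–CB the disulfide torsion (ideal ±87°). A packing score ΔEi
(soft-sphere clash penalty minus a weak contact reward around each Sγ;
negative = favourable) completes the classification rule

* **Good** — ΔEi < 0 and ΔE < 20
* **Bad** — ΔEi > 40, or ΔE > 40, or (ΔEi > 20 and ΔE > 20)
* **Medium** — anything else.

Candidates are never deleted by the advisory filters (near the active site,
involving a native cysteine, buried, adjacent to crystallographic disorder);
they are flagged and demoted in the ranking, since the final choice in a real
campaign mixes criteria with judgment.

**Ensemble stability.** Given multi-model PDB ensembles (stand-ins for MD
trajectory snapshots), the package computes per frame: backbone {N, CA, C}
RMSD after optimal (Kabsch) superposition onto a reference, mass-weighted
radius of gyration R_g, and Sγ–Sγ distances of tracked disulfides. A bond is
*retained* in a frame when d_SS ≤ 2.15 Å; a bond is called stable only when
retention is 1.0 across all frames. An ensemble is flagged unstable when the
mean RMSD over its final 20 % of frames exceeds 1.5× the mean over its first
20 %.

**Primer verification.** Mutagenic primer tables (TSV) are checked for
strand consistency (reverse primer = reverse complement of the forward, up
to a short terminal overhang from staggered ends) and for the presence of a
cysteine codon (TGT/TGC). A six-pair table for the S12C-A270C, S127C-A165C
and Y171C-L201C substitutions ships with the package.

**Synthetic ground truth.** Because real thermal-unfolding trajectories are
cluster-scale, the `synthetic_data` module generates small folded scaffolds
(ideal α-helix or β-hairpin built by internal-coordinate chain extension)
with plantable cysteine pairs and ideal planted disulfides, plus coordinate
ensembles with tunable Gaussian fluctuation, progressive drift (emulating
unfolding) and per-frame random rigid-body transforms — everything the test
suite and acceptance checks need, with exact known truth.

## Worked example

Generate a 20-residue hairpin with a feasible pair planted at residues 6/15
and an ideal disulfide at 4/17, then scan it:

```sh
dsbdesign synth --n-residues 20 --plant-pair 6:15 --disulfide 4:17 \
    --frames 200 --sigma 0.3 --seed 7 --out demo
dsbdesign scan demo.pdb --out demo_scan
```

```
 rank chain_i  res_i aa_i chain_j  res_j aa_j  d_cb  d_ss  chi1_i  chi1_j   chi3  e_strain  e_interaction quality               flags
    1       A      6  SER       A     15  SER 4.062 2.055  -160.0  -125.0 -110.4     0.517           -2.5    Good
    2       A      8  ALA       A     13  ALA 4.057 2.059  -160.0  -125.0 -110.5     0.528           -2.6    Good
  ...
    8       A      4  CYS       A     17  CYS 4.067 2.052  -160.0  -125.0 -110.3     0.530           -2.4    Good involves_native_cys
```

The planted pair ranks first: its Cβ–Cβ distance (4.06 Å) passes the 5 Å
screen, the modeled bridge is 2.055 Å (essentially ideal, strain 0.52) and
packing is favourable (ΔEi = −2.5), so it classifies Good. The planted
native disulfide 4–17 is detected (`native disulfides: 4-17` in the log) and
its pair is demoted to the bottom via the `involves_native_cys` flag.

Analyzing the 200-frame ensemble written next to it:

```sh
dsbdesign analyze demo_ensemble.pdb --bonds 4:17 --temperature 26.85 --out demo_stab
```

```
        label  temperature_C  n_frames  rmsd_mean  rmsd_sd  rg_mean    rg_sd  unstable ss_retention  ss_retention_min  ss_all_stable
demo_ensemble          26.85       200   0.703114 0.060022 9.393622 0.029475     False A4:A17=1.000               1.0           True
```

RMSD fluctuates around 0.70 Å with no drift (not flagged), R_g is steady at
9.39 Å, and the disulfide stays below 2.15 Å in 200 of 200 frames — the
signature of a stably cross-linked structure.

Verify the packaged primer table:

```sh
dsbdesign primers src/dsbdesign/data/table2_primers.tsv
# → "n_pairs": 6, "n_consistent": 6, "n_with_cys_codon": 6
```

For users with a local copy of the endoglucanase crystal structure (PDB
5L9C), `dsbdesign.reference.validate_reference_structure("5L9C.pdb")`
checks the structural facts the design targets: the single native disulfide
C221–C258, the ≤ 5 Å Cβ–Cβ feasibility of the 127/165 and 171/201 pairs, and
the disordered stretch 212–219.

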