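# rigidcsp

Crystal structure prediction (CSP) for small rigid organic molecules, at
desk scale.  The package implements the classic force-field CSP workflow
end to end — quasi-random trial-crystal generation in the common space
groups, staged rigid-body lattice-energy minimisation under an exp-6 +
atomic-multipole energy model, duplicate removal and reference-structure
matching, landscape statistics (energy ranking, space-group preferences,
chiral resolution), and a committee Δ-ML lattice-energy correction trained
by query-by-committee active learning — together with a synthetic-fixture
module so the whole pipeline can be exercised and validated without any
external structure database or electronic-structure code.

It is aimed at people who want a transparent, testable implementation of
the rigid-molecule CSP machinery: each stage is a small library module
with a plain-Python surface, every numerical component is cross-checked
against an independent brute-force oracle, and the study-style analyses
run on landscapes the package generates itself.

## The model

A crystal is a space group *G*, a unit cell, and one rigid molecule in the
asymmetric unit (Z′ = 1); all other molecules are generated by symmetry.
Its **lattice energy** per molecule is

```
E_latt = ½ Σ_i Σ_j' [ A_ij e^(−B_ij r_ij) − C_ij / r_ij⁶ ]   (exp-6, atom–atom)
       + E_elec                                              (atomic multipoles)
```

where *i* runs over the asymmetric-unit molecule, *j* over all other atoms
in the infinite crystal, and the electrostatic part combines an Ewald
summation of the atomic point charges with a whole-molecule direct sum of
the dipole and quadrupole terms.  Rigid monomers make the intramolecular
energy a constant, so `E_latt` is referenced to isolated molecules.

The search minimises `E_latt` over the free packing variables only — the
crystal-system free cell parameters, the molecular centroid, and the
orientation quaternion — so space-group symmetry is preserved exactly.
Starting points come from a scrambled Sobol low-discrepancy sequence;
duplicates among the resulting minima are removed by a powder-pattern
screen confirmed with n-molecule cluster RMSD matching (RMSD_30 for
reporting).  The Δ-ML stage learns ΔE = E_highlevel − E_FF per molecule
on atom-centred symmetry-function descriptors with a committee of eight
regressors, whose disagreement (σ) drives active learning and filters
unreliable corrections when re-ranking a landscape.

## Worked example

```python
import rigidcsp as R
import rigidcsp.analysis as an

mol = R.make_toy_molecule("bent3")              # bent N=C=O-like triatomic
structs = R.run_csp(mol, ["P21", "P-1"], n_valid=40, seed=7)
unique, _ = R.deduplicate(structs)
ls = an.Landscape(mol.name, unique)
gm = ls.global_minimum
print(f"global minimum: E_latt = {gm.e_latt:.3f} kJ/mol, "
      f"rho = {gm.density:.3f} g/cm3, group {gm.group.symbol}")
freq = an.spacegroup_frequencies([ls], "window", window=7.2)
```

prints

```
minimised 80 structures -> 73 unique minima
global minimum: E_latt = -24.423 kJ/mol, rho = 1.326 g/cm3, group P21
space-group frequencies within 7.2 kJ/mol:
P21    0.5
P-1    0.5
```

The 80 quasi-random starts (40 per space group) funnel into 73 unique
minima — many of them families of energy-degenerate stacking variants, a
real feature of small-molecule landscapes that the deduplication keeps
apart because their diffraction patterns differ even though their
15-molecule clusters coincide.  The global minimum is the same packing
whether found through the P21 or the P-1 description (its true symmetry is
higher), which is why the `dE = 0` entries appear in both groups and the
window frequencies split evenly.

The same machinery drives the survey-style analyses: `delta_e` ranks a
match against the (optionally Sohncke-restricted) global minimum,
`chirality_analysis` compares the best enantiopure and racemic packings of
a chiral molecule (ΔE_latt > 0 ⇒ racemate favoured), and
`rigidcsp.ml.train_committee` / `corrected_landscape` fit and apply the
Δ-ML correction.  A `csp` command-line tool wraps the pipeline
(`csp generate`, `csp minimize`, `csp dedupe`, `csp match`, `csp analyze`,
`csp ml …`, `csp fixtures make`).

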