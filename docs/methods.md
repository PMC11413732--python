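# Methods

This note records the scientific and numerical choices behind `rigidcsp`:
the energy model and its guards, the search and comparison machinery, what
the synthetic fixtures emulate (and deliberately do not), and the design
decisions taken where the problem left the design open.

## Scope and model class

The package treats Z′ = 1 crystals of small rigid neutral molecules
(C/H/N/O/F).  A crystal is fully described by a space group, a unit cell
and a single placement (fractional centroid + unit quaternion); all other
molecules are symmetry images.  Molecules are strictly rigid: internal
geometry is never altered by any stage, so the lattice energy is measured
from isolated, non-interacting molecules and contains no intramolecular
term.  Polarisation, induction, free-energy and vibrational contributions
are outside the model class; the 2 kJ mol⁻¹ "thermal window" and the
7.2 kJ mol⁻¹ polymorphism window used in the analyses are interpretation
constants, not computed quantities.

## Units

Å, kJ mol⁻¹, elementary charges; atomic dipoles in e·Å and traceless
(Buckingham-convention) quadrupoles in e·Å², so a single Coulomb constant
k = 1389.35458 kJ mol⁻¹ Å e⁻² covers all electrostatic ranks.  Conversion
from spherical-tensor components (Q₁₀, Q₁₁c, Q₁₁s; Q₂₀ … Q₂₂s) is provided;
moments in atomic units convert by powers of the Bohr radius
(1 e·a₀ = 0.529177 e·Å).

## Repulsion–dispersion

Atom–atom exp-6 (Buckingham): U(r) = A·e^(−Br) − C/r⁶, with homonuclear
parameters per force-field type and combining rules (geometric mean for A
and C, arithmetic for B — the standard choice for exp-6 fields;
configurable).  Two numerical guards define the *working* pair curve:

* **Inner cap.**  The raw exp-6 curve turns over at small r and dives to
  −∞; below the inner barrier maximum r₁ (located per pair by bisection)
  the curve is continued as a steep linear repulsive wall.  Physical
  structures never sample this region (the sampler rejects contacts below
  0.6 × the vdW-radius sum), but line searches during minimisation do.
* **Dispersion taper.**  The −C/r⁶ term is switched off smoothly
  (quintic smoothstep) over the final 1 Å below the cutoff, which removes
  the cutoff discontinuities that otherwise corrupt finite-difference
  gradients.  The analytic uniform-density tail correction integrates the
  *deficit* — taper window plus everything beyond the cutoff — so the
  reported energy stays close to the untruncated sum (verified against
  the brute-force oracle to < 0.01 kJ mol⁻¹ on toy crystals).

Defaults: 15 Å cutoff (toy schedules use 6–9 Å), tail correction on,
0.3 Å hard clash floor below which the geometry is rejected as unphysical.

## Electrostatics

* **Charges** are summed by Ewald (tinfoil boundary conditions): real
  space with erfc screening at α = 4.8/r_real (r_real default 10 Å),
  reciprocal space truncated at the accuracy target (default 10⁻⁸), and
  the rigid intramolecular pairs excluded by an erf correction.  The
  result is independent of the splitting parameter to < 10⁻⁶ kJ mol⁻¹.
* **Dipole and quadrupole terms** (ranks 1–2; the implemented maximum) use
  explicit Cartesian interaction tensors summed in real space over *whole
  molecules* whose centroids lie within the electrostatic cutoff.  The
  whole-molecule grouping keeps every included interaction between neutral
  bodies, so mixed charge–multipole terms decay at least as r⁻⁴; an
  atom-based cutoff is conditionally convergent and was rejected.  For
  crystals whose unit cell carries a net dipole the direct sum is
  conditionally convergent and a warning is emitted; the bundled fixtures
  use molecules with zero net molecular dipole (atomic dipoles cancelling)
  so the remaining sums are absolutely convergent.

The multipole kernels are validated against exact point-charge-array
limits and the classic coaxial-quadrupole closed form (U = 6Θ₁Θ₂/r⁵).

## The brute-force oracle

`brute_force_energy` evaluates the same pair curves by direct double sums
over expanding cubes of whole unit cells — no neighbour lists, no
cutoffs, no Ewald — and converges because each shell of whole cells is
charge-neutral.  It is the independent reference for the production path:
the two agree to < 0.01 kJ mol⁻¹ on the fixture crystals.  Shell sums are
shape-dependent for polar cells (a surface term), so oracle comparisons
use space groups whose image sums cancel the cell dipole (P-1, P21/c,
P212121, Pbca).  Cell quadrupole interactions decay only as 1/S² in the
shell radius S; the Ewald-correctness check therefore runs the rocksalt
toy to S = 34, where the residual is below 10⁻⁴ relative.

## Sampling

Packing variables are drawn from a scrambled Sobol sequence: free cell
parameters per crystal system (shape ratios and angles in [60°, 120°]),
one volume dimension mapped to [0.5, 2.5] × multiplicity × V_mol (V_mol =
vdW-sphere volume / 0.7 packing-efficiency prior), centroid in [0,1)³,
and orientation via the Shoemake map (three uniforms → uniform
rotations).  A candidate passes the geometry check iff no intermolecular
contact is shorter than 0.6 × (vdW_i + vdW_j) (ties pass) — the same
rule per symmetry image and periodic neighbour.  The whole batch is a
pure function of (molecule, group, seed); disjoint index ranges give
disjoint work, so searches parallelise trivially.

## Minimisation

Bounded L-BFGS-B over the free variables only (6/4/3/2/1 cell parameters
for triclinic→cubic, 3 centroid, 3-parameter rotation update composed onto
the quaternion), with forward-difference gradients on coordinates scaled
to a common Å-like arc length.  Cell lengths are bounded to 0.4–2.5 × the
starting value: very repulsive starts otherwise provoke line-search steps
that explode the cell before the surface can guide it back.  Volume per
atom outside [2, 2000] Å³ aborts the run as divergence (the structure is
discarded); hitting the iteration cap keeps the structure flagged
unconverged.

The default three-stage schedule escalates the electrostatic rank and
tightens tolerances (charges-only coarse → charges-only production →
full multipole rank); a two-stage `toy_schedule` (6 Å / 9 Å cutoffs)
drives all desk-scale fixtures.  Planted reference structures receive an
extra "polish" stage (gradient tolerance 10⁻³) so they sit tightly on
their minima; re-minimising one changes E_latt by < 10⁻⁶ kJ mol⁻¹.
Degenerate-direction caveat: in groups with a polar axis the centroid
coordinate along it is a flat direction; L-BFGS-B simply leaves it.

## Comparison and deduplication

Powder patterns are simulated from the reciprocal lattice (Bragg
positions; intensities |F|² with atomic-number form factors — sufficient
for similarity screening, not Rietveld), broadened by a fixed-width
pseudo-Voigt, max-normalised, and compared with a triangle-weighted
cross-correlation (window 1.5°) that is symmetric and scale-invariant.

Cluster matching builds n-molecule clusters around a central molecule
(every symmetry image of the second structure is tried as centre), aligns
central molecules by proper-rotation Kabsch — for *linear* molecules the
free rotation about the molecular axis is scanned, since Kabsch leaves it
undefined — pairs molecules by centroid assignment, and accepts a pair
within a 20 % centroid-distance tolerance and 20° orientation misfit.
If all n pair, the clusters are jointly superposed and RMSD_n reported
(n = 30 for reporting, 15 for dedup; hydrogens included, excludable by
flag).  Atom order is the correspondence; molecules with internal
symmetry would need graph matching, which is out of scope, so the bundled
fixtures are asymmetric by construction.

Deduplication nominates pairs by pattern similarity ≥ 0.98 (within an
optional 0.5 kJ mol⁻¹ energy prefilter), confirms by cluster match,
merges connected components, and keeps the lowest-energy representative
(ties: higher density, then input order).  A notable behaviour, visible
on the toy landscapes: families of energy-degenerate *stacking variants*
share identical 15–30-molecule clusters but different lattices; the
pattern screen correctly keeps them apart even though cluster matching
alone would merge them.

## Landscape analyses

ΔE is measured from the landscape's global minimum — restricted to
Sohncke groups for single-enantiomer chiral molecules (a group is Sohncke
iff every operation's rotation determinant is +1; this matches the
determinant test for all 230 groups).  Space-group frequencies come in
three selectors (per-landscape global minimum, per-landscape densest,
pooled window counts; a per-landscape-normalised window variant sits
behind a flag because both conventions are defensible).  The chirality
record is ΔE_latt = E_min(Sohncke) − E_min(racemic) (positive ⇒ racemate
favoured) and Δρ as the relative density difference (negative ⇒
enantiopure less dense, the Wallach direction).  CSP groups are used
as-is — no symmetry re-detection — so they are lower bounds on the true
symmetry; the worked example in the README shows the same global minimum
surfacing through both its P21 and P-1 sub-descriptions.

## Synthetic fixtures

Toy molecules are fixed coordinate templates (2–11 atoms): a polar
diatomic, a bent triatomic, a planar four-atom, a pyridine-like ring, and
chiral tetrahedra with four distinct substituents.  All are neutral and
free of internal symmetry so packings have unambiguous identity under
atom-order correspondence.  The toy exp-6 table uses magnitudes typical
of empirical organic force fields, chosen once so toy crystals minimise
at 1.1–1.6 g cm⁻³; it makes no claim of matching any published
parameterisation (real tables load from a plain-text parameter file).
The `chiral_resolver` template carries a strongly dipolar charge pattern
whose antiparallel (inversion-related, heterochiral) pairing is designed
to favour the racemate, giving the end-to-end chirality analysis a
known-sign answer (+0.6 kJ mol⁻¹ on the bundled search protocol).

Reference crystals are *planted* by actually running a short CSP and
polishing the global minimum, so every reference is a genuine certified
minimum of the implemented model — the role an experimental structure
plays in matching studies.

**The high-level oracle** stands in for periodic electronic-structure
energies: E_high = E_FF + amplitude·tanh(gain · w·φ̃) + N(0, σ), where φ̃
is the pooled ACSF descriptor standardised by constants calibrated once
on a reference sample and stored in the oracle config, and w is a fixed
random unit direction.  This makes the systematic part bounded, Lipschitz
and *learnable from the model's own inputs by construction*; the noise is
hash-seeded per structure so repeated queries agree.  What it does not
emulate: any real quantum-chemical physics, many-body or long-range
effects absent from the descriptors, or realistic error correlations —
so passing the recovery experiments demonstrates that the Δ-ML machinery
works, not that it would reach any particular accuracy on real reference
data.

## Δ-ML correction

Descriptors are atom-centred symmetry functions (five neighbour-element
radial channels × six Gaussian centres to the 6 Å cutoff, plus a small
angular (ζ, λ) grid), invariant to rigid motions and identical-atom
permutations, with periodic neighbours included; the per-molecule
descriptor is the sum over asymmetric-unit atoms, which keeps the model
additive in atomic contributions.  The committee holds eight sklearn MLP
regressors (one hidden layer of 64, L-BFGS) diversified by bootstrap and
seed; mean = predicted ΔE, standard deviation = uncertainty.  Datasets
sample up to N structures per landscape inside an 8 kJ mol⁻¹ window,
split ~85 % of compounds into training (≥ 1 compound always held for
extrapolation) with one in-domain test structure withheld per training
compound.  Re-ranking uses E_corr = E_FF + ΔE_pred and excludes
predictions with σ above 25 kJ mol⁻¹.

**Recovery protocols** (fixed once, seeded): six single-group landscapes
(bent3, planar4, diatomic, chiral5, plus two charge-scaled variants; 40
accepted trials each), oracle σ = 0.5 kJ mol⁻¹ with gain 1.0.  Held-out
error is evaluated over every window structure of the training compounds
not trained on (a handful of single withheld structures gives an
over-noisy MAE).  Rank recovery compares corrected against true
(noise-free systematic) energies per landscape, over energy levels
separated by more than the noise — degenerate stacking families carry
identical true energies, and rank statistics are only meaningful across
distinguishable levels.  The reorder-recovery experiment uses a separate
strong/low-noise setting (gain 2.0, σ = 0.1) so the correction genuinely
permutes force-field ranks, pooled over four training seeds.
Query-by-committee is compared with random selection by the median (over
ten seeds) of the selected structures' true errors.

## Problem sizes

The bundled experiments run at desk scale by design: 20–200 accepted
trials per space group (the survey-scale preset of 10 000 per group is a
config constant, not exercised by the tests), clusters of 15 molecules
for dedup and 30 for reporting, six-compound Δ-ML suites, ten-seed
rediscovery and selection experiments.  Rediscovery checks stop a seed
early once the planted reference is matched — equivalent to testing
whether the full batch contains a match, at a fraction of the cost.

## Known limitations

Z′ = 1 only; no special positions; no symmetry re-detection; multipole
rank ≤ 2; no analytic gradients (finite differences bound the achievable
gradient tolerance); conditionally convergent dipole sums for polar cells
are warned about rather than resummed; molecules with internal symmetry
defeat the atom-order correspondence in RMSD comparisons; the CIF reader
targets the package's own output plus plain single-block files, not the
full generality of the format.
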