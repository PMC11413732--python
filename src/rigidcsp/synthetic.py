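"""Synthetic fixtures: toy rigid molecules, planted reference crystals and
a stand-in high-level energy oracle.

These emulate the inputs of a large-scale CSP survey at desk scale:

* small, rigid, neutral C/H/N/O/F molecules (including chiral variants)
  whose geometries are fixed template coordinates — deliberately free of
  internal symmetry so that landscape fixtures have unambiguous identity;
* reference crystals planted by actually running the CSP pipeline, so they
  are genuine local minima of the implemented energy model (taking the
  role experimental structures play in matching studies);
* a deterministic smooth "high-level" energy oracle — force-field energy
  plus a bounded smooth function of the crystal's pooled descriptors plus
  reproducible per-structure noise — standing in for periodic DFT so the
  Δ-ML stage is trainable and checkable.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np

from .chem import (Atom, MultipoleSet, RigidMolecule, TOY_FORCE_FIELD,
                   molecular_rmsd)
from .crystal import MinimizedCrystal
from .energy import EnergySettings
from .minimize import MinimizationDiverged, StageSchedule, run_schedule, toy_schedule
from .ml import DescriptorConfig, pooled_descriptor
from .sampler import SamplerConfig, generate_batch
from .symmetry import SpaceGroup, spacegroup

__all__ = [
    "ToyMoleculeSpec",
    "SyntheticOracleConfig",
    "TEMPLATES",
    "make_toy_molecule",
    "perturb_conformer",
    "plant_reference",
    "PlantingError",
    "run_csp",
    "highlevel_oracle",
    "make_oracle",
]


class PlantingError(RuntimeError):
    """No converged structure emerged while planting a reference."""


@dataclass(frozen=True)
class ToyMoleculeSpec:
    template: str
    seed: int = 0
    charge_scale: float = 1.0
    with_multipoles: bool = False


def _tetrahedral_vertices():
    return np.array([
        [1.0, 1.0, 1.0],
        [1.0, -1.0, -1.0],
        [-1.0, 1.0, -1.0],
        [-1.0, -1.0, 1.0],
    ]) / math.sqrt(3.0)


def _ring_template():
    """Pyridine-like planar ring: 1 N + 5 C + 5 H (11 atoms)."""
    atoms = []
    r_ring, r_h = 1.39, 2.47
    ring_elems = ["N", "C", "C", "C", "C", "C"]
    ring_q = [-0.40, 0.17, 0.02, 0.05, 0.02, 0.17]
    for k, (e, q) in enumerate(zip(ring_elems, ring_q)):
        a = 2.0 * math.pi * k / 6.0
        atoms.append((e, (r_ring * math.cos(a), r_ring * math.sin(a), 0.0), q))
    for k in range(1, 6):  # H on each carbon
        a = 2.0 * math.pi * k / 6.0
        atoms.append(("H", (r_h * math.cos(a), r_h * math.sin(a), 0.0), -0.006))
    return atoms


# template name -> list of (element, xyz, charge); all neutral, none with
# internal symmetry (so atom-order correspondence identifies packings
# unambiguously), chiral templates marked below
_BENT_ANGLE = math.radians(124.0)
TEMPLATES: dict = {
    # CO-like polar diatomic
    "diatomic": [
        ("C", (0.0, 0.0, 0.0), 0.25),
        ("O", (1.13, 0.0, 0.0), -0.25),
    ],
    # bent asymmetric NCO-like triatomic
    "bent3": [
        ("O", (1.23, 0.0, 0.0), -0.35),
        ("C", (0.0, 0.0, 0.0), 0.60),
        ("N", (1.35 * math.cos(_BENT_ANGLE), 1.35 * math.sin(_BENT_ANGLE), 0.0), -0.25),
    ],
    # planar asymmetric 4-atom (formyl fluoride-like)
    "planar4": [
        ("C", (0.0, 0.0, 0.0), 0.30),
        ("O", (1.21, 0.0, 0.0), -0.40),
        ("F", (-0.75, 1.10, 0.0), -0.15),
        ("H", (-0.62, -0.90, 0.0), 0.25),
    ],
    "ring": _ring_template(),
    # chiral tetrahedron: C with four distinct substituents
    "chiral5": [
        ("C", (0.0, 0.0, 0.0), 0.50),
        ("H", tuple(1.09 * _tetrahedral_vertices()[0]), 0.05),
        ("N", tuple(1.47 * _tetrahedral_vertices()[1]), -0.25),
        ("O", tuple(1.43 * _tetrahedral_vertices()[2]), -0.20),
        ("F", tuple(1.35 * _tetrahedral_vertices()[3]), -0.10),
    ],
    # chiral tetrahedron with a strong dipolar charge pattern: favours
    # antiparallel (inversion-related, heterochiral) packing, giving the
    # chirality analysis a designed-in racemate-favoured answer
    "chiral_resolver": [
        ("C", (0.0, 0.0, 0.0), 0.30),
        ("H", tuple(1.09 * _tetrahedral_vertices()[0]), 0.45),
        ("N", tuple(1.47 * _tetrahedral_vertices()[1]), -0.45),
        ("O", tuple(1.43 * _tetrahedral_vertices()[2]), -0.25),
        ("F", tuple(1.35 * _tetrahedral_vertices()[3]), -0.05),
    ],
}

_CHIRAL_TEMPLATES = {"chiral5", "chiral_resolver"}


def make_toy_molecule(spec: ToyMoleculeSpec | str) -> RigidMolecule:
    """Instantiate a toy molecule from a template spec (deterministic)."""
    if isinstance(spec, str):
        spec = ToyMoleculeSpec(spec)
    if spec.template not in TEMPLATES:
        raise KeyError(f"unknown toy template {spec.template!r}")
    entries = TEMPLATES[spec.template]
    charges = np.array([q for _, _, q in entries]) * spec.charge_scale
    charges -= charges.mean()  # exact neutrality under any scaling
    atoms = [
        Atom(e, xyz, ff_type=e, charge=float(q))
        for (e, xyz, _), q in zip(entries, charges)
    ]
    multipoles = None
    if spec.with_multipoles:
        multipoles = _template_multipoles(spec.template, charges, len(atoms))
    return RigidMolecule(
        f"{spec.template}-{spec.seed}",
        atoms,
        multipoles,
        is_chiral=spec.template in _CHIRAL_TEMPLATES,
        stereo_label="R" if spec.template in _CHIRAL_TEMPLATES else None,
    )


def _template_multipoles(template: str, charges, n: int) -> MultipoleSet:
    """Modest atomic dipoles/quadrupoles with zero net molecular dipole
    (keeping the lattice sums absolutely convergent)."""
    rng = np.random.default_rng(abs(hash(template)) % (2**31))
    dip = 0.05 * rng.standard_normal((n, 3))
    dip -= dip.mean(axis=0)  # net molecular point-dipole term cancels
    quad = np.zeros((n, 3, 3))
    for i in range(n):
        m = 0.08 * rng.standard_normal((3, 3))
        m = 0.5 * (m + m.T)
        m -= np.eye(3) * np.trace(m) / 3.0
        quad[i] = m
    return MultipoleSet(charges, dip, quad)


def perturb_conformer(mol: RigidMolecule, magnitude: float, seed: int = 0) -> RigidMolecule:
    """Gaussian-perturbed conformer with RMSD ≈ ``magnitude`` (±10%).

    Displacements are rescaled iteratively so the post-superposition RMSD
    matches the requested magnitude; atom count and order are preserved.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be non-negative")
    if magnitude == 0:
        return mol.with_positions(mol.positions.copy())
    rng = np.random.default_rng(seed)
    d = rng.standard_normal(mol.positions.shape)
    scale = magnitude / np.sqrt(np.mean(np.sum(d * d, axis=1)))
    out = mol
    for _ in range(4):
        out = mol.with_positions(mol.positions + scale * d)
        r = molecular_rmsd(mol, out)
        if r == 0:
            break
        scale *= magnitude / r
    return out


def run_csp(mol: RigidMolecule, groups, n_valid: int = 100, seed: int = 0,
            schedule: StageSchedule | None = None, ff=None,
            settings: EnergySettings | None = None,
            dedup: bool = False) -> list[MinimizedCrystal]:
    """A small end-to-end CSP: sample, minimise, optionally deduplicate.

    Returns the converged minimised structures sorted by energy.
    """
    from .compare import deduplicate

    ff = ff or TOY_FORCE_FIELD
    schedule = schedule or toy_schedule()
    out = []
    for g in groups:
        group = spacegroup(g)
        cfg = SamplerConfig(seed=seed)
        for trial in generate_batch(group, mol, cfg, n_valid):
            try:
                mc = run_schedule(trial, schedule, ff, settings)
            except MinimizationDiverged:
                continue
            if mc.converged:
                out.append(mc)
    out.sort(key=lambda s: s.e_latt)
    if dedup:
        out, _ = deduplicate(out)
    return out


def plant_reference(mol: RigidMolecule, group, seed: int = 0,
                    n_valid: int = 60, schedule: StageSchedule | None = None,
                    ff=None, settings: EnergySettings | None = None) -> MinimizedCrystal:
    """Plant a reference crystal: run a short CSP in one space group and
    return the global minimum found (a certified minimum of the implemented
    energy model, playing the role of the experimental structure)."""
    found = run_csp(mol, [group], n_valid=n_valid, seed=seed,
                    schedule=schedule, ff=ff, settings=settings)
    if not found:
        raise PlantingError(
            f"no converged structure found for {mol.name} in {group}"
        )
    # polish so the reference sits tightly on its minimum (fixed-point
    # certificate for downstream tests)
    from .minimize import minimize_stage, polish_stage

    ff = ff or TOY_FORCE_FIELD
    rank = (schedule or toy_schedule()).stages[-1].rank
    return minimize_stage(found[0], polish_stage(rank), ff, settings)


def rediscovers(reference: MinimizedCrystal, seed: int, n_valid: int = 200,
                schedule: StageSchedule | None = None, ff=None,
                settings: EnergySettings | None = None,
                rmsd_tol: float = 0.3, n_cluster: int = 15) -> bool:
    """Does a fresh CSP in the reference's space group rediscover it?

    Generates up to ``n_valid`` geometry-checked trials (a fresh seed),
    minimising and matching each against the reference as it arrives;
    returns True as soon as a cluster match below ``rmsd_tol`` appears.
    Equivalent to asking whether the full ``n_valid`` batch contains a
    match, but stops early on success.
    """
    from .compare import cluster_match

    ff = ff or TOY_FORCE_FIELD
    schedule = schedule or toy_schedule()
    mol = reference.molecule
    group = reference.group
    cfg = SamplerConfig(seed=seed)
    for trial in generate_batch(group, mol, cfg, n_valid):
        try:
            mc = run_schedule(trial, schedule, ff, settings)
        except MinimizationDiverged:
            continue
        if not mc.converged:
            continue
        m = cluster_match(reference, mc, n=n_cluster)
        if m.matched and m.rmsd < rmsd_tol:
            return True
    return False


def perturb_crystal(crystal, seed: int = 0, cell_frac: float = 0.02,
                    pos_ang: float = 0.1, rot_deg: float = 5.0):
    """Perturbed copy of a crystal: cell lengths jittered by ``cell_frac``
    (relative), the molecular centroid by ``pos_ang`` Å and the orientation
    by ``rot_deg`` degrees about a random axis — the standard
    plant-perturb-recover protocol for exercising the minimiser."""
    from scipy.spatial.transform import Rotation

    from .crystal import TrialCrystal
    from .symmetry import Cell, Placement, constrain_cell

    rng = np.random.default_rng(seed)
    cell = crystal.cell
    fac = 1.0 + cell_frac * rng.standard_normal(3)
    new_cell = constrain_cell(crystal.group, Cell(
        cell.a * fac[0], cell.b * fac[1], cell.c * fac[2],
        cell.alpha, cell.beta, cell.gamma,
    ))
    M = new_cell.matrix
    shift_cart = pos_ang * rng.standard_normal(3)
    cen = np.asarray(crystal.placement.centroid) + shift_cart @ np.linalg.inv(M)
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    dq = Rotation.from_rotvec(axis * math.radians(rot_deg))
    q = (dq * crystal.placement.rotation).as_quat()
    return TrialCrystal(crystal.group, new_cell,
                        Placement(tuple(cen % 1.0), tuple(q)),
                        crystal.molecule, index=crystal.index, seed=seed)


@dataclass(frozen=True)
class SyntheticOracleConfig:
    """Configuration of the stand-in high-level energy oracle.

    E_highlevel = E_FF + f + Normal(0, noise_sigma), with the smooth
    systematic part

        f = amplitude · tanh( gain · w·φ̃ ),

    where φ̃ is the pooled descriptor vector standardised by the
    calibration constants stored in the config (``phi_center``,
    ``phi_scale``) and ``w`` a fixed unit vector over the descriptor
    dimensions.  Calibrating on a reference sample of crystals
    (:func:`calibrate_oracle`) conditions the projection so that f varies
    by O(amplitude) both between and within landscapes — bounded,
    Lipschitz, and learnable from the same descriptors by construction.
    Without calibration the descriptor vector is simply normalised to unit
    length.  The noise is seeded per structure id, so repeated queries are
    identical.
    """

    amplitude: float = 3.0        # kJ/mol, scale of the systematic correction
    noise_sigma: float = 0.5      # kJ/mol
    seed: int = 0
    gain: float = 1.5             # slope of the tanh argument (keeps f smooth)
    phi_center: tuple | None = None   # calibration: descriptor means
    phi_scale: tuple | None = None    # calibration: descriptor scales
    descriptor: DescriptorConfig = field(default_factory=DescriptorConfig)


def make_oracle(config: SyntheticOracleConfig):
    """Returns ``oracle(crystal) -> float`` (E_highlevel in kJ/mol)."""
    rng = np.random.default_rng(config.seed)
    w: dict[int, np.ndarray] = {}

    def direction(dim: int) -> np.ndarray:
        if dim not in w:
            v = np.random.default_rng(config.seed + dim).standard_normal(dim)
            w[dim] = v / np.linalg.norm(v)
        return w[dim]

    def oracle(crystal) -> float:
        e_ff = crystal.e_latt if isinstance(crystal, MinimizedCrystal) else None
        if e_ff is None:
            raise ValueError("oracle expects a minimised crystal with energy")
        return e_ff + oracle_correction(crystal, config, direction)

    return oracle


def calibrate_oracle(config: SyntheticOracleConfig,
                     crystals) -> SyntheticOracleConfig:
    """Freeze descriptor standardisation constants from a reference sample.

    Part of constructing the oracle for an experiment: the constants become
    fixed functional-form parameters, so every subsequent query is a pure
    function of (structure, config)."""
    from dataclasses import replace as _replace

    phi = np.stack([pooled_descriptor(c, config.descriptor) for c in crystals])
    center = phi.mean(axis=0)
    scale = phi.std(axis=0)
    scale[scale < 1e-9] = 1.0
    return _replace(config, phi_center=tuple(center), phi_scale=tuple(scale))


def oracle_correction(crystal, config: SyntheticOracleConfig, direction=None) -> float:
    """The smooth systematic part f(structure) plus the seeded noise."""
    phi = pooled_descriptor(crystal, config.descriptor)
    if config.phi_center is not None:
        # w has unit norm, so z ~ gain × O(1) over the calibration sample
        phi_hat = (phi - np.asarray(config.phi_center)) / np.asarray(config.phi_scale)
    else:
        norm = np.linalg.norm(phi)
        phi_hat = phi / norm if norm > 0 else phi
    if direction is None:
        v = np.random.default_rng(config.seed + phi.size).standard_normal(phi.size)
        wvec = v / np.linalg.norm(v)
    else:
        wvec = direction(phi.size)
    z = config.gain * float(wvec @ phi_hat)
    f = config.amplitude * math.tanh(z)
    if config.noise_sigma > 0:
        h = hashlib.sha256(
            f"{config.seed}:{crystal.structure_id}".encode()
        ).digest()
        sub = int.from_bytes(h[:4], "little") % (2**31)
        eps = float(np.random.default_rng(sub).standard_normal()) * config.noise_sigma
    else:
        eps = 0.0
    return f + eps


def highlevel_oracle(crystal, config: SyntheticOracleConfig | None = None) -> float:
    """Stand-in high-level lattice energy (kJ/mol) for one crystal."""
    config = config or SyntheticOracleConfig()
    return make_oracle(config)(crystal)


def energy_distinct(structures, values=None, min_gap: float = 0.05):
    """Indices of structures whose energies are pairwise distinguishable.

    Degenerate packing families (e.g. stacking variants) carry identical
    energies; rank-based comparisons are only meaningful across distinct
    energy levels, so near-ties (within ``min_gap`` kJ/mol) collapse to
    their first representative.
    """
    if values is None:
        values = [s.e_latt for s in structures]
    order = np.argsort(values)
    out = []
    last = None
    for i in order:
        v = values[i]
        if last is None or v - last >= min_gap:
            out.append(int(i))
            last = v
    return sorted(out)
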