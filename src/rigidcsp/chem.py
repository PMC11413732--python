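"""Molecular and force-field data model shared by every stage of the pipeline.

Units used throughout the package: lengths in Å, energies in kJ mol⁻¹,
charges in elementary charges *e*, atomic dipoles in e·Å and (traceless,
Buckingham-convention) quadrupoles in e·Å².

Molecules are strictly rigid: the internal geometry set here is never
altered by sampling, minimisation or analysis.  Only elements C, H, N, O
and F are supported by the bundled tables, matching the survey's scope of
small rigid organics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Atom",
    "MultipoleSet",
    "RigidMolecule",
    "PairParams",
    "ForceField",
    "combine_params",
    "molecular_rmsd",
    "mirror_image",
    "load_force_field",
    "load_molecule_xyz",
    "write_molecule_xyz",
    "VDW_RADII",
    "ATOMIC_MASSES",
    "ATOMIC_NUMBERS",
    "TOY_FORCE_FIELD",
]

# Bondi van der Waals radii (Å) — used only for overlap checks and volume
# estimates, never in the energy model.
VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47}

ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998}
ATOMIC_NUMBERS = {"H": 1, "C": 6, "N": 7, "O": 8, "F": 9}

STANDARD_ELEMENTS = frozenset(VDW_RADII)


class ParameterMissingError(KeyError):
    """A force-field atom type has no parameters."""


@dataclass(frozen=True)
class Atom:
    """One atom of a rigid molecule.

    ``ff_type`` is a free-form force-field type label; ``charge`` is the
    atomic point charge (the rank-0 multipole).
    """

    element: str
    position: tuple[float, float, float]
    ff_type: str
    charge: float = 0.0
    vdw_radius: float | None = None

    def __post_init__(self):
        if self.element not in STANDARD_ELEMENTS:
            raise ValueError(f"unsupported element {self.element!r} (C,H,N,O,F only)")
        if self.vdw_radius is None:
            object.__setattr__(self, "vdw_radius", VDW_RADII[self.element])
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")
        object.__setattr__(self, "position", tuple(float(x) for x in self.position))


# Spherical -> Cartesian conversion factors follow Stone's conventions with
# the Buckingham traceless quadrupole Θ_ab = Σ q (3 x_a x_b − r² δ_ab)/2.
_SQ3_2 = np.sqrt(3.0) / 2.0


class MultipoleSet:
    """Atom-centred multipole moments up to quadrupole (rank 2).

    Internally Cartesian: ``charges`` (n,), ``dipoles`` (n,3) in e·Å and
    traceless ``quadrupoles`` (n,3,3) in e·Å².  Rank 3-4 moments are not
    implemented; the electrostatic model is truncated at quadrupole.
    """

    def __init__(self, charges, dipoles=None, quadrupoles=None, rank: int | None = None):
        self.charges = np.asarray(charges, dtype=float)
        n = self.charges.shape[0]
        self.dipoles = (
            np.zeros((n, 3)) if dipoles is None else np.asarray(dipoles, dtype=float)
        )
        self.quadrupoles = (
            np.zeros((n, 3, 3))
            if quadrupoles is None
            else np.asarray(quadrupoles, dtype=float)
        )
        if self.dipoles.shape != (n, 3) or self.quadrupoles.shape != (n, 3, 3):
            raise ValueError("inconsistent multipole array shapes")
        if rank is None:
            rank = 0
            if np.any(self.dipoles):
                rank = 1
            if np.any(self.quadrupoles):
                rank = 2
        if not 0 <= rank <= 2:
            raise ValueError("implemented multipole ranks are 0-2")
        self.rank = int(rank)

    @classmethod
    def from_spherical(cls, charges, dipoles_sph=None, quadrupoles_sph=None):
        """Build from spherical-tensor components.

        ``dipoles_sph``: (n,3) columns (Q10, Q11c, Q11s);
        ``quadrupoles_sph``: (n,5) columns (Q20, Q21c, Q21s, Q22c, Q22s).
        """
        charges = np.asarray(charges, dtype=float)
        n = charges.shape[0]
        dip = np.zeros((n, 3))
        quad = np.zeros((n, 3, 3))
        rank = 0
        if dipoles_sph is not None:
            d = np.asarray(dipoles_sph, dtype=float)
            dip[:, 2] = d[:, 0]  # z
            dip[:, 0] = d[:, 1]  # x
            dip[:, 1] = d[:, 2]  # y
            rank = 1
        if quadrupoles_sph is not None:
            q = np.asarray(quadrupoles_sph, dtype=float)
            q20, q21c, q21s, q22c, q22s = q.T
            quad[:, 2, 2] = q20
            quad[:, 0, 0] = -0.5 * q20 + _SQ3_2 * q22c
            quad[:, 1, 1] = -0.5 * q20 - _SQ3_2 * q22c
            quad[:, 0, 2] = quad[:, 2, 0] = _SQ3_2 * q21c
            quad[:, 1, 2] = quad[:, 2, 1] = _SQ3_2 * q21s
            quad[:, 0, 1] = quad[:, 1, 0] = _SQ3_2 * q22s
            rank = 2
        return cls(charges, dip, quad, rank=rank)

    def rotated(self, R: np.ndarray) -> "MultipoleSet":
        """Transform moments by a 3×3 orthogonal matrix (proper or improper)."""
        R = np.asarray(R, dtype=float)
        dip = self.dipoles @ R.T
        quad = np.einsum("ab,nbc,dc->nad", R, self.quadrupoles, R)
        return MultipoleSet(self.charges.copy(), dip, quad, rank=self.rank)

    def inverted(self) -> "MultipoleSet":
        """Parity transform (inversion through the origin)."""
        return self.rotated(-np.eye(3))

    def __eq__(self, other):
        return (
            isinstance(other, MultipoleSet)
            and self.rank == other.rank
            and np.allclose(self.charges, other.charges)
            and np.allclose(self.dipoles, other.dipoles)
            and np.allclose(self.quadrupoles, other.quadrupoles)
        )


class RigidMolecule:
    """An ordered collection of atoms treated as a rigid body.

    The pipeline only ever translates/rotates the molecule as a whole;
    internal geometry is immutable.
    """

    def __init__(
        self,
        name: str,
        atoms: list[Atom],
        multipoles: MultipoleSet | None = None,
        is_chiral: bool = False,
        stereo_label: str | None = None,
    ):
        if len(atoms) < 2:
            raise ValueError("a rigid molecule needs at least 2 atoms")
        self.name = name
        self.atoms = list(atoms)
        self.positions = np.array([a.position for a in atoms], dtype=float)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        self.elements = [a.element for a in atoms]
        self.ff_types = [a.ff_type for a in atoms]
        self.charges = np.array([a.charge for a in atoms], dtype=float)
        self.vdw_radii = np.array([a.vdw_radius for a in atoms], dtype=float)
        if abs(self.charges.sum()) > 1e-8:
            raise ValueError(f"molecule {name!r} is not neutral (q={self.charges.sum():g})")
        if multipoles is None:
            multipoles = MultipoleSet(self.charges)
        if not np.allclose(multipoles.charges, self.charges, atol=1e-10):
            raise ValueError("rank-0 multipole components must equal atom charges")
        self.multipoles = multipoles
        self.is_chiral = bool(is_chiral)
        self.stereo_label = stereo_label

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    @property
    def local_coords(self) -> np.ndarray:
        """Coordinates relative to the geometric centroid."""
        return self.positions - self.centroid

    @property
    def mass(self) -> float:
        """Molecular mass, g mol⁻¹."""
        return float(sum(ATOMIC_MASSES[e] for e in self.elements))

    @property
    def radius(self) -> float:
        """Largest centroid-to-atom distance plus the vdW radius, Å."""
        d = np.linalg.norm(self.local_coords, axis=1)
        return float(np.max(d + self.vdw_radii))

    def vdw_volume(self) -> float:
        """Sum of atomic vdW sphere volumes (no overlap correction), Å³."""
        return float(np.sum(4.0 / 3.0 * np.pi * self.vdw_radii**3))

    def with_positions(self, positions: np.ndarray, name: str | None = None,
                       multipoles: MultipoleSet | None = None,
                       stereo_label: str | None = None) -> "RigidMolecule":
        atoms = [
            replace(a, position=tuple(p)) for a, p in zip(self.atoms, positions)
        ]
        return RigidMolecule(
            name if name is not None else self.name,
            atoms,
            multipoles if multipoles is not None else self.multipoles,
            is_chiral=self.is_chiral,
            stereo_label=stereo_label if stereo_label is not None else self.stereo_label,
        )


@dataclass(frozen=True)
class PairParams:
    """exp-6 (Buckingham) pair parameters: A·exp(−B·r) − C/r⁶."""

    A: float  # kJ mol⁻¹
    B: float  # Å⁻¹
    C: float  # kJ mol⁻¹ Å⁶

    def __post_init__(self):
        if self.A < 0 or self.C < 0 or self.B <= 0:
            raise ValueError("require A ≥ 0, B > 0, C ≥ 0")


def _combine(x: float, y: float, rule: str) -> float:
    if rule == "geometric":
        return float(np.sqrt(x * y))
    if rule == "arithmetic":
        return 0.5 * (x + y)
    raise ValueError(f"unknown combining rule {rule!r}")


class ForceField:
    """Homonuclear exp-6 parameters per ff_type plus combining rules.

    Default rules (geometric mean for A and C, arithmetic mean for B) are the
    standard choice for FIT-style exp-6 fields and are configurable.
    """

    def __init__(
        self,
        params: dict[str, PairParams],
        rules: tuple[str, str, str] = ("geometric", "arithmetic", "geometric"),
    ):
        self.params = dict(params)
        self.rules = tuple(rules)

    def combine(self, type_i: str, type_j: str) -> PairParams:
        for t in (type_i, type_j):
            if t not in self.params:
                raise ParameterMissingError(f"no exp-6 parameters for ff_type {t!r}")
        pi, pj = self.params[type_i], self.params[type_j]
        ra, rb, rc = self.rules
        return PairParams(
            _combine(pi.A, pj.A, ra), _combine(pi.B, pj.B, rb), _combine(pi.C, pj.C, rc)
        )

    def pair_tables(self, ff_types: list[str]):
        """Dense (n,n) A/B/C matrices for an ordered atom-type list."""
        n = len(ff_types)
        A = np.empty((n, n))
        B = np.empty((n, n))
        C = np.empty((n, n))
        for i, ti in enumerate(ff_types):
            for j, tj in enumerate(ff_types):
                p = self.combine(ti, tj)
                A[i, j], B[i, j], C[i, j] = p.A, p.B, p.C
        return A, B, C


def combine_params(type_i: str, type_j: str, ff: ForceField) -> PairParams:
    """Cross-term exp-6 parameters for a pair of atom types (symmetric)."""
    return ff.combine(type_i, type_j)


# Self-consistent toy homonuclear exp-6 table for C,H,N,O,F.  Magnitudes are
# typical of empirical exp-6 fields for organics but the values are this
# package's own (chosen so toy crystals minimise at sane densities); real
# published parameter sets load from a parameter file instead.
TOY_FORCE_FIELD = ForceField(
    {
        "C": PairParams(226000.0, 3.60, 2200.0),
        "H": PairParams(11000.0, 3.74, 130.0),
        "N": PairParams(365000.0, 3.78, 1300.0),
        "O": PairParams(295000.0, 3.96, 1250.0),
        "F": PairParams(300000.0, 4.20, 600.0),
    }
)


def molecular_rmsd(conf_a: RigidMolecule, conf_b: RigidMolecule) -> float:
    """All-atom RMSD (Å) after optimal rigid (proper) superposition.

    Atom ordering defines the correspondence; both conformers must have the
    same atom count.  Improper operations are excluded, so an enantiomer pair
    of a chiral molecule yields a nonzero RMSD.
    """
    if conf_a.n_atoms != conf_b.n_atoms:
        raise ValueError(
            f"atom-count mismatch: {conf_a.n_atoms} vs {conf_b.n_atoms}"
        )
    return kabsch_rmsd(conf_a.positions, conf_b.positions)


def kabsch_rmsd(xa: np.ndarray, xb: np.ndarray) -> float:
    """Least-squares RMSD of two (n,3) coordinate sets under proper rotation
    + translation, with fixed row correspondence."""
    xa = np.asarray(xa, float)
    xb = np.asarray(xb, float)
    a = xa - xa.mean(axis=0)
    b = xb - xb.mean(axis=0)
    with warnings.catch_warnings():
        # linear/planar sets make the optimal rotation non-unique; any
        # optimal one gives the same RMSD
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(a, b)
    d = a - rot.apply(b)
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def kabsch_rotation(xa: np.ndarray, xb: np.ndarray) -> Rotation:
    """Proper rotation best aligning centred ``xb`` onto centred ``xa``."""
    a = np.asarray(xa, float)
    b = np.asarray(xb, float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(a - a.mean(axis=0), b - b.mean(axis=0))
    return rot


def mirror_image(mol: RigidMolecule) -> RigidMolecule:
    """Enantiomer of a molecule: inversion through the origin.

    Dipoles change sign (odd parity); quadrupoles are unchanged (even
    parity).  The stereo label, when present, is toggled R↔S.
    """
    swap = {"R": "S", "S": "R"}
    label = mol.stereo_label
    if label is not None:
        label = swap.get(label, label + "*")
    return mol.with_positions(
        -mol.positions,
        multipoles=mol.multipoles.inverted(),
        stereo_label=label,
    )


def load_force_field(path, rules=("geometric", "arithmetic", "geometric")) -> ForceField:
    """Read a plain-text parameter file: one ``label A B C`` record per line.

    ``#`` starts a comment; blank lines are ignored.
    """
    params = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 'label A B C'")
            label, a, b, c = parts
            params[label] = PairParams(float(a), float(b), float(c))
    return ForceField(params, rules)


def write_molecule_xyz(mol: RigidMolecule, path) -> None:
    """Extended-XYZ-style molecule file: ``element x y z ff_type charge``
    with an optional trailing multipole block (see :func:`load_molecule_xyz`)."""
    lines = [str(mol.n_atoms), f"{mol.name} chiral={int(mol.is_chiral)}"]
    for a in mol.atoms:
        x, y, z = a.position
        lines.append(
            f"{a.element} {x:.10f} {y:.10f} {z:.10f} {a.ff_type} {a.charge:.6f}"
        )
    mp = mol.multipoles
    if mp.rank >= 1:
        lines.append("multipoles cartesian")
        for i in range(mol.n_atoms):
            d = mp.dipoles[i]
            q = mp.quadrupoles[i]
            comps = list(d) + [q[0, 0], q[1, 1], q[2, 2], q[0, 1], q[0, 2], q[1, 2]]
            lines.append(f"{i} " + " ".join(f"{v:.10f}" for v in comps))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_molecule_xyz(path) -> RigidMolecule:
    """Read the extended-XYZ molecule format written by
    :func:`write_molecule_xyz`.

    Multipole block lines are ``index dx dy dz Qxx Qyy Qzz Qxy Qxz Qyz``
    (Cartesian, e·Å and e·Å²)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    n = int(lines[0].split()[0])
    header = lines[1].split()
    name = header[0] if header else "molecule"
    chiral = any(tok == "chiral=1" for tok in header)
    atoms = []
    for ln in lines[2 : 2 + n]:
        parts = ln.split()
        el, x, y, z, ff_type, charge = parts[:6]
        atoms.append(Atom(el, (float(x), float(y), float(z)), ff_type, float(charge)))
    multipoles = None
    rest = [ln for ln in lines[2 + n :] if ln.strip()]
    if rest and rest[0].startswith("multipoles"):
        nn = len(atoms)
        dip = np.zeros((nn, 3))
        quad = np.zeros((nn, 3, 3))
        for ln in rest[1:]:
            parts = [float(v) for v in ln.split()]
            i = int(parts[0])
            dip[i] = parts[1:4]
            qxx, qyy, qzz, qxy, qxz, qyz = parts[4:10]
            quad[i] = [[qxx, qxy, qxz], [qxy, qyy, qyz], [qxz, qyz, qzz]]
        charges = np.array([a.charge for a in atoms])
        multipoles = MultipoleSet(charges, dip, quad)
    return RigidMolecule(name, atoms, multipoles, is_chiral=chiral)
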