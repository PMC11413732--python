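"""Space-group machinery for Z′ = 1 crystal structure prediction.

A bundled registry covers the space groups most commonly adopted by small
organic molecules (the CSD top-20 plus P1); any other group can be added by
international number / Hermann–Mauguin symbol (operators come from gemmi's
ITA tables, standard settings) or loaded from a plain-text operation table.

Each symmetry image carries a parity flag (determinant of the rotation
part) so that chirality bookkeeping — which images are the mirror
enantiomer — is explicit downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import gemmi
import numpy as np

__all__ = [
    "cell_matrix",
    "SymOp",
    "SpaceGroup",
    "Cell",
    "Placement",
    "registry",
    "spacegroup",
    "is_sohncke",
    "constrain_cell",
    "free_cell_params",
    "cell_from_free_params",
    "expand_to_cell",
    "load_group_table",
    "DEFAULT_GROUP_SYMBOLS",
    "CellConstraintError",
]

# CSD top-20 space groups for small organic molecules, plus P1 (already in
# the list).  User-extensible via ``spacegroup``/``load_group_table``.
DEFAULT_GROUP_SYMBOLS = [
    "P21/c", "P-1", "P212121", "C2/c", "P21", "Pbca", "Pna21", "Cc", "P1",
    "Pca21", "C2", "Pbcn", "P21/m", "Pc", "P2/c", "Fdd2", "R-3", "Pnma",
    "C2/m", "I41/a",
]


class CellConstraintError(ValueError):
    """Cell parameters violate the crystal-system constraints."""


@dataclass(frozen=True)
class SymOp:
    """One symmetry operation in fractional coordinates: x → rot·x + tran."""

    rot: tuple  # 3×3 nested tuple
    tran: tuple  # length 3

    @property
    def rot_array(self) -> np.ndarray:
        return np.array(self.rot, dtype=float)

    @property
    def tran_array(self) -> np.ndarray:
        return np.array(self.tran, dtype=float)

    @property
    def det(self) -> int:
        return int(round(np.linalg.det(self.rot_array)))

    def apply(self, frac: np.ndarray) -> np.ndarray:
        return frac @ self.rot_array.T + self.tran_array


@dataclass(frozen=True)
class SpaceGroup:
    number: int
    symbol: str
    operations: tuple[SymOp, ...]
    crystal_system: str
    sohncke: bool
    multiplicity: int

    def __post_init__(self):
        if self.multiplicity != len(self.operations):
            raise ValueError("multiplicity must equal the operation count")


def _from_gemmi(sg: gemmi.SpaceGroup) -> SpaceGroup:
    den = float(gemmi.Op.DEN)
    ops = []
    for op in sg.operations():
        rot = tuple(tuple(v / den for v in row) for row in op.rot)
        tran = tuple((t / den) % 1.0 for t in op.tran)
        ops.append(SymOp(rot, tran))
    # identity first (stable convention for "the" asymmetric unit)
    ops.sort(key=lambda o: 0 if (np.allclose(o.rot_array, np.eye(3)) and np.allclose(o.tran_array, 0)) else 1)
    sohncke = all(o.det == 1 for o in ops)
    short = sg.short_name()
    if short.startswith("H"):  # gemmi's alias for rhombohedral groups on hexagonal axes
        short = sg.hm.replace(" ", "")
    return SpaceGroup(
        number=sg.number,
        symbol=short,
        operations=tuple(ops),
        crystal_system=sg.crystal_system_str(),
        sohncke=sohncke,
        multiplicity=len(ops),
    )


def spacegroup(key) -> SpaceGroup:
    """Look up a space group by H-M symbol or international number."""
    if isinstance(key, SpaceGroup):
        return key
    if isinstance(key, int):
        sg = gemmi.find_spacegroup_by_number(key)
    else:
        sg = gemmi.find_spacegroup_by_name(str(key))
    if sg is None:
        raise KeyError(f"unknown space group {key!r}")
    return _from_gemmi(sg)


def registry(default: bool = True, symbols=None) -> list[SpaceGroup]:
    """The bundled space-group registry (or a custom symbol list)."""
    syms = DEFAULT_GROUP_SYMBOLS if default and symbols is None else list(symbols or [])
    return [spacegroup(s) for s in syms]


def is_sohncke(group: SpaceGroup) -> bool:
    """True iff every operation is proper (det = +1): the groups an
    enantiopure crystal can adopt."""
    return all(op.det == 1 for op in group.operations)


def load_group_table(path) -> list[SpaceGroup]:
    """Load space groups from a plain-text table.

    Format per group::

        group <number> <symbol>
        x,y,z
        -x,y+1/2,-z+1/2
        ...
    """
    groups = []
    current = None
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("group"):
                if current is not None:
                    groups.append(_finish_group(*current))
                _, num, sym = line.split()
                current = (int(num), sym, [])
            else:
                if current is None:
                    raise ValueError("operation line before any 'group' header")
                current[2].append(line)
    if current is not None:
        groups.append(_finish_group(*current))
    return groups


def _finish_group(number: int, symbol: str, triplets: list[str]) -> SpaceGroup:
    den = float(gemmi.Op.DEN)
    ops = []
    for trip in triplets:
        op = gemmi.Op(trip)
        rot = tuple(tuple(v / den for v in row) for row in op.rot)
        tran = tuple((t / den) % 1.0 for t in op.tran)
        ops.append(SymOp(rot, tran))
    ref = gemmi.find_spacegroup_by_number(number)
    system = ref.crystal_system_str() if ref is not None else "triclinic"
    sohncke = all(o.det == 1 for o in ops)
    return SpaceGroup(number, symbol, tuple(ops), system, sohncke, len(ops))


def cell_matrix(a: float, b: float, c: float,
                alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Lattice-vector rows for cell lengths (Å) and angles (degrees),
    in the standard orientation (a along x, b in the xy-plane)."""
    al, be, ga = math.radians(alpha), math.radians(beta), math.radians(gamma)
    ca, cb, cg = math.cos(al), math.cos(be), math.cos(ga)
    sg = math.sin(ga)
    cx = c * cb
    cy = c * (ca - cb * cg) / sg
    cz2 = c * c - cx * cx - cy * cy
    if cz2 <= 0:
        raise ValueError("degenerate cell (non-positive volume)")
    return np.array([
        [a, 0.0, 0.0],
        [b * cg, b * sg, 0.0],
        [cx, cy, math.sqrt(cz2)],
    ])


@dataclass(frozen=True)
class Cell:
    """Unit cell: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0°, 180°)")

    @property
    def matrix(self) -> np.ndarray:
        """Lattice vectors as rows; Cartesian = fractional @ matrix."""
        return cell_matrix(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.matrix)))


_SYSTEM_FREE = {
    "triclinic": ("a", "b", "c", "alpha", "beta", "gamma"),
    "monoclinic": ("a", "b", "c", "beta"),
    "orthorhombic": ("a", "b", "c"),
    "tetragonal": ("a", "c"),
    "trigonal": ("a", "c"),
    "hexagonal": ("a", "c"),
    "cubic": ("a",),
}


def free_cell_params(group: SpaceGroup) -> tuple[str, ...]:
    """Names of the cell parameters free to vary in this crystal system."""
    return _SYSTEM_FREE[group.crystal_system]


def constrain_cell(group: SpaceGroup, raw: Cell) -> Cell:
    """Project a cell onto its crystal-system constraints (idempotent).

    Monoclinic uses the b-unique setting (α = γ = 90°); trigonal groups use
    the hexagonal-axes setting.
    """
    s = group.crystal_system
    if s == "triclinic":
        return raw
    if s == "monoclinic":
        return Cell(raw.a, raw.b, raw.c, 90.0, raw.beta, 90.0)
    if s == "orthorhombic":
        return Cell(raw.a, raw.b, raw.c, 90.0, 90.0, 90.0)
    if s == "tetragonal":
        return Cell(raw.a, raw.a, raw.c, 90.0, 90.0, 90.0)
    if s in ("trigonal", "hexagonal"):
        return Cell(raw.a, raw.a, raw.c, 90.0, 90.0, 120.0)
    if s == "cubic":
        return Cell(raw.a, raw.a, raw.a, 90.0, 90.0, 90.0)
    raise ValueError(f"unknown crystal system {s!r}")


def cell_from_free_params(group: SpaceGroup, values) -> Cell:
    """Inverse of the free-parameter projection used by sampler/minimiser."""
    names = free_cell_params(group)
    if len(values) != len(names):
        raise ValueError(f"expected {len(names)} free cell parameters")
    kw = dict(zip(names, (float(v) for v in values)))
    base = Cell(
        kw.get("a", 1.0),
        kw.get("b", kw.get("a", 1.0)),
        kw.get("c", kw.get("a", 1.0)),
        kw.get("alpha", 90.0),
        kw.get("beta", 90.0),
        kw.get("gamma", 90.0),
    )
    return constrain_cell(group, base)


def _check_cell(group: SpaceGroup, cell: Cell) -> None:
    ref = constrain_cell(group, cell)
    if not np.allclose(
        [cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma],
        [ref.a, ref.b, ref.c, ref.alpha, ref.beta, ref.gamma],
        atol=1e-8,
    ):
        raise CellConstraintError(
            f"cell {cell} violates {group.crystal_system} constraints for {group.symbol}"
        )


@dataclass(frozen=True)
class Placement:
    """Position + orientation of the single asymmetric-unit molecule.

    ``centroid`` is fractional in [0,1)³; ``quaternion`` is a unit
    quaternion in scipy (x, y, z, w) order.
    """

    centroid: tuple[float, float, float]
    quaternion: tuple[float, float, float, float]

    def __post_init__(self):
        q = np.asarray(self.quaternion, float)
        n = np.linalg.norm(q)
        if not np.isfinite(n) or n == 0:
            raise ValueError("invalid quaternion")
        object.__setattr__(self, "quaternion", tuple(q / n))
        object.__setattr__(
            self, "centroid", tuple(float(x) % 1.0 for x in self.centroid)
        )

    @property
    def rotation(self):
        from scipy.spatial.transform import Rotation

        return Rotation.from_quat(np.asarray(self.quaternion))


@dataclass(frozen=True)
class MoleculeImage:
    """One symmetry copy of the molecule: Cartesian coordinates plus the
    parity (handedness) of the generating operation."""

    cart: np.ndarray       # (n_atoms, 3)
    frac: np.ndarray       # (n_atoms, 3)
    parity: int            # ±1
    op_index: int
    cart_rot: np.ndarray   # 3×3 Cartesian rotation of the op (for multipoles)


def expand_to_cell(group: SpaceGroup, cell: Cell, mol, placement: Placement,
                   check: bool = True) -> list[MoleculeImage]:
    """Generate all symmetry images of the placed molecule in the unit cell.

    Images are produced by applying each fractional-space operation to the
    placed molecule; improper operations yield the mirror enantiomer
    (parity −1).  Atom ordering is preserved in every image, and each image
    is wrapped so its centroid lies in [0,1)³.
    """
    if check:
        _check_cell(group, cell)
    M = cell.matrix
    Minv = np.linalg.inv(M)
    local = mol.local_coords
    cart0 = placement.rotation.apply(local)
    frac0 = np.asarray(placement.centroid) + cart0 @ Minv
    images = []
    for k, op in enumerate(group.operations):
        frac = op.apply(frac0)
        cen = frac.mean(axis=0)
        frac = frac + (cen % 1.0 - cen)
        cart = frac @ M
        cart_rot = M.T @ op.rot_array @ Minv.T
        images.append(
            MoleculeImage(cart=cart, frac=frac, parity=op.det, op_index=k,
                          cart_rot=cart_rot)
        )
    return images
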