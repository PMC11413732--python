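"""File formats: CIF for single crystal structures, JSON-lines for
landscapes, YAML-ish run configuration, and a content hash for
reproducibility checks.

The JSON-lines landscape format is self-contained: a header record embeds
the molecule definition (atoms, types, charges, multipoles), so a
landscape file round-trips losslessly without external inputs.  CIF files
carry the cell, the symmetry operations and the asymmetric-unit atom
sites (with nonstandard ``_atom_site_ff_type`` / ``_atom_site_charge``
columns so the force-field typing survives the round trip).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import gemmi
import numpy as np
import yaml

from .chem import Atom, MultipoleSet, RigidMolecule
from .crystal import MinimizedCrystal, TrialCrystal
from .energy import EnergyBreakdown
from .symmetry import (Cell, Placement, SpaceGroup, SymOp, spacegroup)

__all__ = [
    "write_cif",
    "read_cif",
    "write_landscape",
    "read_landscape",
    "load_config",
    "config_hash",
    "FormatError",
]

_ENERGY_DECIMALS = 4   # energies are reported to 10⁻⁴ kJ/mol
_GEOM_DECIMALS = 8


class FormatError(ValueError):
    """Malformed structure or landscape file."""


# ---------------------------------------------------------------------------
# CIF


def write_cif(crystal, path) -> None:
    """Write a crystal (cell + symmetry + asymmetric unit) as CIF."""
    cell = crystal.cell
    group = crystal.group
    mol = crystal.molecule
    Minv = np.linalg.inv(cell.matrix)
    images = crystal.images(check=False)
    frac = images[0].frac
    lines = [
        f"data_{getattr(crystal, 'structure_id', 'crystal')}",
        f"_cell_length_a    {cell.a:.8f}",
        f"_cell_length_b    {cell.b:.8f}",
        f"_cell_length_c    {cell.c:.8f}",
        f"_cell_angle_alpha {cell.alpha:.8f}",
        f"_cell_angle_beta  {cell.beta:.8f}",
        f"_cell_angle_gamma {cell.gamma:.8f}",
        f"_symmetry_space_group_name_H-M '{group.symbol}'",
        f"_space_group_IT_number {group.number}",
        "loop_",
        "_symmetry_equiv_pos_as_xyz",
    ]
    for op in group.operations:
        g = gemmi.Op()
        g.rot = [[int(round(v * gemmi.Op.DEN)) for v in row] for row in op.rot]
        g.tran = [int(round(t * gemmi.Op.DEN)) for t in op.tran]
        lines.append(f"  '{g.triplet()}'")
    lines += [
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
        "_atom_site_ff_type",
        "_atom_site_charge",
    ]
    for k, (a, f) in enumerate(zip(mol.atoms, frac)):
        lines.append(
            f"{a.element}{k + 1} {a.element} {f[0]:.8f} {f[1]:.8f} {f[2]:.8f} "
            f"{a.ff_type} {a.charge:.6f}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _ops_key(ops) -> frozenset:
    out = []
    for op in ops:
        r = tuple(np.round(np.asarray(op.rot, float), 6).ravel())
        t = tuple(np.round(np.asarray(op.tran, float) % 1.0, 6))
        out.append((r, t))
    return frozenset(out)


def _group_from_ops(ops: list[SymOp]) -> SpaceGroup:
    """Reconstruct a registered space group by operation-set matching."""
    key = _ops_key(ops)
    for num in range(1, 231):
        try:
            g = spacegroup(num)
        except KeyError:
            continue
        if _ops_key(g.operations) == key:
            return g
    # unknown setting: build an ad-hoc group
    sohncke = all(
        int(round(np.linalg.det(np.asarray(op.rot, float)))) == 1 for op in ops
    )
    return SpaceGroup(0, "custom", tuple(ops), "triclinic", sohncke, len(ops))


def read_cif(path) -> TrialCrystal:
    """Read a CIF structure (cell, symmetry, asymmetric-unit molecule).

    The space group comes from the H-M symbol when present, otherwise by
    matching the listed operations against the bundled tables; a file with
    no symmetry information falls back to P1.
    """
    try:
        doc = gemmi.cif.read_file(str(path))
        block = doc.sole_block()
    except Exception as exc:
        raise FormatError(f"cannot parse CIF {path}: {exc}") from None

    def need(tag):
        v = block.find_value(tag)
        if v is None:
            raise FormatError(f"{path}: missing {tag}")
        return float(v)

    cell = Cell(
        need("_cell_length_a"), need("_cell_length_b"), need("_cell_length_c"),
        need("_cell_angle_alpha"), need("_cell_angle_beta"),
        need("_cell_angle_gamma"),
    )
    symbol = block.find_value("_symmetry_space_group_name_H-M") or \
        block.find_value("_space_group_name_H-M_alt")
    group = None
    if symbol:
        try:
            group = spacegroup(symbol.strip("'\" "))
        except KeyError:
            group = None
    if group is None:
        trips = [row.str(0) for row in block.find(["_symmetry_equiv_pos_as_xyz"])]
        if trips:
            den = float(gemmi.Op.DEN)
            ops = []
            for trip in trips:
                op = gemmi.Op(trip)
                ops.append(SymOp(
                    tuple(tuple(v / den for v in row) for row in op.rot),
                    tuple((t / den) % 1.0 for t in op.tran),
                ))
            group = _group_from_ops(ops)
        else:
            group = spacegroup("P1")

    table = block.find(["_atom_site_type_symbol", "_atom_site_fract_x",
                        "_atom_site_fract_y", "_atom_site_fract_z"])
    if not table:
        raise FormatError(f"{path}: no atom sites")
    ff_col = block.find(["_atom_site_ff_type"])
    q_col = block.find(["_atom_site_charge"])
    atoms = []
    M = cell.matrix
    fracs = []
    for i, row in enumerate(table):
        el = row.str(0)
        f = np.array([float(row.str(1)), float(row.str(2)), float(row.str(3))])
        fracs.append(f)
        cart = f @ M
        ff = ff_col[i].str(0) if ff_col else el
        q = float(q_col[i].str(0)) if q_col else 0.0
        atoms.append(Atom(el, tuple(cart), ff, q))
    mol = RigidMolecule(str(path), atoms)
    centroid = np.mean(fracs, axis=0) % 1.0
    placement = Placement(tuple(centroid), (0.0, 0.0, 0.0, 1.0))
    return TrialCrystal(group, cell, placement, mol)


# ---------------------------------------------------------------------------
# landscape JSON-lines


def _molecule_record(mol: RigidMolecule) -> dict:
    rec = {
        "name": mol.name,
        "is_chiral": mol.is_chiral,
        "stereo_label": mol.stereo_label,
        "atoms": [
            {
                "element": a.element,
                "xyz": [round(x, _GEOM_DECIMALS) for x in a.position],
                "ff_type": a.ff_type,
                "charge": a.charge,
            }
            for a in mol.atoms
        ],
    }
    mp = mol.multipoles
    if mp.rank >= 1:
        rec["dipoles"] = np.round(mp.dipoles, 10).tolist()
        rec["quadrupoles"] = np.round(mp.quadrupoles, 10).tolist()
    return rec


def _molecule_from_record(rec: dict) -> RigidMolecule:
    atoms = [
        Atom(a["element"], tuple(a["xyz"]), a["ff_type"], a["charge"])
        for a in rec["atoms"]
    ]
    multipoles = None
    if "dipoles" in rec:
        charges = np.array([a.charge for a in atoms])
        multipoles = MultipoleSet(charges, np.array(rec["dipoles"]),
                                  np.array(rec["quadrupoles"]))
    return RigidMolecule(rec["name"], atoms, multipoles,
                         is_chiral=rec.get("is_chiral", False),
                         stereo_label=rec.get("stereo_label"))


_STRUCT_KEYS = {"record", "id", "group", "group_number", "cell", "centroid",
                "quaternion", "e_latt", "e_repdisp", "e_elec", "density",
                "converged", "sohncke", "n_steps", "index", "seed", "cluster"}


def write_landscape(structures, path, molecule: RigidMolecule | None = None,
                    labels=None) -> None:
    """Write minimised structures as JSON-lines (header + one record per
    structure), sorted by lattice energy."""
    structures = sorted(structures, key=lambda s: s.e_latt)
    if molecule is None and structures:
        molecule = structures[0].molecule
    if molecule is None:
        raise ValueError("an empty landscape still needs a molecule")
    with open(path, "w") as fh:
        header = {
            "record": "landscape",
            "schema": 1,
            "molecule": _molecule_record(molecule),
            "n_structures": len(structures),
        }
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for i, s in enumerate(structures):
            rec = {
                "record": "structure",
                "id": s.structure_id,
                "group": s.group.symbol,
                "group_number": s.group.number,
                "cell": [round(v, _GEOM_DECIMALS) for v in
                         (s.cell.a, s.cell.b, s.cell.c,
                          s.cell.alpha, s.cell.beta, s.cell.gamma)],
                "centroid": [round(v, _GEOM_DECIMALS) for v in s.placement.centroid],
                "quaternion": [round(v, _GEOM_DECIMALS) for v in s.placement.quaternion],
                "e_latt": round(s.energy.E_latt, _ENERGY_DECIMALS),
                "e_repdisp": round(s.energy.E_repdisp, _ENERGY_DECIMALS),
                "e_elec": round(s.energy.E_elec, _ENERGY_DECIMALS),
                "density": round(s.density, 6),
                "converged": bool(s.converged),
                "sohncke": bool(s.group.sohncke),
                "n_steps": int(s.n_steps),
                "index": int(s.index),
                "seed": int(s.seed),
            }
            if labels is not None:
                rec["cluster"] = int(labels[i])
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_landscape(path) -> tuple[RigidMolecule, list[MinimizedCrystal]]:
    """Read a JSON-lines landscape; structures come back sorted by energy."""
    structures = []
    molecule = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}:{lineno}: invalid JSON: {exc}") from None
            kind = rec.get("record")
            if kind == "landscape":
                molecule = _molecule_from_record(rec["molecule"])
            elif kind == "structure":
                if molecule is None:
                    raise FormatError(f"{path}:{lineno}: structure before header")
                unknown = set(rec) - _STRUCT_KEYS
                if unknown:
                    raise FormatError(
                        f"{path}:{lineno}: unknown fields {sorted(unknown)}"
                    )
                for fld in ("group", "cell", "centroid", "quaternion", "e_latt"):
                    if fld not in rec:
                        raise FormatError(f"{path}:{lineno}: missing field {fld!r}")
                group = spacegroup(rec["group"])
                a, b, c, al, be, ga = rec["cell"]
                cell = Cell(a, b, c, al, be, ga)
                placement = Placement(tuple(rec["centroid"]),
                                      tuple(rec["quaternion"]))
                energy = EnergyBreakdown(rec["e_repdisp"], rec["e_elec"])
                structures.append(MinimizedCrystal(
                    group=group, cell=cell, placement=placement,
                    molecule=molecule, energy=energy,
                    density=rec["density"], converged=rec["converged"],
                    n_steps=rec.get("n_steps", 0),
                    index=rec.get("index", 0), seed=rec.get("seed", 0),
                ))
            else:
                raise FormatError(f"{path}:{lineno}: unknown record {kind!r}")
    if molecule is None:
        raise FormatError(f"{path}: missing landscape header")
    structures.sort(key=lambda s: s.e_latt)
    return molecule, structures


def write_trials(trials, path, molecule: RigidMolecule | None = None) -> None:
    """Write trial (pre-minimisation) crystals as JSON-lines."""
    if molecule is None and trials:
        molecule = trials[0].molecule
    if molecule is None:
        raise ValueError("an empty trial set still needs a molecule")
    with open(path, "w") as fh:
        fh.write(json.dumps({
            "record": "trials", "schema": 1,
            "molecule": _molecule_record(molecule), "n_structures": len(trials),
        }, sort_keys=True) + "\n")
        for t in trials:
            fh.write(json.dumps({
                "record": "trial",
                "group": t.group.symbol,
                "cell": [round(v, _GEOM_DECIMALS) for v in
                         (t.cell.a, t.cell.b, t.cell.c,
                          t.cell.alpha, t.cell.beta, t.cell.gamma)],
                "centroid": [round(v, _GEOM_DECIMALS) for v in t.placement.centroid],
                "quaternion": [round(v, _GEOM_DECIMALS) for v in t.placement.quaternion],
                "index": int(t.index),
                "seed": int(t.seed),
            }, sort_keys=True) + "\n")


def read_trials(path) -> tuple[RigidMolecule, list[TrialCrystal]]:
    molecule = None
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            rec = json.loads(line)
            if rec.get("record") == "trials":
                molecule = _molecule_from_record(rec["molecule"])
            elif rec.get("record") == "trial":
                if molecule is None:
                    raise FormatError(f"{path}:{lineno}: trial before header")
                a, b, c, al, be, ga = rec["cell"]
                out.append(TrialCrystal(
                    spacegroup(rec["group"]), Cell(a, b, c, al, be, ga),
                    Placement(tuple(rec["centroid"]), tuple(rec["quaternion"])),
                    molecule, index=rec.get("index", 0), seed=rec.get("seed", 0),
                ))
            else:
                raise FormatError(f"{path}:{lineno}: unknown record")
    if molecule is None:
        raise FormatError(f"{path}: missing trials header")
    return molecule, out


# ---------------------------------------------------------------------------
# configuration

_CONFIG_SECTIONS = {"sampler", "energy", "schedule", "compare", "analysis",
                    "ml", "seed", "log_level"}


def load_config(path) -> dict:
    """Load a YAML run configuration; unknown top-level keys are rejected."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError("configuration must be a mapping")
    unknown = set(cfg) - _CONFIG_SECTIONS
    if unknown:
        raise FormatError(f"unknown configuration sections: {sorted(unknown)}")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable hash of a configuration (key order irrelevant)."""
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, separators=(",", ":")).encode()
    ).hexdigest()[:16]
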