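"""Crystal containers: a trial (sampled) crystal and a minimised crystal.

A crystal is a space group, a unit cell and a single asymmetric-unit
placement of a rigid molecule (Z′ = 1); everything else in the cell is
generated by symmetry.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .chem import RigidMolecule
from .symmetry import Cell, Placement, SpaceGroup, expand_to_cell

__all__ = ["TrialCrystal", "MinimizedCrystal", "density_g_cm3"]

# 1 / (N_A × 1 Å³ in cm³) with masses in g mol⁻¹  →  ρ = Z·M / (0.602214·V)
_AVOGADRO_A3 = 0.602214076


def density_g_cm3(molecule: RigidMolecule, group: SpaceGroup, cell: Cell) -> float:
    """Crystal density, g cm⁻³, for Z = group multiplicity whole molecules."""
    return group.multiplicity * molecule.mass / (_AVOGADRO_A3 * cell.volume)


@dataclass(frozen=True)
class TrialCrystal:
    """A quasi-randomly generated trial packing (pre-minimisation)."""

    group: SpaceGroup
    cell: Cell
    placement: Placement
    molecule: RigidMolecule
    index: int = 0      # low-discrepancy sequence index
    seed: int = 0       # sampler seed

    def images(self, check: bool = True):
        return expand_to_cell(self.group, self.cell, self.molecule,
                              self.placement, check=check)

    @property
    def structure_id(self) -> str:
        h = hashlib.sha256()
        h.update(self.group.symbol.encode())
        arr = np.array(
            [self.cell.a, self.cell.b, self.cell.c, self.cell.alpha,
             self.cell.beta, self.cell.gamma,
             *self.placement.centroid, *self.placement.quaternion],
            dtype=float,
        )
        h.update(np.round(arr, 8).tobytes())
        h.update(self.molecule.name.encode())
        return h.hexdigest()[:16]

    def replace(self, **kw) -> "TrialCrystal":
        return replace(self, **kw)


@dataclass(frozen=True)
class MinimizedCrystal:
    """A locally lattice-energy-minimised crystal structure."""

    group: SpaceGroup
    cell: Cell
    placement: Placement
    molecule: RigidMolecule
    energy: object                # EnergyBreakdown
    density: float                # g cm⁻³
    converged: bool
    n_steps: int = 0
    stage_history: tuple = ()
    index: int = 0
    seed: int = 0

    def images(self, check: bool = True):
        return expand_to_cell(self.group, self.cell, self.molecule,
                              self.placement, check=check)

    @property
    def e_latt(self) -> float:
        return self.energy.E_latt

    @property
    def sohncke(self) -> bool:
        return self.group.sohncke

    @property
    def structure_id(self) -> str:
        return TrialCrystal(
            self.group, self.cell, self.placement, self.molecule,
            self.index, self.seed,
        ).structure_id

    def replace(self, **kw) -> "MinimizedCrystal":
        return replace(self, **kw)
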