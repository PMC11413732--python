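"""Symmetry-constrained rigid-body lattice-energy minimisation.

Only the free variables of the packing are optimised: the crystal-system
free cell parameters (6/4/3/… for triclinic/monoclinic/orthorhombic/…),
the fractional centroid of the asymmetric-unit molecule, and its
orientation (a 3-parameter rotation update composed onto the quaternion).
Space-group symmetry is therefore preserved exactly by construction.

Minimisation is staged: early stages use charges-only electrostatics and
coarse cutoffs, the final stage the configured multipole rank and the
tightest tolerances, mirroring the usual staged CSP refinement.  The
optimiser is bounded L-BFGS-B with finite-difference gradients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial.transform import Rotation

from .chem import ForceField
from .crystal import MinimizedCrystal, TrialCrystal, density_g_cm3
from .energy import ClashError, EnergySettings, LatticeEnergyEvaluator
from .symmetry import (Cell, Placement, cell_from_free_params, cell_matrix,
                       constrain_cell, free_cell_params)

__all__ = [
    "Stage",
    "StageSchedule",
    "MinimizationDiverged",
    "minimize_stage",
    "run_schedule",
    "default_schedule",
    "toy_schedule",
]

_PENALTY = 1.0e6


class MinimizationDiverged(RuntimeError):
    """Cell collapse/explosion during minimisation; structure discarded."""


@dataclass(frozen=True)
class Stage:
    """One stage of the minimisation schedule."""

    name: str
    rank: int
    cutoff: float
    elec_cutoff: float
    ftol: float
    gtol: float
    maxiter: int
    fd_step: float = 1e-4       # finite-difference step in scaled coordinates

    def settings(self, base: EnergySettings) -> EnergySettings:
        # the Ewald split is kept at the base real-space cutoff across
        # stages: the reciprocal grid stays small and the split-dependent
        # constants stay precomputable
        return replace(
            base,
            rank=self.rank,
            cutoff=self.cutoff,
            elec_cutoff=self.elec_cutoff,
        )


@dataclass(frozen=True)
class StageSchedule:
    stages: tuple[Stage, ...]
    vol_floor: float = 2.0      # Å³ per atom in the cell — below ⇒ collapse
    vol_ceiling: float = 2000.0  # Å³ per atom — above ⇒ explosion

    def __post_init__(self):
        if not self.stages:
            raise ValueError("schedule needs at least one stage")
        ftols = [s.ftol for s in self.stages]
        if any(b > a for a, b in zip(ftols, ftols[1:])):
            raise ValueError("stage tolerances must tighten down the schedule")


def default_schedule(rank: int = 2) -> StageSchedule:
    """The default three-stage schedule: charges-only coarse, charges-only
    production, then full multipole rank at the tightest tolerance."""
    return StageSchedule((
        Stage("coarse", rank=0, cutoff=8.0, elec_cutoff=8.0,
              ftol=1e-5, gtol=5e-2, maxiter=60),
        Stage("production", rank=0, cutoff=12.0, elec_cutoff=12.0,
              ftol=1e-7, gtol=1e-2, maxiter=120),
        Stage("multipole", rank=rank, cutoff=15.0, elec_cutoff=15.0,
              ftol=1e-9, gtol=5e-3, maxiter=200),
    ))


def toy_schedule(rank: int = 0) -> StageSchedule:
    """A faster two-stage schedule sized for small toy systems."""
    return StageSchedule((
        Stage("coarse", rank=0, cutoff=6.0, elec_cutoff=6.0,
              ftol=1e-5, gtol=1e-1, maxiter=40),
        Stage("fine", rank=rank, cutoff=9.0, elec_cutoff=9.0,
              ftol=1e-9, gtol=2e-3, maxiter=150),
    ))


def polish_stage(rank: int = 0) -> Stage:
    """An extra tight final stage used when planting reference minima."""
    return Stage("polish", rank=rank, cutoff=9.0, elec_cutoff=9.0,
                 ftol=1e-12, gtol=1e-3, maxiter=250, fd_step=5e-5)


def _quat_from_rotvec(w: np.ndarray) -> np.ndarray:
    th = math.sqrt(w[0] * w[0] + w[1] * w[1] + w[2] * w[2])
    if th < 1e-14:
        return np.array([0.5 * w[0], 0.5 * w[1], 0.5 * w[2], 1.0])
    s = math.sin(0.5 * th) / th
    return np.array([w[0] * s, w[1] * s, w[2] * s, math.cos(0.5 * th)])


def _quat_mul(q1, q2) -> np.ndarray:
    """Hamilton product in scipy (x, y, z, w) order: rotation q2 then q1."""
    x1, y1, z1, w1 = q1
    x2, y2, z2, w2 = q2
    return np.array([
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
    ])


class _Parameterisation:
    """Maps (cell, placement) to and from the scaled optimisation vector.

    Scales convert every coordinate to a comparable Å-like arc length, so a
    single finite-difference step is meaningful for all of them.
    """

    def __init__(self, group, molecule, cell0: Cell, placement0: Placement):
        self.group = group
        self.system = group.crystal_system
        self.free_names = free_cell_params(group)
        self.angle_names = {"alpha", "beta", "gamma"}
        self.len_scale = 1.0
        self.ang_scale = math.radians(1.0) * (cell0.a + cell0.b + cell0.c) / 3.0
        self.frac_scale = (cell0.a + cell0.b + cell0.c) / 3.0
        self.rot_scale = max(molecule.radius, 1.0)
        self.base_quat = np.asarray(placement0.quaternion)
        self._cell0 = cell0

    def pack(self, cell: Cell, placement: Placement) -> np.ndarray:
        vals = []
        for name in self.free_names:
            v = getattr(cell, name)
            vals.append(v * (self.ang_scale if name in self.angle_names else self.len_scale))
        vals.extend(np.asarray(placement.centroid) * self.frac_scale)
        vals.extend([0.0, 0.0, 0.0])  # rotation update, composed onto base_quat
        return np.array(vals, dtype=float)

    def unpack_raw(self, x: np.ndarray):
        """(a,b,c,α,β,γ), centroid, quaternion — no container objects."""
        nf = len(self.free_names)
        kw = {}
        for name, v in zip(self.free_names, x[:nf]):
            kw[name] = v / (self.ang_scale if name in self.angle_names else self.len_scale)
        a = kw["a"]
        s = self.system
        if s == "triclinic":
            c6 = (a, kw["b"], kw["c"], kw["alpha"], kw["beta"], kw["gamma"])
        elif s == "monoclinic":
            c6 = (a, kw["b"], kw["c"], 90.0, kw["beta"], 90.0)
        elif s == "orthorhombic":
            c6 = (a, kw["b"], kw["c"], 90.0, 90.0, 90.0)
        elif s == "tetragonal":
            c6 = (a, a, kw["c"], 90.0, 90.0, 90.0)
        elif s in ("trigonal", "hexagonal"):
            c6 = (a, a, kw["c"], 90.0, 90.0, 120.0)
        else:  # cubic
            c6 = (a, a, a, 90.0, 90.0, 90.0)
        cen = x[nf : nf + 3] / self.frac_scale
        w = x[nf + 3 :] / self.rot_scale
        quat = _quat_mul(_quat_from_rotvec(w), self.base_quat)
        quat = quat / np.linalg.norm(quat)
        return c6, cen, quat

    def unpack(self, x: np.ndarray) -> tuple[Cell, Placement]:
        c6, cen, quat = self.unpack_raw(x)
        return Cell(*c6), Placement(tuple(cen % 1.0), tuple(quat))

    def bounds(self):
        # lengths are bounded relative to the start: wild line-search steps
        # from very repulsive trial structures would otherwise explode the
        # cell long before the energy surface can guide it back
        b = []
        for name in self.free_names:
            if name in self.angle_names:
                b.append((45.0 * self.ang_scale, 135.0 * self.ang_scale))
            else:
                v0 = getattr(self._cell0, name)
                b.append((max(1.5, 0.4 * v0) * self.len_scale,
                          min(80.0, 2.5 * v0) * self.len_scale))
        b.extend([(-2.0 * self.frac_scale, 3.0 * self.frac_scale)] * 3)
        b.extend([(-np.pi * self.rot_scale, np.pi * self.rot_scale)] * 3)
        return b


def _objective_factory(par, evaluator):
    cache = {}

    def fun(x):
        key = x.tobytes()
        if key in cache:
            return cache[key]
        try:
            c6, cen, quat = par.unpack_raw(x)
            M = cell_matrix(*c6)
            e = evaluator.breakdown_raw(M, cen, quat).E_latt
        except (ClashError, ValueError):
            e = _PENALTY
        if not np.isfinite(e):
            e = _PENALTY
        cache[key] = e
        return e

    return fun, cache


def minimize_stage(start, stage: Stage, ff: ForceField,
                   settings: EnergySettings | None = None,
                   schedule: StageSchedule | None = None) -> MinimizedCrystal:
    """Quasi-Newton descent over the free packing variables for one stage.

    Returns a :class:`MinimizedCrystal`; raises
    :class:`MinimizationDiverged` on cell collapse or explosion.  Structures
    that hit the iteration cap are kept but flagged unconverged.
    """
    settings = settings or EnergySettings()
    schedule = schedule or StageSchedule((stage,))
    group, mol = start.group, start.molecule
    cell0 = constrain_cell(group, start.cell)
    par = _Parameterisation(group, mol, cell0, start.placement)
    evaluator = LatticeEnergyEvaluator(mol, group, ff, stage.settings(settings))
    fun, cache = _objective_factory(par, evaluator)
    x0 = par.pack(cell0, start.placement)

    accepted = []

    def callback(xk):
        accepted.append(cache.get(xk.tobytes(), np.nan))

    res = _scipy_minimize(
        fun, x0, method="L-BFGS-B", bounds=par.bounds(), callback=callback,
        options={
            "maxiter": stage.maxiter,
            "ftol": stage.ftol,
            "gtol": stage.gtol,
            "eps": stage.fd_step,
            "maxcor": 12,
        },
    )
    cell, placement = par.unpack(res.x)
    n_cell_atoms = group.multiplicity * mol.n_atoms
    vol_per_atom = cell.volume / n_cell_atoms
    if not (schedule.vol_floor <= vol_per_atom <= schedule.vol_ceiling):
        raise MinimizationDiverged(
            f"cell volume {cell.volume:.1f} Å³ out of bounds "
            f"({vol_per_atom:.2f} Å³/atom) at stage {stage.name!r}"
        )
    if res.fun >= _PENALTY:
        raise MinimizationDiverged(f"stage {stage.name!r} ended in a clash region")
    grad_ok = np.max(np.abs(res.jac)) <= 10.0 * stage.gtol
    converged = bool(res.success or grad_ok)
    breakdown = evaluator.breakdown(cell, placement)
    breakdown = replace(breakdown, converged=converged)
    history = {
        "stage": stage.name,
        "n_iter": int(res.nit),
        "energy": float(res.fun),
        "accepted_energies": tuple(float(v) for v in accepted),
        "converged": converged,
    }
    prior = start.stage_history if isinstance(start, MinimizedCrystal) else ()
    return MinimizedCrystal(
        group=group, cell=cell, placement=placement, molecule=mol,
        energy=breakdown, density=density_g_cm3(mol, group, cell),
        converged=converged,
        n_steps=(start.n_steps if isinstance(start, MinimizedCrystal) else 0) + int(res.nit),
        stage_history=prior + (history,),
        index=start.index, seed=start.seed,
    )


def run_schedule(start: TrialCrystal, schedule: StageSchedule | None = None,
                 ff: ForceField | None = None,
                 settings: EnergySettings | None = None) -> MinimizedCrystal:
    """Chain the stages of a schedule; the final energy is evaluated at the
    last stage's settings."""
    if ff is None:
        raise ValueError("a ForceField is required")
    settings = settings or EnergySettings()
    schedule = schedule or default_schedule(settings.rank)
    current = start
    for stage in schedule.stages:
        current = minimize_stage(current, stage, ff, settings, schedule)
    return current
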