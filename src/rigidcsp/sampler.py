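"""Quasi-random generation of geometrically sane trial crystals.

Packing variables — the crystal-system free cell parameters, the
fractional centroid and the molecular orientation — are drawn from a
scrambled Sobol low-discrepancy sequence, so that trial structures cover
the packing space far more uniformly than pseudo-random sampling.
Orientations use the Shoemake construction (three sequence dimensions →
uniform rotations).  Each candidate is screened by a vdW-overlap geometry
check before being accepted for minimisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import qmc

from .chem import RigidMolecule
from .crystal import TrialCrystal
from .energy import _Block, _pair_arrays
from .symmetry import (SpaceGroup, cell_from_free_params, free_cell_params)

__all__ = ["SamplerConfig", "SamplingExhausted", "next_trial",
           "geometry_check", "generate_batch", "SURVEY_SCALE", "DESK_SCALE"]

# packing-efficiency prior used to turn summed vdW sphere volumes into a
# molecular volume estimate
_PACKING_EFFICIENCY = 0.7


class SamplingExhausted(RuntimeError):
    """Too few candidates passed the geometry check."""


@dataclass(frozen=True)
class SamplerConfig:
    """Controls for trial-crystal generation.

    ``overlap_s`` scales the sum of vdW radii below which an intermolecular
    contact rejects the candidate; ``vol_lo``/``vol_hi`` bound the cell
    volume relative to multiplicity × estimated molecular volume.
    """

    seed: int = 0
    vol_lo: float = 0.5
    vol_hi: float = 2.5
    length_ratio_lo: float = 0.5
    length_ratio_hi: float = 2.0
    angle_lo: float = 60.0
    angle_hi: float = 120.0
    overlap_s: float = 0.6
    max_attempts: int = 200     # per accepted structure

    def __post_init__(self):
        if not 0.0 < self.overlap_s < 1.0:
            raise ValueError("overlap factor must satisfy 0 < s < 1")
        if self.vol_hi <= self.vol_lo or self.length_ratio_hi <= self.length_ratio_lo:
            raise ValueError("degenerate sampling bounds")
        if self.angle_hi <= self.angle_lo:
            raise ValueError("degenerate angle bounds")


# presets: the full survey-scale setting (10 000 minimised structures per
# space group) and the desk-scale default used throughout the test fixtures
SURVEY_SCALE = {"n_per_group": 10_000}
DESK_SCALE = {"n_per_group": 200}


def molecular_volume_estimate(mol: RigidMolecule) -> float:
    """vdW-sphere volume divided by a 0.7 packing-efficiency prior, Å³."""
    return mol.vdw_volume() / _PACKING_EFFICIENCY


def _sobol(group: SpaceGroup, cfg: SamplerConfig) -> qmc.Sobol:
    # cell shape + volume scale + centroid (3) + orientation (3)
    dim = len(free_cell_params(group)) + 7
    return qmc.Sobol(d=dim, scramble=True, seed=cfg.seed)


def _trial_from_uniforms(u: np.ndarray, group: SpaceGroup, mol: RigidMolecule,
                         cfg: SamplerConfig, index: int) -> TrialCrystal:
    names = free_cell_params(group)
    nf = len(names)
    uc = u[:nf]
    uvol = u[nf]
    ucen = u[nf + 1 : nf + 4]
    urot = u[nf + 4 :]
    vals = []
    for name, ui in zip(names, uc):
        if name in ("alpha", "beta", "gamma"):
            vals.append(cfg.angle_lo + ui * (cfg.angle_hi - cfg.angle_lo))
        else:
            vals.append(cfg.length_ratio_lo + ui * (cfg.length_ratio_hi - cfg.length_ratio_lo))
    cell = cell_from_free_params(group, [
        v * 5.0 if n not in ("alpha", "beta", "gamma") else v
        for n, v in zip(names, vals)
    ])
    # rescale isotropically to the sampled target volume
    v_target = (cfg.vol_lo + uvol * (cfg.vol_hi - cfg.vol_lo)) * \
        group.multiplicity * molecular_volume_estimate(mol)
    s = (v_target / cell.volume) ** (1.0 / 3.0)
    scaled = []
    for name in names:
        v = getattr(cell, name)
        scaled.append(v * s if name not in ("alpha", "beta", "gamma") else v)
    cell = cell_from_free_params(group, scaled)

    # Shoemake uniform random rotation from three uniforms
    u1, u2, u3 = urot
    q = np.array([
        np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
        np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
        np.sqrt(u1) * np.sin(2 * np.pi * u3),
        np.sqrt(u1) * np.cos(2 * np.pi * u3),
    ])
    from .symmetry import Placement

    placement = Placement(tuple(ucen), tuple(q))
    return TrialCrystal(group, cell, placement, mol, index=index, seed=cfg.seed)


def next_trial(group: SpaceGroup, mol: RigidMolecule, cfg: SamplerConfig,
               index: int) -> TrialCrystal:
    """The ``index``-th trial crystal of the (seeded) low-discrepancy
    sequence — a pure function of (seed, index)."""
    if index < 0:
        raise ValueError("index must be non-negative")
    eng = _sobol(group, cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        if index:
            eng.fast_forward(index)
        u = eng.random(1)[0]
    return _trial_from_uniforms(u, group, mol, cfg, index)


def geometry_check(trial: TrialCrystal, cfg: SamplerConfig) -> bool:
    """True iff no intermolecular contact (over symmetry images and
    neighbouring cells) is closer than s×(vdW_i + vdW_j); contacts exactly
    at the threshold pass."""
    mol = trial.molecule
    radii = mol.vdw_radii
    reach = cfg.overlap_s * 2.0 * float(radii.max()) + 1e-9
    images = trial.images(check=False)
    blocks = [
        _Block(img.cart, np.zeros(mol.n_atoms, dtype=int), mol.charges,
               np.zeros((mol.n_atoms, 3)), np.zeros((mol.n_atoms, 3, 3)))
        for img in images
    ]
    ii, jatom, _, r = _pair_arrays(trial.cell, blocks, 0, reach)
    if r.size == 0:
        return True
    rj = np.tile(radii, len(blocks))[jatom]
    return bool(np.all(r >= cfg.overlap_s * (radii[ii] + rj) - 1e-12))


def generate_batch(group: SpaceGroup, mol: RigidMolecule, cfg: SamplerConfig,
                   n_valid: int, start_index: int = 0) -> list[TrialCrystal]:
    """Exactly ``n_valid`` geometry-checked trials, consuming sequence
    indices in order from ``start_index`` (disjoint index ranges give
    disjoint, independently reproducible work)."""
    if n_valid < 0:
        raise ValueError("n_valid must be non-negative")
    out: list[TrialCrystal] = []
    if n_valid == 0:
        return out
    eng = _sobol(group, cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        if start_index:
            eng.fast_forward(start_index)
    index = start_index
    max_attempts = cfg.max_attempts * n_valid
    attempts = 0
    while len(out) < n_valid:
        if attempts >= max_attempts:
            rate = len(out) / max(attempts, 1)
            raise SamplingExhausted(
                f"only {len(out)}/{n_valid} trials accepted after {attempts} "
                f"attempts (acceptance rate {rate:.3f})"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            u = eng.random(1)[0]
        trial = _trial_from_uniforms(u, group, mol, cfg, index)
        index += 1
        attempts += 1
        if geometry_check(trial, cfg):
            out.append(trial)
    return out
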