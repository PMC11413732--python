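"""Lattice energy of a periodic rigid-molecule crystal.

The model is the classic anisotropic atom–atom intermolecular potential
used in force-field CSP: exp-6 (Buckingham) repulsion–dispersion between
atom pairs plus atom-centred multipole electrostatics (charges by Ewald
summation; dipole and quadrupole terms by a whole-molecule direct sum with
a centroid cutoff, which keeps every included interaction between neutral
molecules so the mixed terms decay at least as r⁻⁴).  Intramolecular terms
are excluded: with rigid monomers they are constant and the lattice energy
is referenced to isolated molecules.

Two numerical guards define the working potential:

* the dispersion −C/r⁶ term is tapered smoothly to zero over the final
  ``taper_width`` Å below the cutoff, and the analytic uniform-density tail
  correction accounts for both the taper window and everything beyond the
  cutoff;
* below the inner turnover radius of each exp-6 pair curve the potential is
  continued as a steep repulsive wall, removing the unphysical short-range
  collapse of the Buckingham form.

Energies are per molecule of the asymmetric unit (Z′ = 1), kJ mol⁻¹.
A brute-force expanding-supercell oracle (no neighbour lists, no cutoffs,
no Ewald) is included for testing; it shares only the pair-curve
definition, not the lattice summation machinery.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.special import erf, erfc

from .chem import ForceField, MultipoleSet, PairParams, RigidMolecule
from .crystal import MinimizedCrystal, TrialCrystal
from .symmetry import Cell, Placement, SpaceGroup, expand_to_cell

__all__ = [
    "COULOMB_K",
    "EnergySettings",
    "EnergyBreakdown",
    "ClashError",
    "NeutralityError",
    "exp6_pair",
    "repdisp_energy",
    "electrostatic_energy",
    "lattice_energy",
    "brute_force_energy",
    "LatticeEnergyEvaluator",
]

# Coulomb constant: e² / (4π ε0) in kJ mol⁻¹ Å e⁻² (CODATA-derived).
COULOMB_K = 1389.35458


class ClashError(ValueError):
    """An intermolecular pair distance fell below the hard clash floor."""


class NeutralityError(ValueError):
    """The unit cell carries a net charge."""


@dataclass(frozen=True)
class EnergySettings:
    """Cutoffs and convergence controls of the energy model.

    ``rank`` selects the electrostatic truncation: 0 = charges, 1 = +dipoles,
    2 = +quadrupoles (the default and the implemented maximum).
    """

    cutoff: float = 15.0            # repulsion-dispersion cutoff, Å
    elec_cutoff: float = 15.0       # molecule-centroid cutoff, rank ≥ 1 terms
    rank: int = 2
    ewald_real_cutoff: float = 10.0
    ewald_alpha: float | None = None  # Å⁻¹; None → 4.8 / ewald_real_cutoff
    ewald_accuracy: float = 1e-8    # reciprocal-space truncation target
    tail_correction: bool = True
    taper_width: float = 1.0        # Å; dispersion switch-off window
    clash_floor: float = 0.3        # Å; below this the geometry is unphysical
    dipole_warn: float = 1e-3       # |cell dipole| (e·Å) triggering a warning

    def __post_init__(self):
        if self.cutoff <= 0 or self.elec_cutoff <= 0 or self.ewald_real_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if not 0 <= self.rank <= 2:
            raise ValueError("implemented electrostatic ranks are 0-2")
        if not 0 <= self.taper_width < self.cutoff:
            raise ValueError("taper width must lie in [0, cutoff)")

    @property
    def alpha(self) -> float:
        return self.ewald_alpha if self.ewald_alpha is not None else 4.8 / self.ewald_real_cutoff

    def snapshot(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "elec_cutoff": self.elec_cutoff,
            "rank": self.rank,
            "ewald_alpha": self.alpha,
            "ewald_accuracy": self.ewald_accuracy,
            "tail_correction": self.tail_correction,
            "taper_width": self.taper_width,
        }


@dataclass(frozen=True)
class EnergyBreakdown:
    E_repdisp: float
    E_elec: float
    converged: bool = True
    settings: dict = field(default_factory=dict)

    @property
    def E_latt(self) -> float:
        return self.E_repdisp + self.E_elec


def exp6_pair(params: PairParams, r) -> float:
    """Raw Buckingham pair energy A·exp(−B·r) − C/r⁶ (kJ mol⁻¹)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    out = params.A * np.exp(-params.B * r) - params.C / r**6
    return float(out) if out.ndim == 0 else out


def exp6_inner_turnover(params: PairParams) -> float:
    """Radius of the inner maximum of the exp-6 curve (the top of the
    barrier guarding the unphysical short-range well)."""
    A, B, C = params.A, params.B, params.C
    if A == 0 or C == 0:
        return 0.0
    target = 6.0 * C / (A * B)
    g = lambda r: r**7 * math.exp(-B * r) - target
    hi = 7.0 / B
    if g(hi) <= 0:  # curve is attractive everywhere: no barrier
        return hi
    lo = 1e-3
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _cap_tables(Atab, Btab, Ctab):
    n = Atab.shape[0]
    rcap = np.zeros((n, n))
    ucap = np.zeros((n, n))
    scap = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            p = PairParams(Atab[i, j], Btab[i, j], Ctab[i, j])
            r1 = exp6_inner_turnover(p)
            rcap[i, j] = r1
            if r1 > 0:
                ucap[i, j] = p.A * math.exp(-p.B * r1) - p.C / r1**6
                scap[i, j] = p.A * p.B * math.exp(-p.B * r1)
    return rcap, ucap, scap


def _taper(r, cutoff, width):
    """Quintic smooth-step factor for the dispersion term: 1 well inside the
    cutoff, 0 at and beyond it."""
    if width <= 0:
        return np.where(r <= cutoff, 1.0, 0.0)
    x = np.clip((r - (cutoff - width)) / width, 0.0, 1.0)
    return 1.0 - x**3 * (10.0 - 15.0 * x + 6.0 * x**2)


def _tail_factor(settings: EnergySettings) -> float:
    """∫ r⁻⁴ weighted by the dispersion deficit: taper window + beyond-cutoff."""
    rc, w = settings.cutoff, settings.taper_width
    beyond = 1.0 / (3.0 * rc**3)
    if w <= 0:
        return beyond
    rr = np.linspace(rc - w, rc, 201)
    window = np.trapezoid((1.0 - _taper(rr, rc, w)) / rr**4, rr)
    return float(window + beyond)


def _exp6_lattice_kernel(r, A, B, C, rcap, ucap, scap, cutoff, width):
    """Vectorised working pair curve: exp-6 with taper and inner cap."""
    e = A * np.exp(-B * r) - C / r**6 * _taper(r, cutoff, width)
    inner = r < rcap
    if np.any(inner):
        e = np.where(inner, ucap + scap * (rcap - r), e)
    return np.where(r <= cutoff, e, 0.0)


# ---------------------------------------------------------------------------
# internal geometry plumbing


def _translation_grid(cell: Cell, reach: float) -> np.ndarray:
    """Integer cell offsets guaranteed to cover all pairs within ``reach``."""
    Minv = np.linalg.inv(cell.matrix)
    # perpendicular inter-plane spacings along each axis (reciprocal columns)
    d = 1.0 / np.linalg.norm(Minv, axis=0)
    nmax = np.ceil(reach / d).astype(int) + 1
    rng = [np.arange(-n, n + 1) for n in nmax]
    grid = np.stack(np.meshgrid(*rng, indexing="ij"), axis=-1).reshape(-1, 3)
    return grid


class _MatrixCell:
    """Duck-typed cell carrying a precomputed lattice matrix (hot path)."""

    def __init__(self, M: np.ndarray, volume: float):
        self.matrix = M
        self.volume = volume


@dataclass
class _Block:
    """One rigid-molecule instance in the unit cell (Cartesian)."""

    cart: np.ndarray          # (n, 3)
    tidx: np.ndarray          # (n,) indices into the type tables
    q: np.ndarray             # (n,)
    mu: np.ndarray            # (n, 3)
    theta: np.ndarray         # (n, 3, 3)


def _blocks_from_crystal(crystal, rank: int) -> tuple[list[_Block], list[str]]:
    mol = crystal.molecule
    types = sorted(set(mol.ff_types))
    tmap = {t: i for i, t in enumerate(types)}
    tidx = np.array([tmap[t] for t in mol.ff_types])
    mp = mol.multipoles
    images = crystal.images(check=False)
    # orientation of the placed molecule (applied before symmetry ops)
    R0 = crystal.placement.rotation.as_matrix()
    blocks = []
    for img in images:
        Rc = img.cart_rot @ R0
        if rank >= 1 and mp.rank >= 1:
            mu = mp.dipoles @ Rc.T
        else:
            mu = np.zeros((mol.n_atoms, 3))
        if rank >= 2 and mp.rank >= 2:
            theta = np.einsum("ab,nbc,dc->nad", Rc, mp.quadrupoles, Rc)
        else:
            theta = np.zeros((mol.n_atoms, 3, 3))
        blocks.append(_Block(img.cart, tidx, mol.charges.copy(), mu, theta))
    return blocks, types


def _pair_arrays(cell: Cell, blocks: list[_Block], probe: int, reach: float):
    """All (probe-atom, image-atom) pair geometry within ``reach``.

    Returns flat arrays with the probe instance itself (t = 0) excluded.
    """
    M = cell.matrix
    # atoms can stick out of their home cell by the molecular radius
    r_g = max(
        float(np.linalg.norm(b.cart - b.cart.mean(axis=0), axis=1).max())
        for b in blocks
    )
    grid = _translation_grid(cell, reach + 2.0 * r_g)
    tvecs = grid @ M
    base = np.concatenate([b.cart for b in blocks])          # (N, 3)
    na = blocks[0].cart.shape[0]
    N = base.shape[0]
    pos = base[None, :, :] + tvecs[:, None, :]
    pos = pos.reshape(-1, 3)
    zero_t = int(np.flatnonzero((grid == 0).all(axis=1))[0])
    excl = np.zeros((grid.shape[0], N), dtype=bool)
    excl[zero_t, probe * na : (probe + 1) * na] = True
    excl = excl.reshape(-1)

    A = blocks[probe].cart
    diff = pos[None, :, :] - A[:, None, :]                   # (na, m, 3)
    r2 = np.einsum("imk,imk->im", diff, diff)
    within = (r2 <= reach * reach) & ~excl[None, :]
    ii, jj = np.nonzero(within)
    rvec = diff[ii, jj]
    r = np.sqrt(r2[ii, jj])
    jatom = jj % N                                           # index into base arrays
    return ii, jatom, rvec, r


def _base_arrays(blocks: list[_Block]):
    tidx = np.concatenate([b.tidx for b in blocks])
    q = np.concatenate([b.q for b in blocks])
    mu = np.concatenate([b.mu for b in blocks])
    theta = np.concatenate([b.theta for b in blocks])
    return tidx, q, mu, theta


# ---------------------------------------------------------------------------
# reference (numpy) energy components


def _repdisp(cell, blocks, probe, Atab, Btab, Ctab, settings) -> float:
    pb = blocks[probe]
    ii, jatom, rvec, r = _pair_arrays(cell, blocks, probe, settings.cutoff)
    if r.size and r.min() < settings.clash_floor:
        raise ClashError(f"intermolecular contact at {r.min():.3f} Å")
    tidx_all, _, _, _ = _base_arrays(blocks)
    ti = blocks[probe].tidx[ii]
    tj = tidx_all[jatom]
    rcap, ucap, scap = _cap_tables(Atab, Btab, Ctab)
    e = 0.5 * np.sum(
        _exp6_lattice_kernel(
            r, Atab[ti, tj], Btab[ti, tj], Ctab[ti, tj],
            rcap[ti, tj], ucap[ti, tj], scap[ti, tj],
            settings.cutoff, settings.taper_width,
        )
    )
    if settings.tail_correction:
        csum = Ctab[pb.tidx[:, None], tidx_all[None, :]].sum()
        e += -(2.0 * np.pi / cell.volume) * csum * _tail_factor(settings)
    return float(e)


def _ewald_charges(cell, blocks, probe, settings) -> float:
    """Charge-charge electrostatic energy per molecule by Ewald summation
    (tinfoil boundary conditions)."""
    alpha = settings.alpha
    pb = blocks[probe]
    nb = len(blocks)
    tq_all = np.concatenate([b.q for b in blocks])
    if abs(tq_all.sum()) > 1e-8:
        raise NeutralityError(f"unit cell charge {tq_all.sum():g} ≠ 0")
    M = cell.matrix
    V = cell.volume

    # real space: probe molecule against everything else
    ii, jatom, rvec, r = _pair_arrays(cell, blocks, probe, settings.ewald_real_cutoff)
    e_real = 0.5 * np.sum(pb.q[ii] * tq_all[jatom] * erfc(alpha * r) / r)

    # reciprocal space over the whole cell, then per molecule
    base = np.concatenate([b.cart for b in blocks])
    kmax = 2.0 * alpha * math.sqrt(max(-math.log(settings.ewald_accuracy), 1.0))
    hmax = np.ceil(kmax * np.linalg.norm(M, axis=1) / (2 * np.pi)).astype(int)
    hr = [np.arange(-h, h + 1) for h in hmax]
    H = np.stack(np.meshgrid(*hr, indexing="ij"), axis=-1).reshape(-1, 3)
    K = 2.0 * np.pi * H @ np.linalg.inv(M).T
    k2 = np.einsum("ij,ij->i", K, K)
    sel = (k2 > 1e-12) & (k2 <= kmax * kmax)
    K = K[sel]
    k2 = k2[sel]
    phase = K @ base.T                                       # (nk, N)
    S = (tq_all[None, :] * np.exp(1j * phase)).sum(axis=1)
    e_recip = (2.0 * np.pi / V) * np.sum(np.exp(-k2 / (4 * alpha**2)) / k2 * np.abs(S) ** 2)

    e_self = -alpha / math.sqrt(np.pi) * np.sum(tq_all**2)

    # remove intramolecular interactions of the probe instance (the erf part;
    # the real-space sum above never contained the excluded erfc part)
    d = pb.cart[:, None, :] - pb.cart[None, :, :]
    rij = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    iu = np.triu_indices(len(pb.q), k=1)
    e_excl = -np.sum(pb.q[iu[0]] * pb.q[iu[1]] * erf(alpha * rij[iu]) / rij[iu])

    return COULOMB_K * float(e_real + (e_recip + e_self) / nb + e_excl)


def _multipole_pair_energy(qi, mui, thi, qj, muj, thj, rvec, r, rank: int,
                           include_qq: bool = False) -> np.ndarray:
    """Vectorised multipole interaction terms (without the Coulomb constant).

    ``rvec`` points from site i to site j.  Quadrupoles are traceless
    Buckingham tensors.  The charge-charge term is skipped unless requested
    (the periodic path handles it by Ewald).
    """
    n = rvec / r[:, None]
    inv_r = 1.0 / r
    e = np.zeros_like(r)
    if include_qq:
        e += qi * qj * inv_r
    if rank >= 1:
        mi_n = np.einsum("ik,ik->i", mui, n)
        mj_n = np.einsum("ik,ik->i", muj, n)
        e += (qj * mi_n - qi * mj_n) * inv_r**2
        mi_mj = np.einsum("ik,ik->i", mui, muj)
        e += (mi_mj - 3.0 * mi_n * mj_n) * inv_r**3
    if rank >= 2:
        thi_n = np.einsum("ikl,il->ik", thi, n)
        thj_n = np.einsum("ikl,il->ik", thj, n)
        n_thi_n = np.einsum("ik,ik->i", n, thi_n)
        n_thj_n = np.einsum("ik,ik->i", n, thj_n)
        e += (qj * n_thi_n + qi * n_thj_n) * inv_r**3
        mi_n = np.einsum("ik,ik->i", mui, n)
        mj_n = np.einsum("ik,ik->i", muj, n)
        mj_thi_n = np.einsum("ik,ik->i", muj, thi_n)
        mi_thj_n = np.einsum("ik,ik->i", mui, thj_n)
        e += (2.0 * mj_thi_n - 5.0 * mj_n * n_thi_n
              - 2.0 * mi_thj_n + 5.0 * mi_n * n_thj_n) * inv_r**4
        tr_ij = np.einsum("ikl,ikl->i", thi, thj)
        n_titj_n = np.einsum("ik,ik->i", thi_n, thj_n)
        e += (2.0 * tr_ij - 20.0 * n_titj_n + 35.0 * n_thi_n * n_thj_n) / 3.0 * inv_r**5
    return e


def _highrank_direct(cell, blocks, probe, settings) -> float:
    """Direct-sum dipole/quadrupole terms (everything above charge-charge).

    Pairs are selected molecule-by-molecule (centroid within ``elec_cutoff``)
    so every included interaction is between whole neutral molecules; the
    mixed charge-dipole/quadrupole terms then decay at least as r⁻⁴.
    """
    pb = blocks[probe]
    M = cell.matrix
    cen = np.stack([b.cart.mean(axis=0) for b in blocks])      # (nb, 3)
    grid = _translation_grid(cell, settings.elec_cutoff + 1e-9)
    tvecs = grid @ M
    pc = pb.cart.mean(axis=0)
    allcen = cen[None, :, :] + tvecs[:, None, :]
    d2 = np.einsum("tbk,tbk->tb", allcen - pc, allcen - pc)
    sel = d2 <= settings.elec_cutoff**2
    zero_t = int(np.flatnonzero((grid == 0).all(axis=1))[0])
    sel[zero_t, probe] = False
    tt, bb = np.nonzero(sel)
    if tt.size == 0:
        return 0.0
    block_cart = np.stack([b.cart for b in blocks])
    block_q = np.stack([b.q for b in blocks])
    block_mu = np.stack([b.mu for b in blocks])
    block_th = np.stack([b.theta for b in blocks])
    imgpos = (block_cart[bb] + tvecs[tt][:, None, :]).reshape(-1, 3)
    qj = block_q[bb].reshape(-1)
    muj = block_mu[bb].reshape(-1, 3)
    thj = block_th[bb].reshape(-1, 3, 3)
    na = pb.cart.shape[0]
    m = imgpos.shape[0]
    diff = imgpos[None, :, :] - pb.cart[:, None, :]            # (na, m, 3)
    r = np.sqrt(np.einsum("imk,imk->im", diff, diff))
    ii = np.repeat(np.arange(na), m)
    rvec = diff.reshape(-1, 3)
    rr = r.reshape(-1)
    e = _multipole_pair_energy(
        pb.q[ii], pb.mu[ii], pb.theta[ii],
        np.tile(qj, na), np.tile(muj, (na, 1)), np.tile(thj, (na, 1, 1)),
        rvec, rr, settings.rank, include_qq=False,
    )
    return COULOMB_K * 0.5 * float(e.sum())


def _warn_cell_dipole(blocks, settings) -> None:
    p = sum(b.q @ b.cart + b.mu.sum(axis=0) for b in blocks)
    if np.linalg.norm(p) > settings.dipole_warn:
        warnings.warn(
            f"unit cell carries a net dipole ({np.linalg.norm(p):.3g} e·Å); "
            "the direct-sum dipole terms are conditionally convergent",
            stacklevel=3,
        )


# ---------------------------------------------------------------------------
# fused fast path (numba) used by the minimiser


@njit(cache=True)
def _njit_rd_real(probe, base, tvecs, zero_t, na_probe,
                  tidx_probe, tidx_all, q_probe, q_all,
                  Atab, Btab, Ctab, Rcap, Ucap, Scap,
                  cutoff, width, alpha, ewald_rc, do_charges):
    """Fused exp-6 + Ewald-real loops.  Returns (e_rd, e_real, r_min)."""
    e_rd = 0.0
    e_real = 0.0
    rmin = 1.0e30
    c2 = cutoff * cutoff
    w2 = ewald_rc * ewald_rc
    reach2 = max(c2, w2)
    N = base.shape[0]
    for t in range(tvecs.shape[0]):
        tx, ty, tz = tvecs[t, 0], tvecs[t, 1], tvecs[t, 2]
        is_zero = t == zero_t
        for j in range(N):
            xj = base[j, 0] + tx
            yj = base[j, 1] + ty
            zj = base[j, 2] + tz
            for i in range(na_probe):
                if is_zero and j < na_probe:
                    continue
                dx = xj - probe[i, 0]
                dy = yj - probe[i, 1]
                dz = zj - probe[i, 2]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 > reach2:
                    continue
                if r2 < 1e-12:  # coincident sites: unphysical, flag as clash
                    rmin = 0.0
                    continue
                r = math.sqrt(r2)
                if r < rmin:
                    rmin = r
                ti = tidx_probe[i]
                tj = tidx_all[j]
                if r2 <= c2:
                    rc1 = Rcap[ti, tj]
                    if r < rc1:
                        e_rd += Ucap[ti, tj] + Scap[ti, tj] * (rc1 - r)
                    else:
                        s = 1.0
                        if width > 0.0 and r > cutoff - width:
                            x = (r - (cutoff - width)) / width
                            s = 1.0 - x * x * x * (10.0 - 15.0 * x + 6.0 * x * x)
                        e_rd += Atab[ti, tj] * math.exp(-Btab[ti, tj] * r) \
                            - Ctab[ti, tj] / (r2 * r2 * r2) * s
                if do_charges and r2 <= w2:
                    e_real += q_probe[i] * q_all[j] * math.erfc(alpha * r) / r
    return 0.5 * e_rd, 0.5 * e_real, rmin


@njit(cache=True)
def _njit_recip(H, MinvT, base, q, alpha, kmax, volume):
    """Reciprocal-space Ewald sum over the filtered k grid."""
    e = 0.0
    kmax2 = kmax * kmax
    inv4a2 = 1.0 / (4.0 * alpha * alpha)
    N = base.shape[0]
    for h in range(H.shape[0]):
        kx = 2.0 * math.pi * (H[h, 0] * MinvT[0, 0] + H[h, 1] * MinvT[1, 0] + H[h, 2] * MinvT[2, 0])
        ky = 2.0 * math.pi * (H[h, 0] * MinvT[0, 1] + H[h, 1] * MinvT[1, 1] + H[h, 2] * MinvT[2, 1])
        kz = 2.0 * math.pi * (H[h, 0] * MinvT[0, 2] + H[h, 1] * MinvT[1, 2] + H[h, 2] * MinvT[2, 2])
        k2 = kx * kx + ky * ky + kz * kz
        if k2 < 1e-12 or k2 > kmax2:
            continue
        sr = 0.0
        si = 0.0
        for j in range(N):
            ph = kx * base[j, 0] + ky * base[j, 1] + kz * base[j, 2]
            sr += q[j] * math.cos(ph)
            si += q[j] * math.sin(ph)
        e += math.exp(-k2 * inv4a2) / k2 * (sr * sr + si * si)
    return 2.0 * math.pi / volume * e


def _quat_to_matrix(q):
    x, y, z, w = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


class LatticeEnergyEvaluator:
    """Re-usable lattice-energy evaluator for one (molecule, group, force
    field, settings) combination.

    The minimiser drives this directly (it has a fused compiled inner loop);
    the module-level operations provide an independent plain-numpy path.
    """

    def __init__(self, molecule: RigidMolecule, group: SpaceGroup,
                 ff: ForceField, settings: EnergySettings):
        self.molecule = molecule
        self.group = group
        self.ff = ff
        self.settings = settings
        self.types = sorted(set(molecule.ff_types))
        tmap = {t: i for i, t in enumerate(self.types)}
        self.tidx = np.array([tmap[t] for t in molecule.ff_types])
        self.Atab, self.Btab, self.Ctab = ff.pair_tables(self.types)
        self.Rcap, self.Ucap, self.Scap = _cap_tables(self.Atab, self.Btab, self.Ctab)
        self._tail = _tail_factor(settings) if settings.tail_correction else 0.0
        self._csum_per_pair = None
        self._has_charges = bool(np.any(molecule.charges))
        self._has_highrank = settings.rank >= 1 and molecule.multipoles.rank >= 1
        self._ops_R = np.stack([op.rot_array for op in group.operations])
        self._ops_t = np.stack([op.tran_array for op in group.operations])
        self._local = molecule.local_coords
        self._r_g = float(np.linalg.norm(self._local, axis=1).max())
        # rigid intramolecular geometry is constant: cache the Ewald
        # exclusion distances
        d = self._local[:, None, :] - self._local[None, :, :]
        rij = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        iu = np.triu_indices(molecule.n_atoms, k=1)
        self._intra_r = rij[iu]
        self._intra_qq = molecule.charges[iu[0]] * molecule.charges[iu[1]]
        self._grid_cache: dict = {}
        # constant Ewald pieces: tiled type/charge arrays, self energy and
        # the rigid intramolecular exclusion
        nb = group.multiplicity
        self._tidx_all = np.tile(self.tidx, nb)
        self._q_all = np.tile(molecule.charges, nb)
        alpha = settings.alpha
        self._e_self = -alpha / math.sqrt(np.pi) * float(np.sum(self._q_all**2))
        if self._intra_r.size:
            self._e_excl = -float(
                np.sum(self._intra_qq * erf(alpha * self._intra_r) / self._intra_r)
            )
        else:
            self._e_excl = 0.0
        self._kmax = 2.0 * alpha * math.sqrt(max(-math.log(settings.ewald_accuracy), 1.0))

    # -- geometry ----------------------------------------------------------
    def _cell_blocks(self, M, Minv, centroid, quat):
        R0 = _quat_to_matrix(np.asarray(quat))
        cart0 = self._local @ R0.T
        frac0 = np.asarray(centroid) + cart0 @ Minv
        F = np.einsum("oab,nb->ona", self._ops_R, frac0) + self._ops_t[:, None, :]
        cen = F.mean(axis=1)
        F = F + (cen % 1.0 - cen)[:, None, :]
        base = (F @ M).reshape(-1, 3)
        return base, R0

    def _grid(self, Minv, reach: float):
        d = 1.0 / np.linalg.norm(Minv, axis=0)
        nmax = tuple(np.ceil(reach / d).astype(int) + 1)
        grid = self._grid_cache.get(nmax)
        if grid is None:
            rng = [np.arange(-n, n + 1) for n in nmax]
            grid = np.stack(np.meshgrid(*rng, indexing="ij"), axis=-1).reshape(-1, 3)
            self._grid_cache[nmax] = grid
        return grid

    # -- energy ------------------------------------------------------------
    def breakdown(self, cell: Cell, placement: Placement) -> EnergyBreakdown:
        M = cell.matrix
        return self.breakdown_raw(M, np.asarray(placement.centroid),
                                  np.asarray(placement.quaternion))

    def breakdown_raw(self, M: np.ndarray, centroid, quat) -> EnergyBreakdown:
        """Energy from the raw cell matrix and placement arrays (hot path)."""
        st = self.settings
        Minv = np.linalg.inv(M)
        base, R0 = self._cell_blocks(M, Minv, centroid, quat)
        volume = float(abs(np.linalg.det(M)))
        na = self.molecule.n_atoms
        nb = self.group.multiplicity
        probe = base[:na]
        reach = max(st.cutoff, st.ewald_real_cutoff if self._has_charges else 0.0)
        grid = self._grid(Minv, reach + 2.0 * self._r_g)
        zero_t = (grid.shape[0] - 1) // 2  # symmetric meshgrid: centre row
        tvecs = grid @ M
        e_rd, e_real, rmin = _njit_rd_real(
            probe, base, tvecs, zero_t, na,
            self.tidx, self._tidx_all, self.molecule.charges, self._q_all,
            self.Atab, self.Btab, self.Ctab, self.Rcap, self.Ucap, self.Scap,
            st.cutoff, st.taper_width, st.alpha, st.ewald_real_cutoff,
            self._has_charges,
        )
        if rmin < st.clash_floor:
            raise ClashError(f"intermolecular contact at {rmin:.3f} Å")
        if st.tail_correction:
            csum = self.Ctab[self.tidx[:, None], self._tidx_all[None, :]].sum()
            e_rd += -(2.0 * np.pi / volume) * csum * self._tail
        e_el = 0.0
        if self._has_charges:
            hmax = tuple(
                np.ceil(self._kmax * np.linalg.norm(M, axis=1) / (2 * np.pi)).astype(int)
            )
            key = ("k",) + hmax
            H = self._grid_cache.get(key)
            if H is None:
                hr = [np.arange(-h, h + 1) for h in hmax]
                H = np.stack(np.meshgrid(*hr, indexing="ij"), axis=-1).reshape(-1, 3).astype(float)
                self._grid_cache[key] = H
            e_recip = _njit_recip(H, np.ascontiguousarray(Minv.T), base,
                                  self._q_all, st.alpha, self._kmax, volume)
            e_el = COULOMB_K * (
                e_real + (e_recip + self._e_self) / nb + self._e_excl
            )
        if self._has_highrank:
            e_el += self._highrank(M, Minv, volume, base, R0, st)
        return EnergyBreakdown(float(e_rd), float(e_el), converged=True,
                               settings=st.snapshot())

    def _highrank(self, M, Minv, volume, base, R0, st):
        mp = self.molecule.multipoles
        na = self.molecule.n_atoms
        blocks = []
        for k, (Rf, _) in enumerate(zip(self._ops_R, self._ops_t)):
            Rc = (M.T @ Rf @ Minv.T) @ R0
            mu = mp.dipoles @ Rc.T
            theta = (
                np.einsum("ab,nbc,dc->nad", Rc, mp.quadrupoles, Rc)
                if st.rank >= 2 else np.zeros((na, 3, 3))
            )
            blocks.append(_Block(base[k * na : (k + 1) * na], self.tidx,
                                 self.molecule.charges, mu, theta))
        _warn_cell_dipole(blocks, st)
        return _highrank_direct(_MatrixCell(M, volume), blocks, 0, st)

    def energy(self, cell: Cell, placement: Placement) -> float:
        return self.breakdown(cell, placement).E_latt


def _as_crystal(crystal):
    if not isinstance(crystal, (TrialCrystal, MinimizedCrystal)):
        raise TypeError("expected a TrialCrystal or MinimizedCrystal")
    return crystal


def repdisp_energy(crystal, ff: ForceField, settings: EnergySettings | None = None) -> float:
    """exp-6 repulsion–dispersion lattice energy per molecule (kJ mol⁻¹),
    with the analytic uniform-density tail correction beyond the cutoff."""
    crystal = _as_crystal(crystal)
    settings = settings or EnergySettings()
    blocks, types = _blocks_from_crystal(crystal, 0)
    Atab, Btab, Ctab = ff.pair_tables(types)
    return _repdisp(crystal.cell, blocks, 0, Atab, Btab, Ctab, settings)


def electrostatic_energy(crystal, multipoles: MultipoleSet | None = None,
                         settings: EnergySettings | None = None) -> float:
    """Electrostatic lattice energy per molecule (kJ mol⁻¹).

    Charge-charge by Ewald summation; dipole and quadrupole terms by a
    whole-molecule direct sum within ``elec_cutoff`` (a warning is issued if
    the cell carries a net dipole, for which the direct sum is conditionally
    convergent)."""
    crystal = _as_crystal(crystal)
    settings = settings or EnergySettings()
    if multipoles is not None and multipoles is not crystal.molecule.multipoles:
        crystal = crystal.replace(
            molecule=crystal.molecule.with_positions(
                crystal.molecule.positions, multipoles=multipoles))
    blocks, _ = _blocks_from_crystal(crystal, settings.rank)
    e = 0.0
    if np.any(crystal.molecule.charges):
        e += _ewald_charges(crystal.cell, blocks, 0, settings)
    if settings.rank >= 1 and crystal.molecule.multipoles.rank >= 1:
        _warn_cell_dipole(blocks, settings)
        e += _highrank_direct(crystal.cell, blocks, 0, settings)
    return float(e)


def lattice_energy(crystal, ff: ForceField, multipoles: MultipoleSet | None = None,
                   settings: EnergySettings | None = None) -> EnergyBreakdown:
    """Total lattice energy per molecule: exp-6 + electrostatics."""
    settings = settings or EnergySettings()
    e_rd = repdisp_energy(crystal, ff, settings)
    e_el = electrostatic_energy(crystal, multipoles, settings)
    return EnergyBreakdown(e_rd, e_el, converged=True, settings=settings.snapshot())


def expanded_reference_energy(crystal, ff: ForceField,
                              settings: EnergySettings | None = None,
                              supercell: tuple[int, int, int] = (1, 1, 1),
                              probe: int = 0) -> EnergyBreakdown:
    """Energy of the crystal evaluated from an explicit P1-style expansion.

    All symmetry copies (optionally replicated into a diagonal supercell)
    are treated as independent rigid bodies; ``probe`` selects which copy is
    regarded as "the" asymmetric unit.  Per-molecule energies must agree
    with the symmetry-reduced evaluation — the representation-invariance
    contract of the energy model.
    """
    crystal = _as_crystal(crystal)
    settings = settings or EnergySettings()
    blocks, types = _blocks_from_crystal(crystal, settings.rank)
    sx, sy, sz = supercell
    cell = crystal.cell
    M = cell.matrix
    if (sx, sy, sz) != (1, 1, 1):
        reps = []
        for ix in range(sx):
            for iy in range(sy):
                for iz in range(sz):
                    shift = np.array([ix, iy, iz]) @ M
                    for b in blocks:
                        reps.append(_Block(b.cart + shift, b.tidx, b.q, b.mu, b.theta))
        blocks = reps
        la, lb, lc = np.linalg.norm(M, axis=1)
        cell = Cell(la * sx, lb * sy, lc * sz, cell.alpha, cell.beta, cell.gamma)
    Atab, Btab, Ctab = ff.pair_tables(types)
    e_rd = _repdisp(cell, blocks, probe, Atab, Btab, Ctab, settings)
    e_el = 0.0
    if np.any(crystal.molecule.charges):
        e_el += _ewald_charges(cell, blocks, probe, settings)
    if settings.rank >= 1 and crystal.molecule.multipoles.rank >= 1:
        e_el += _highrank_direct(cell, blocks, probe, settings)
    return EnergyBreakdown(e_rd, e_el, converged=True, settings=settings.snapshot())


def brute_force_energy(crystal, ff: ForceField, multipoles: MultipoleSet | None = None,
                       radius: int = 6, rank: int | None = None,
                       return_trace: bool = False):
    """Direct double-sum oracle over an expanding block of image cells.

    No neighbour lists, no cutoffs or tapers, no Ewald: shell ``s`` adds
    every cell with Chebyshev offset exactly ``s``; because each shell of
    whole cells is charge-neutral, the Coulomb part converges for cells
    without a net dipole.  The exp-6 curve keeps the inner repulsive cap
    (part of the model definition) but is otherwise untruncated.  Returns
    the final estimate (and the per-shell trace on request).  Intended for
    small toy systems only.
    """
    crystal = _as_crystal(crystal)
    if rank is None:
        rank = crystal.molecule.multipoles.rank
    blocks, types = _blocks_from_crystal(crystal, rank)
    Atab, Btab, Ctab = ff.pair_tables(types)
    Rcap, Ucap, Scap = _cap_tables(Atab, Btab, Ctab)
    M = crystal.cell.matrix
    pb = blocks[0]
    tidx_all, q_all, mu_all, th_all = _base_arrays(blocks)
    base = np.concatenate([b.cart for b in blocks])
    na = pb.cart.shape[0]
    N = base.shape[0]

    trace = []
    total = 0.0
    for s in range(radius + 1):
        offs = _chebyshev_shell(s)
        tvecs = offs @ M
        pos = (base[None, :, :] + tvecs[:, None, :]).reshape(-1, 3)
        excl = np.zeros((offs.shape[0], N), dtype=bool)
        if s == 0:
            zero = int(np.flatnonzero((offs == 0).all(axis=1))[0])
            excl[zero, :na] = True
        excl = excl.reshape(-1)
        diff = pos[None, :, :] - pb.cart[:, None, :]
        r = np.sqrt(np.einsum("imk,imk->im", diff, diff))
        keep = ~excl[None, :].repeat(na, axis=0)
        ii, jj = np.nonzero(keep)
        rr = r[ii, jj]
        jatom = jj % N
        ti = pb.tidx[ii]
        tj = tidx_all[jatom]
        e_rd = Atab[ti, tj] * np.exp(-Btab[ti, tj] * rr) - Ctab[ti, tj] / rr**6
        inner = rr < Rcap[ti, tj]
        if np.any(inner):
            e_rd = np.where(
                inner, Ucap[ti, tj] + Scap[ti, tj] * (Rcap[ti, tj] - rr), e_rd
            )
        e = float(e_rd.sum())
        e += COULOMB_K * float(np.sum(
            _multipole_pair_energy(
                pb.q[ii], pb.mu[ii], pb.theta[ii],
                q_all[jatom], mu_all[jatom], th_all[jatom],
                diff[ii, jj], rr, rank, include_qq=True,
            )
        ))
        total += 0.5 * e
        trace.append(total)
    if return_trace:
        return total, trace
    return total


def _chebyshev_shell(s: int) -> np.ndarray:
    if s == 0:
        return np.zeros((1, 3), dtype=int)
    rng = np.arange(-s, s + 1)
    grid = np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1).reshape(-1, 3)
    return grid[np.abs(grid).max(axis=1) == s]
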