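"""Crystal identity and similarity.

Minimising many quasi-random starts funnels into the same local minima, so
a landscape must be deduplicated, and predicted structures must be matched
against reference (e.g. experimental) structures.  Both use the standard
two-tier approach:

* a fast screen on simulated powder X-ray diffraction patterns, compared
  with a de Gelder-style triangle-weighted cross-correlation;
* confirmation by a COMPACK-style comparison of n-molecule clusters with
  distance/angle tolerances, reporting the all-atom RMSD_n of the
  superposed clusters (RMSD_30 for reporting, a smaller n for dedup).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation

from .chem import ATOMIC_NUMBERS, kabsch_rotation
from .crystal import MinimizedCrystal

__all__ = [
    "PowderPattern",
    "ClusterMatch",
    "CompareConfig",
    "simulate_pxrd",
    "pxrd_similarity",
    "cluster_match",
    "deduplicate",
]


@dataclass(frozen=True)
class CompareConfig:
    n_molecules: int = 30          # cluster size for reporting (RMSD_30)
    dedup_n: int = 15              # cluster size used during dedup
    distance_tol: float = 0.20     # fractional tolerance on centroid distances
    angle_tol: float = 20.0        # degrees, molecular orientation misfit
    pxrd_threshold: float = 0.98   # similarity needed to nominate a duplicate
    two_theta_min: float = 5.0
    two_theta_max: float = 50.0
    two_theta_step: float = 0.02
    wavelength: float = 1.5406     # Å, Cu Kα
    peak_fwhm: float = 0.3         # degrees
    lorentz_polarization: bool = False
    triangle_width: float = 1.5    # degrees, de Gelder weighting window
    pair_rmsd_tol: float = 0.35    # Å, per-molecule superposition residual
    energy_window: float | None = 0.5  # kJ/mol prefilter during dedup

    def __post_init__(self):
        if self.distance_tol <= 0 or self.angle_tol <= 0 or self.triangle_width <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class PowderPattern:
    two_theta: np.ndarray
    intensity: np.ndarray
    wavelength: float

    def __post_init__(self):
        if np.any(np.diff(self.two_theta) <= 0):
            raise ValueError("2θ grid must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class ClusterMatch:
    matched: bool
    n_matched: int
    rmsd: float | None   # Å; RMSD_n of the superposed clusters when matched

    @property
    def rmsd_n(self):
        return self.rmsd


def simulate_pxrd(crystal, config: CompareConfig | None = None) -> PowderPattern:
    """Simulated powder pattern from the reciprocal lattice.

    Bragg positions follow 2θ = 2·asin(λ/2d); intensities are |F|² with
    atomic form factors approximated by the atomic number (sufficient for
    similarity screening, not for Rietveld-grade patterns); peaks are
    broadened with a fixed-width pseudo-Voigt and the pattern is
    max-normalised.
    """
    config = config or CompareConfig()
    lam = config.wavelength
    M = crystal.cell.matrix
    Minv = np.linalg.inv(M)
    images = crystal.images(check=False)
    frac = np.concatenate([img.frac for img in images])          # (N, 3)
    Z = np.array(
        [ATOMIC_NUMBERS[e] for e in crystal.molecule.elements] * len(images),
        dtype=float,
    )
    theta_max = np.radians(config.two_theta_max / 2.0)
    d_min = lam / (2.0 * np.sin(theta_max))
    hmax = np.ceil(np.linalg.norm(M, axis=1) / d_min).astype(int) + 1
    hr = [np.arange(-h, h + 1) for h in hmax]
    H = np.stack(np.meshgrid(*hr, indexing="ij"), axis=-1).reshape(-1, 3)
    H = H[np.any(H != 0, axis=1)]
    q = H @ Minv                                                  # rows: 1/d
    inv_d = np.linalg.norm(q, axis=1)
    sel = (inv_d > 1e-9) & (lam * inv_d / 2.0 < np.sin(theta_max))
    H = H[sel]
    inv_d = inv_d[sel]
    two_theta = 2.0 * np.degrees(np.arcsin(lam * inv_d / 2.0))
    keep = two_theta >= config.two_theta_min
    H, two_theta = H[keep], two_theta[keep]
    phase = 2.0 * np.pi * H @ frac.T
    F = (Z[None, :] * np.exp(1j * phase)).sum(axis=1)
    I = np.abs(F) ** 2
    if config.lorentz_polarization:
        th = np.radians(two_theta / 2.0)
        I = I * (1 + np.cos(2 * th) ** 2) / (np.sin(th) ** 2 * np.cos(th))
    grid = np.arange(config.two_theta_min, config.two_theta_max + 1e-9,
                     config.two_theta_step)
    # fixed-width pseudo-Voigt (η = 0.5), vectorised over peaks
    fwhm = config.peak_fwhm
    sig = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    gam = fwhm / 2.0
    strong = I > I.max() * 1e-6 if I.size else np.zeros(0, dtype=bool)
    tt = two_theta[strong]
    ii = I[strong]
    if tt.size:
        d = grid[None, :] - tt[:, None]
        prof = 0.5 * np.exp(-0.5 * (d / sig) ** 2) + \
            0.5 * gam**2 / (d**2 + gam**2)
        y = prof.T @ ii
    else:
        y = np.zeros_like(grid)
    if y.max() > 0:
        y = y / y.max()
    return PowderPattern(grid, y, lam)


def pxrd_similarity(p: PowderPattern, q: PowderPattern,
                    config: CompareConfig | None = None) -> float:
    """Normalised de Gelder-style weighted cross-correlation in [0, 1].

    Symmetric, invariant to intensity scaling; 1 for identical patterns and
    ≈ 0 for patterns with no peaks within the triangle-weighting window of
    each other.
    """
    config = config or CompareConfig()
    if p.two_theta.shape != q.two_theta.shape or \
            not np.allclose(p.two_theta, q.two_theta):
        raise ValueError("patterns are on different 2θ grids")
    step = float(p.two_theta[1] - p.two_theta[0])
    L = int(round(config.triangle_width / step))
    w = 1.0 - np.abs(np.arange(-L, L + 1)) * step / config.triangle_width

    def wcorr(a, b):
        n = a.size
        tot = 0.0
        for k, lag in enumerate(range(-L, L + 1)):
            if lag >= 0:
                tot += w[k] * float(a[: n - lag] @ b[lag:])
            else:
                tot += w[k] * float(a[-lag:] @ b[: n + lag])
        return tot

    cpq = wcorr(p.intensity, q.intensity)
    cpp = wcorr(p.intensity, p.intensity)
    cqq = wcorr(q.intensity, q.intensity)
    if cpp <= 0 or cqq <= 0:
        return 0.0
    return float(np.clip(cpq / np.sqrt(cpp * cqq), 0.0, 1.0))


# ---------------------------------------------------------------------------
# COMPACK-style cluster matching


def _molecule_cluster(crystal, n: int, central_op: int = 0):
    """Coordinates of the ``n`` molecules nearest the chosen central image
    (central first), each as an (n_atoms, 3) block with consistent atom
    order."""
    images = crystal.images(check=False)
    M = crystal.cell.matrix
    cell_coords = np.stack([img.cart for img in images])       # (nb, na, 3)
    centroids = cell_coords.mean(axis=1)
    nb = len(images)
    # enough whole cells to surround the cluster
    v_mol = crystal.cell.volume / nb
    r_cluster = ((3.0 * n * v_mol) / (4.0 * np.pi)) ** (1.0 / 3.0)
    reach = 2.0 * r_cluster + 2.0 * crystal.molecule.radius + 2.0
    Minv = np.linalg.inv(M)
    spacing = 1.0 / np.linalg.norm(Minv, axis=0)
    nmax = np.ceil(reach / spacing).astype(int) + 1
    rng = [np.arange(-k, k + 1) for k in nmax]
    grid = np.stack(np.meshgrid(*rng, indexing="ij"), axis=-1).reshape(-1, 3)
    tvecs = grid @ M
    all_coords = (cell_coords[None, :, :, :] + tvecs[:, None, None, :]).reshape(-1, cell_coords.shape[1], 3)
    all_cen = centroids[None, :, :] + tvecs[:, None, :]
    all_cen = all_cen.reshape(-1, 3)
    zero_t = (grid.shape[0] - 1) // 2
    central_idx = zero_t * nb + central_op
    d = np.linalg.norm(all_cen - all_cen[central_idx], axis=1)
    order = np.lexsort((np.arange(d.size), np.round(d, 8)))
    pick = order[:n]
    # central molecule first
    pick = np.concatenate(([central_idx], pick[pick != central_idx]))[:n]
    return all_coords[pick], all_cen[pick]


def cluster_match(a, b, config: CompareConfig | None = None,
                  n: int | None = None) -> ClusterMatch:
    """COMPACK-style n-molecule cluster comparison.

    A cluster around a central molecule of ``a`` is compared against
    clusters around every distinct symmetry image of ``b``; molecules are
    paired by centroid assignment after aligning the central molecules, and
    a pair is accepted when the centroid distances agree within the
    fractional tolerance and the molecular orientations within the angle
    tolerance.  If all n molecules pair, the match is confirmed and the
    all-atom RMSD of the jointly superposed clusters is reported.
    """
    config = config or CompareConfig()
    if n is None:
        n = config.n_molecules
    mol_a, mol_b = a.molecule, b.molecule
    if mol_a.n_atoms != mol_b.n_atoms or mol_a.elements != mol_b.elements:
        raise ValueError("structures contain different molecules")
    coords_a, cen_a = _molecule_cluster(a, n, 0)
    rel_a = cen_a - cen_a[0]
    da = np.linalg.norm(rel_a, axis=1)
    # linear molecules leave the rotation about their axis undefined, so the
    # orientation-angle criterion is meaningless; the superposition residual
    # then carries the whole test
    svals = np.linalg.svd(mol_a.local_coords, compute_uv=False)
    check_angle = svals[1] > 1e-6
    best = ClusterMatch(False, 0, None)

    def evaluate(coords_b, cen_b, R):
        """Pairing + tolerance checks for one candidate alignment matrix."""
        rel_b = (cen_b - cen_b[0]) @ R.T
        cost = np.linalg.norm(rel_a[:, None, :] - rel_b[None, :, :], axis=2)
        ra, rb = linear_sum_assignment(cost)
        ok = 0
        pairs = []
        for i, j in zip(ra, rb):
            tol = config.distance_tol * max(da[i], 1.0) + 1e-6
            if cost[i, j] > tol:
                continue
            # orientation misfit between the paired molecules
            ma = coords_a[i] - coords_a[i].mean(axis=0)
            mb = (coords_b[j] - coords_b[j].mean(axis=0)) @ R.T
            rrel = kabsch_rotation(ma, mb)
            ang = np.degrees(rrel.magnitude()) if check_angle else 0.0
            resid2 = ma - rrel.apply(mb)
            if ang > config.angle_tol or \
                    np.sqrt((resid2**2).sum(axis=1).mean()) > config.pair_rmsd_tol:
                continue
            ok += 1
            pairs.append((i, j))
        return ok, pairs

    for central_op in range(len(b.group.operations)):
        coords_b, cen_b = _molecule_cluster(b, n, central_op)
        # align central molecules (proper rotations only)
        ca = coords_a[0] - coords_a[0].mean(axis=0)
        cb = coords_b[0] - coords_b[0].mean(axis=0)
        rot = kabsch_rotation(ca, cb)
        resid = ca - rot.apply(cb)
        if np.sqrt((resid**2).sum(axis=1).mean()) > config.pair_rmsd_tol:
            continue  # e.g. opposite handedness of a chiral molecule
        if check_angle:
            candidates = [rot.as_matrix()]
        else:
            # a linear central molecule leaves a free rotation about its
            # axis: scan it and let the cluster centroids decide
            u, _, _ = np.linalg.svd(ca.T @ ca)
            axis = u[:, 0]
            candidates = [
                (Rotation.from_rotvec(axis * phi) * rot).as_matrix()
                for phi in np.linspace(0.0, 2.0 * np.pi, 73)[:-1]
            ]
        for R in candidates:
            ok, pairs = evaluate(coords_b, cen_b, R)
            if ok == n:
                stack_a = np.concatenate([coords_a[i] for i, _ in pairs])
                stack_b = np.concatenate([coords_b[j] for _, j in pairs])
                aa = stack_a - stack_a.mean(axis=0)
                bb = stack_b - stack_b.mean(axis=0)
                rfull = kabsch_rotation(aa, bb)
                diff = aa - rfull.apply(bb)
                rmsd = float(np.sqrt((diff**2).sum(axis=1).mean()))
                if not best.matched or rmsd < best.rmsd:
                    best = ClusterMatch(True, n, rmsd)
            elif not best.matched and ok > best.n_matched:
                best = ClusterMatch(False, ok, None)
    return best


# ---------------------------------------------------------------------------
# landscape deduplication


def deduplicate(structures: list[MinimizedCrystal],
                config: CompareConfig | None = None):
    """Collapse duplicate minima.

    PXRD similarity ≥ threshold nominates candidate pairs (optionally
    prefiltered by an energy window); cluster matching at the dedup cluster
    size confirms them; connected components are merged.  The representative
    of each component is the lowest-energy member (ties: higher density,
    then input order) and the survivors are returned sorted by energy,
    together with a cluster label per input structure.
    """
    config = config or CompareConfig()
    k = len(structures)
    if k == 0:
        return [], []
    patterns = [simulate_pxrd(s, config) for s in structures]
    energies = np.array([s.e_latt for s in structures])

    parent = list(range(k))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i in range(k):
        for j in range(i + 1, k):
            if config.energy_window is not None and \
                    abs(energies[i] - energies[j]) > config.energy_window:
                continue
            if find(i) == find(j):
                continue
            if pxrd_similarity(patterns[i], patterns[j], config) < config.pxrd_threshold:
                continue
            m = cluster_match(structures[i], structures[j], config,
                              n=config.dedup_n)
            if m.matched:
                union(i, j)

    labels = [find(i) for i in range(k)]
    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)

    reps = []
    for lab, members in groups.items():
        ms = sorted(
            members,
            key=lambda i: (round(energies[i], 9), -structures[i].density, i),
        )
        reps.append(ms[0])
    reps.sort(key=lambda i: (energies[i], i))
    unique = [structures[i] for i in reps]
    # relabel components by their representative's output position
    rep_pos = {find(i): pos for pos, i in enumerate(reps)}
    labels = [rep_pos[find(i)] for i in range(k)]
    return unique, labels
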