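"""Committee Δ-ML lattice-energy correction with query-by-committee
active learning.

The correction target is ΔE = E_highlevel − E_FF per molecule: instead of
learning absolute lattice energies, a committee of regressors learns the
*difference* between the cheap force-field energy and a higher-level
reference, on rotation/translation/permutation-invariant atom-centred
symmetry-function (ACSF) descriptors of the crystal environment.  The
committee mean is the predicted correction and the committee standard
deviation its uncertainty, which drives query-by-committee selection of
new training structures and the exclusion of unreliable predictions when
re-ranking landscapes.

The committee is sklearn-style: ``CorrectionModel.fit(dataset)`` /
``predict(crystal)``; members are small MLP regressors on per-molecule
sum-pooled, element-resolved descriptors, diversified by bootstrap
resampling and seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

from .analysis import Landscape
from .crystal import MinimizedCrystal

__all__ = [
    "DescriptorConfig",
    "CorrectionDataset",
    "CorrectionModel",
    "CorrectionPrediction",
    "featurize",
    "pooled_descriptor",
    "build_dataset",
    "train_committee",
    "predict",
    "active_learning_round",
    "corrected_landscape",
]

_ELEMENTS = ("C", "H", "N", "O", "F")


@dataclass(frozen=True)
class DescriptorConfig:
    """ACSF hyperparameters.

    Radial G2 functions use Gaussians at ``n_radial`` centres spread from
    ``r_min`` to the cutoff (one channel per neighbour element); angular
    G4-style functions use a small (ζ, λ) grid summed over all neighbour
    pairs.  Everything is smoothly cut off by ½(cos(πr/rc)+1).
    """

    cutoff: float = 6.0
    n_radial: int = 6
    r_min: float = 1.0
    eta: float = 4.0            # Å⁻², radial Gaussian width parameter
    zetas: tuple = (1.0, 4.0)
    lambdas: tuple = (1.0, -1.0)
    eta_ang: float = 0.05       # Å⁻², angular radial damping

    def __post_init__(self):
        if self.cutoff <= 0 or self.n_radial < 1:
            raise ValueError("invalid descriptor grid")

    @property
    def n_features(self) -> int:
        return len(_ELEMENTS) * self.n_radial + len(self.zetas) * len(self.lambdas)


def _cutoff_fn(r, rc):
    return np.where(r < rc, 0.5 * (np.cos(np.pi * r / rc) + 1.0), 0.0)


def _neighbour_environment(crystal, cutoff: float):
    """For each asymmetric-unit atom: neighbour vectors (periodic images
    included) and neighbour elements within the cutoff."""
    from .energy import _translation_grid

    mol = crystal.molecule
    M = crystal.cell.matrix
    images = crystal.images(check=False)
    base = np.concatenate([img.cart for img in images])
    elems = mol.elements * len(images)
    r_g = float(np.linalg.norm(mol.local_coords, axis=1).max())
    grid = _translation_grid(crystal.cell, cutoff + 2.0 * r_g)
    tvecs = grid @ M
    pos = (base[None, :, :] + tvecs[:, None, :]).reshape(-1, 3)
    elems_all = np.array(elems * grid.shape[0])
    probe = images[0].cart
    out = []
    for i in range(mol.n_atoms):
        d = pos - probe[i]
        r2 = np.einsum("ik,ik->i", d, d)
        sel = (r2 > 1e-12) & (r2 <= cutoff * cutoff)
        out.append((d[sel], np.sqrt(r2[sel]), elems_all[sel]))
    return out


def featurize(crystal, config: DescriptorConfig | None = None) -> np.ndarray:
    """Per-atom ACSF descriptor matrix (n_atoms, n_features).

    Invariant to rigid motions of the crystal and to permutations of
    identical atoms; periodic neighbours are included.
    """
    config = config or DescriptorConfig()
    env = _neighbour_environment(crystal, config.cutoff)
    centres = np.linspace(config.r_min, config.cutoff, config.n_radial)
    feats = np.zeros((len(env), config.n_features))
    for i, (vec, r, el) in enumerate(env):
        fc = _cutoff_fn(r, config.cutoff)
        col = 0
        for e in _ELEMENTS:
            mask = el == e
            if np.any(mask):
                g = np.exp(-config.eta * (r[mask, None] - centres[None, :]) ** 2)
                feats[i, col : col + config.n_radial] = (g * fc[mask, None]).sum(axis=0)
            col += config.n_radial
        # angular terms over neighbour pairs (element-agnostic)
        if r.size >= 2:
            u = vec / r[:, None]
            cos = np.clip(u @ u.T, -1.0, 1.0)
            rad = np.exp(-config.eta_ang * (r[:, None] ** 2 + r[None, :] ** 2))
            w = np.outer(fc, fc) * rad
            iu = np.triu_indices(r.size, k=1)
            cu, wu = cos[iu], w[iu]
            for z in config.zetas:
                for lam in config.lambdas:
                    feats[i, col] = float(
                        np.sum(2.0 ** (1.0 - z) * (1.0 + lam * cu) ** z * wu)
                    )
                    col += 1
    return feats


_POOLED_CACHE: dict = {}


def pooled_descriptor(crystal, config: DescriptorConfig | None = None) -> np.ndarray:
    """Per-molecule descriptor: per-atom features sum-pooled over the
    asymmetric unit (additive in atomic contributions by construction; the
    neighbour-element channels already resolve composition).

    Cached per (structure id, descriptor config): descriptors of a given
    crystal are immutable."""
    config = config or DescriptorConfig()
    key = (crystal.structure_id, config)
    hit = _POOLED_CACHE.get(key)
    if hit is not None:
        return hit
    out = featurize(crystal, config).sum(axis=0)
    if len(_POOLED_CACHE) > 20000:
        _POOLED_CACHE.clear()
    _POOLED_CACHE[key] = out
    return out


@dataclass
class CorrectionDataset:
    """Training data for the Δ-ML correction.

    ``split``: 'train', 'test' (in-domain) or 'extrapolation' (compounds
    never seen in training)."""

    crystals: list
    targets: np.ndarray            # kJ/mol per molecule
    compounds: list[str]
    split: list[str]
    features: np.ndarray | None = None

    def __len__(self):
        return len(self.crystals)

    def subset(self, which: str):
        idx = [i for i, s in enumerate(self.split) if s == which]
        return idx


@dataclass(frozen=True)
class CorrectionPrediction:
    delta_e: float     # committee mean, kJ/mol
    sigma: float       # committee standard deviation, kJ/mol


class CorrectionModel:
    """Committee of descriptor-based regressors (default 8 members)."""

    def __init__(self, descriptor: DescriptorConfig | None = None,
                 n_members: int = 8, hidden: tuple = (64,),
                 max_iter: int = 800, seed: int = 0, diversify: bool = True):
        if n_members < 2:
            raise ValueError("a committee needs at least 2 members")
        self.descriptor = descriptor or DescriptorConfig()
        self.n_members = n_members
        self.hidden = hidden
        self.max_iter = max_iter
        self.seed = seed
        self.diversify = diversify  # False → identical members (σ ≡ 0)
        self.members_: list | None = None
        self.scaler_: StandardScaler | None = None
        self.y_mean_: float = 0.0
        self.y_std_: float = 1.0
        self.metrics_: dict = {}

    # -- sklearn-style interface ------------------------------------------
    def fit(self, dataset: CorrectionDataset) -> "CorrectionModel":
        tr = dataset.subset("train")
        if len(tr) < 10:
            raise ValueError("need at least 10 training records")
        X = self._features(dataset)
        Xtr, ytr = X[tr], dataset.targets[tr]
        self.scaler_ = StandardScaler().fit(Xtr)
        self.y_mean_ = float(ytr.mean())
        self.y_std_ = float(ytr.std())
        degenerate = self.y_std_ < 1e-12
        Xs = self.scaler_.transform(Xtr)
        ys = np.zeros_like(ytr) if degenerate else (ytr - self.y_mean_) / self.y_std_
        rng = np.random.default_rng(self.seed)
        self.members_ = []
        for m in range(self.n_members):
            if self.diversify:
                boot = rng.integers(0, len(tr), size=len(tr))
                state = int(self.seed + 1000 * m + 17) % (2**31)
            else:
                boot = np.arange(len(tr))
                state = int(self.seed) % (2**31)
            net = MLPRegressor(
                hidden_layer_sizes=self.hidden, solver="lbfgs",
                alpha=1e-4, max_iter=self.max_iter,
                random_state=state,
            )
            with warnings.catch_warnings():
                from sklearn.exceptions import ConvergenceWarning

                warnings.simplefilter("ignore", ConvergenceWarning)
                net.fit(Xs[boot], ys[boot])
            self.members_.append(net)
        # error report on the three splits
        self.metrics_ = {}
        for which in ("train", "test", "extrapolation"):
            idx = dataset.subset(which)
            if idx:
                pred = self._predict_features(X[idx])[0]
                self.metrics_[f"mae_{which}"] = float(
                    np.mean(np.abs(pred - dataset.targets[idx]))
                )
        return self

    def _features(self, dataset: CorrectionDataset) -> np.ndarray:
        if dataset.features is None:
            dataset.features = np.stack(
                [pooled_descriptor(c, self.descriptor) for c in dataset.crystals]
            )
        return dataset.features

    def _predict_features(self, X: np.ndarray):
        if self.members_ is None:
            raise RuntimeError("model is not fitted")
        Xs = self.scaler_.transform(X)
        preds = np.stack([m.predict(Xs) for m in self.members_])
        preds = preds * (self.y_std_ if self.y_std_ > 1e-12 else 0.0) + self.y_mean_
        return preds.mean(axis=0), preds.std(axis=0)

    def predict(self, crystal) -> CorrectionPrediction:
        X = pooled_descriptor(crystal, self.descriptor)[None, :]
        mean, std = self._predict_features(X)
        return CorrectionPrediction(float(mean[0]), float(std[0]))

    def predict_many(self, crystals) -> list[CorrectionPrediction]:
        X = np.stack([pooled_descriptor(c, self.descriptor) for c in crystals])
        mean, std = self._predict_features(X)
        return [CorrectionPrediction(float(m), float(s)) for m, s in zip(mean, std)]

    def get_params(self, deep: bool = True) -> dict:
        return {
            "descriptor": self.descriptor,
            "n_members": self.n_members,
            "hidden": self.hidden,
            "max_iter": self.max_iter,
            "seed": self.seed,
            "diversify": self.diversify,
        }

    def set_params(self, **params) -> "CorrectionModel":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self


def build_dataset(landscapes: list[Landscape], oracle, per_compound_n: int = 10,
                  window: float = 8.0, seed: int = 0,
                  train_fraction: float = 0.85) -> CorrectionDataset:
    """Sample low-energy structures per landscape and label them.

    Up to ``per_compound_n`` structures are drawn uniformly from within
    ``window`` kJ/mol of each landscape's global minimum; targets are
    ΔE = oracle(crystal) − E_FF.  Compounds are split ~``train_fraction``
    train / rest extrapolation (at least one extrapolation compound), and
    one structure per training compound is withheld as an in-domain test
    set.
    """
    rng = np.random.default_rng(seed)
    crystals, targets, compounds = [], [], []
    per_compound: dict[str, list[int]] = {}
    for ls in landscapes:
        if len(ls) == 0 or per_compound_n == 0:
            continue
        ref = ls.global_minimum.e_latt
        pool = [s for s in ls if s.e_latt - ref <= window]
        if not pool:
            continue
        take = min(per_compound_n, len(pool))
        pick = rng.choice(len(pool), size=take, replace=False)
        for i in pick:
            s = pool[i]
            crystals.append(s)
            targets.append(oracle(s) - s.e_latt)
            compounds.append(ls.molecule_name)
            per_compound.setdefault(ls.molecule_name, []).append(len(crystals) - 1)

    names = sorted(per_compound)
    if not names:
        return CorrectionDataset([], np.zeros(0), [], [])
    n_train = max(int(np.floor(train_fraction * len(names))), 0)
    if len(names) > 1:
        n_train = min(n_train, len(names) - 1)  # ≥ 1 extrapolation compound
    order = rng.permutation(len(names))
    train_names = {names[i] for i in order[:n_train]}
    split = ["extrapolation"] * len(crystals)
    for name in train_names:
        members = per_compound[name]
        held = members[int(rng.integers(len(members)))] if len(members) > 1 else None
        for i in members:
            split[i] = "test" if i == held else "train"
    return CorrectionDataset(crystals, np.array(targets), compounds, split)


def train_committee(dataset: CorrectionDataset,
                    descriptor: DescriptorConfig | None = None,
                    n_members: int = 8, seed: int = 0, **kw) -> CorrectionModel:
    """Fit a fresh committee on the dataset (deterministic given the seed)."""
    model = CorrectionModel(descriptor=descriptor, n_members=n_members,
                            seed=seed, **kw)
    return model.fit(dataset)


def predict(model: CorrectionModel, crystal) -> CorrectionPrediction:
    return model.predict(crystal)


def active_learning_round(model: CorrectionModel, pool: list, budget: int):
    """Query-by-committee: the ``budget`` pool structures with the highest
    committee disagreement (ties broken by structure id)."""
    if budget <= 0 or not pool:
        return []
    preds = model.predict_many(pool)
    order = sorted(
        range(len(pool)),
        key=lambda i: (-preds[i].sigma, pool[i].structure_id),
    )
    return [pool[i] for i in order[: min(budget, len(pool))]]


def corrected_landscape(landscape: Landscape, model: CorrectionModel,
                        sigma_cap: float = 25.0):
    """Re-rank a landscape on E_corr = E_FF + ΔE_pred.

    Structures with committee uncertainty above ``sigma_cap`` (kJ/mol) are
    excluded from the ranking.  Returns the re-ranked structure list (with
    corrected energies) and the per-structure predictions.
    """
    if len(landscape) == 0:
        raise ValueError("empty landscape")
    preds = model.predict_many(landscape.structures)
    kept = [
        (s, p) for s, p in zip(landscape.structures, preds) if p.sigma <= sigma_cap
    ]
    if not kept:
        raise ValueError("all structures excluded by the uncertainty cap")
    ranked = sorted(kept, key=lambda sp: sp[0].e_latt + sp[1].delta_e)
    e_corr = np.array([s.e_latt + p.delta_e for s, p in ranked])
    return {
        "structures": [s for s, _ in ranked],
        "e_corr": e_corr,
        "delta_e": e_corr - e_corr[0],
        "predictions": [p for _, p in ranked],
        "n_excluded": len(landscape) - len(kept),
    }
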