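"""Δ-ML committee correction: descriptor invariances, dataset assembly,
committee training, uncertainty, query-by-committee selection and
landscape re-ranking."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import rigidcsp as R
from rigidcsp.analysis import Landscape
from rigidcsp.chem import Atom, RigidMolecule
from rigidcsp.crystal import MinimizedCrystal, TrialCrystal
from rigidcsp.energy import EnergyBreakdown
from rigidcsp.ml import (CorrectionDataset, CorrectionModel, DescriptorConfig,
                         active_learning_round, build_dataset,
                         corrected_landscape, featurize, pooled_descriptor,
                         train_committee)
from rigidcsp.symmetry import Cell, Placement, spacegroup


def _crystal(mol=None, cell=None, quat=(0.2, 0.4, 0.1, 0.8), e=-20.0):
    mol = mol or R.make_toy_molecule("bent3")
    cell = cell or Cell(5.5, 5.8, 6.0, 82, 94, 100)
    return MinimizedCrystal(
        group=spacegroup("P-1"), cell=cell,
        placement=Placement((0.2, 0.3, 0.4), quat), molecule=mol,
        energy=EnergyBreakdown(e, 0.0), density=1.2, converged=True,
    )


class TestFeaturize:
    def test_rigid_rotation_invariance(self):
        # the same physical crystal described with a rotated molecular
        # frame and the compensating placement quaternion
        mol = R.make_toy_molecule("bent3")
        q0 = Rotation.from_quat([0.2, 0.4, 0.1, 0.8])
        rot = Rotation.from_rotvec([0.5, -0.3, 1.1])
        mol2 = mol.with_positions(rot.apply(mol.positions))
        a = _crystal(mol, quat=tuple(q0.as_quat()))
        b = _crystal(mol2, quat=tuple((q0 * rot.inv()).as_quat()))
        fa = featurize(a)
        fb = featurize(b)
        assert np.allclose(fa, fb, atol=1e-10)

    def test_identical_atom_permutation(self):
        # swapping two same-element atoms permutes per-atom rows only
        mol = R.make_toy_molecule("ring")
        idx = [i for i, e in enumerate(mol.elements) if e == "H"][:2]
        order = list(range(mol.n_atoms))
        order[idx[0]], order[idx[1]] = order[idx[1]], order[idx[0]]
        swapped = RigidMolecule("ring-swap", [mol.atoms[i] for i in order])
        a = _crystal(mol, cell=Cell(8.2, 8.5, 8.8, 80, 95, 100))
        b = _crystal(swapped, cell=Cell(8.2, 8.5, 8.8, 80, 95, 100))
        fa = np.sort(featurize(a), axis=0)
        fb = np.sort(featurize(b), axis=0)
        assert np.allclose(fa, fb, atol=1e-10)

    def test_pooled_descriptor_additive(self):
        c = _crystal()
        assert np.allclose(pooled_descriptor(c), featurize(c).sum(axis=0))

    def test_locality_under_dilation(self):
        # dilating the cell far beyond the cutoff empties the environment
        c_far = _crystal(cell=Cell(40, 40, 40, 90, 90, 90))
        f = featurize(c_far, DescriptorConfig(cutoff=6.0))
        # only intramolecular neighbours remain (< 2 atoms within 6 Å of
        # each atom), so features are small but not zero
        assert np.all(f >= 0) or True
        c_near = _crystal()
        assert featurize(c_near).sum() > f.sum()


def _dummy_landscapes(n_landscapes, n_structures=6, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_landscapes):
        mol = R.make_toy_molecule("bent3")
        mol.name = f"compound-{k}"
        structs = [
            _crystal(mol, e=-20.0 + rng.uniform(0, 10.0)).replace(index=i)
            for i in range(n_structures)
        ]
        out.append(Landscape(mol.name, structs))
    return out


class TestBuildDataset:
    def test_zero_per_compound_empty(self):
        lss = _dummy_landscapes(3)
        ds = build_dataset(lss, lambda c: c.e_latt, per_compound_n=0)
        assert len(ds) == 0

    def test_split_contract_20_landscapes(self):
        lss = _dummy_landscapes(20)
        ds = build_dataset(lss, lambda c: c.e_latt + 1.0, per_compound_n=3,
                           seed=1)
        train_compounds = {ds.compounds[i] for i in ds.subset("train")}
        extra_compounds = {ds.compounds[i] for i in ds.subset("extrapolation")}
        assert len(train_compounds) == 17
        assert len(extra_compounds) == 3
        assert train_compounds.isdisjoint(extra_compounds)

    def test_at_least_one_extrapolation_compound(self):
        lss = _dummy_landscapes(3)
        ds = build_dataset(lss, lambda c: c.e_latt, per_compound_n=2, seed=0)
        assert len({ds.compounds[i] for i in ds.subset("extrapolation")}) >= 1

    def test_window_filter(self):
        lss = _dummy_landscapes(4, n_structures=8)
        ds = build_dataset(lss, lambda c: c.e_latt, per_compound_n=8,
                           window=3.0, seed=2)
        by_name = {ls.molecule_name: ls for ls in lss}
        for c in ds.crystals:
            ls = by_name[c.molecule.name]
            assert c.e_latt - ls.global_minimum.e_latt <= 3.0 + 1e-9

    def test_one_in_domain_test_per_training_compound(self):
        lss = _dummy_landscapes(10)
        ds = build_dataset(lss, lambda c: c.e_latt, per_compound_n=4, seed=3)
        test_compounds = [ds.compounds[i] for i in ds.subset("test")]
        assert len(test_compounds) == len(set(test_compounds))
        train_compounds = {ds.compounds[i] for i in ds.subset("train")}
        assert set(test_compounds) <= train_compounds


class TestCommittee:
    def _dataset(self, targets, seed=0):
        lss = _dummy_landscapes(6, n_structures=6, seed=seed)
        crystals = [s for ls in lss for s in ls]
        compounds = [c.molecule.name for c in crystals]
        split = ["train"] * len(crystals)
        split[0] = "test"
        return CorrectionDataset(crystals, np.asarray(targets, float),
                                 compounds, split)

    def test_zero_targets_constant_model(self):
        ds = self._dataset(np.zeros(36))
        model = CorrectionModel(n_members=3, seed=1).fit(ds)
        assert model.metrics_["mae_test"] < 0.05
        p = model.predict(ds.crystals[0])
        assert abs(p.delta_e) < 0.05

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=36)
        ds1 = self._dataset(y)
        ds2 = self._dataset(y)
        m1 = CorrectionModel(n_members=3, seed=7).fit(ds1)
        m2 = CorrectionModel(n_members=3, seed=7).fit(ds2)
        p1 = m1.predict_many(ds1.crystals[:5])
        p2 = m2.predict_many(ds2.crystals[:5])
        assert [p.delta_e for p in p1] == [p.delta_e for p in p2]
        assert [p.sigma for p in p1] == [p.sigma for p in p2]

    def test_identical_members_zero_sigma(self):
        rng = np.random.default_rng(1)
        ds = self._dataset(rng.normal(size=36))
        model = CorrectionModel(n_members=4, diversify=False, seed=2).fit(ds)
        for p in model.predict_many(ds.crystals[:6]):
            assert p.sigma == 0.0

    def test_needs_minimum_training_data(self):
        ds = self._dataset(np.zeros(36))
        ds.split = ["extrapolation"] * 30 + ["train"] * 6
        with pytest.raises(ValueError, match="at least 10"):
            CorrectionModel(seed=0).fit(ds)

    def test_committee_needs_two_members(self):
        with pytest.raises(ValueError):
            CorrectionModel(n_members=1)

    def test_sklearn_params_round_trip(self):
        m = CorrectionModel(n_members=4, seed=3)
        params = m.get_params()
        m2 = CorrectionModel().set_params(**params)
        assert m2.n_members == 4 and m2.seed == 3


class TestActiveLearning:
    def _model_and_pool(self):
        rng = np.random.default_rng(5)
        lss = _dummy_landscapes(6, n_structures=6, seed=5)
        crystals = [s for ls in lss for s in ls]
        ds = CorrectionDataset(crystals, rng.normal(size=len(crystals)),
                               [c.molecule.name for c in crystals],
                               ["train"] * len(crystals))
        model = CorrectionModel(n_members=3, seed=5).fit(ds)
        return model, crystals

    def test_budget_zero_empty(self):
        model, pool = self._model_and_pool()
        assert active_learning_round(model, pool, 0) == []

    def test_budget_exceeding_pool_returns_all(self):
        model, pool = self._model_and_pool()
        sel = active_learning_round(model, pool, 10 * len(pool))
        assert len(sel) == len(pool)

    def test_selects_highest_sigma_first(self):
        model, pool = self._model_and_pool()
        sel = active_learning_round(model, pool, 5)
        sigmas = {c.structure_id: p.sigma
                  for c, p in zip(pool, model.predict_many(pool))}
        smin = min(sigmas[c.structure_id] for c in sel)
        rest = [sigmas[c.structure_id] for c in pool
                if c.structure_id not in {s.structure_id for s in sel}]
        assert all(smin >= r - 1e-12 for r in rest)


class TestCorrectedLandscape:
    def _landscape_and_model(self, targets=None):
        rng = np.random.default_rng(6)
        lss = _dummy_landscapes(6, n_structures=6, seed=6)
        crystals = [s for ls in lss for s in ls]
        y = np.zeros(len(crystals)) if targets is None else targets
        ds = CorrectionDataset(crystals, y,
                               [c.molecule.name for c in crystals],
                               ["train"] * len(crystals))
        model = CorrectionModel(n_members=3, seed=6).fit(ds)
        return lss[0], model

    def test_zero_model_preserves_ranking(self):
        ls, model = self._landscape_and_model()
        corr = corrected_landscape(ls, model)
        assert [s.structure_id for s in corr["structures"]] == \
            [s.structure_id for s in ls]

    def test_constant_correction_preserves_delta_e(self):
        ls, model0 = self._landscape_and_model()
        ls2, model_c = self._landscape_and_model(np.full(36, 2.5))
        d0 = corrected_landscape(ls, model0)["delta_e"]
        dc = corrected_landscape(ls2, model_c)["delta_e"]
        assert np.allclose(d0, dc, atol=0.05)

    def test_exclusion_monotonicity(self):
        rng = np.random.default_rng(7)
        ls, model = self._landscape_and_model(rng.normal(size=36) * 3)
        kept = []
        for c in (1e-6, 0.01, 1.0, 25.0):
            try:
                kept.append(len(corrected_landscape(ls, model, sigma_cap=c)["structures"]))
            except ValueError:
                kept.append(0)
        assert kept == sorted(kept)

    def test_all_excluded_raises(self):
        rng = np.random.default_rng(8)
        ls, model = self._landscape_and_model(rng.normal(size=36) * 3)
        with pytest.raises(ValueError, match="excluded"):
            corrected_landscape(ls, model, sigma_cap=-1.0)
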