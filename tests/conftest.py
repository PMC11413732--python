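"""Shared fixtures: toy molecules, planted references and small landscapes.

Expensive artefacts (planted reference crystals, the six-compound
landscape suite) are session-scoped so the whole suite pays for them
once.  Everything is generated programmatically and deterministically.
"""

import numpy as np
import pytest

import rigidcsp as R
import rigidcsp.analysis as analysis
import rigidcsp.minimize as minimize
import rigidcsp.synthetic as synthetic


@pytest.fixture(scope="session")
def toy_ff():
    return R.TOY_FORCE_FIELD


@pytest.fixture
def bent3():
    return R.make_toy_molecule("bent3")


@pytest.fixture
def diatomic():
    return R.make_toy_molecule("diatomic")


@pytest.fixture
def chiral5():
    return R.make_toy_molecule("chiral5")


@pytest.fixture(scope="session")
def toy_sched():
    return minimize.toy_schedule()


@pytest.fixture(scope="session")
def p21_reference(toy_ff):
    """Planted reference crystal: bent triatomic in P21 (Sohncke)."""
    mol = R.make_toy_molecule("bent3")
    return synthetic.plant_reference(mol, "P21", seed=100, n_valid=60)


@pytest.fixture(scope="session")
def pminus1_reference(toy_ff):
    """Planted reference crystal: bent triatomic in P-1 (racemic)."""
    mol = R.make_toy_molecule("bent3")
    return synthetic.plant_reference(mol, "P-1", seed=100, n_valid=60)


@pytest.fixture(scope="session")
def small_landscape(toy_ff):
    """A small deduplicated P-1 landscape of the bent triatomic."""
    mol = R.make_toy_molecule("bent3")
    structs = synthetic.run_csp(mol, ["P-1"], n_valid=20, seed=3)
    unique, _ = R.deduplicate(structs)
    return analysis.Landscape(mol.name, unique)


SUITE_SPECS = [("bent3", 1.0), ("planar4", 1.0), ("diatomic", 1.0),
               ("chiral5", 1.0), ("bent3", 0.6), ("planar4", 1.4)]


@pytest.fixture(scope="session")
def six_landscapes():
    """Six-compound landscape suite (the Δ-ML study conditions)."""
    out = []
    for template, cs in SUITE_SPECS:
        mol = synthetic.make_toy_molecule(
            synthetic.ToyMoleculeSpec(template, charge_scale=cs))
        if cs != 1.0:
            mol.name = f"{template}-cs{cs}"
        structs = synthetic.run_csp(mol, ["P-1"], n_valid=40, seed=2)
        unique, _ = R.deduplicate(structs)
        out.append(analysis.Landscape(mol.name, unique))
    return out


@pytest.fixture(scope="session")
def window_structures(six_landscapes):
    """All structures within the 8 kJ/mol training window, per landscape."""
    wins = []
    for ls in six_landscapes:
        ref = ls.global_minimum.e_latt
        wins.append([s for s in ls if s.e_latt - ref <= 8.0])
    return wins


@pytest.fixture(scope="session")
def noise_oracle_config(window_structures):
    """Calibrated oracle for the noisy-recovery protocol (σ = 0.5)."""
    cal = [s for win in window_structures for s in win]
    return synthetic.calibrate_oracle(
        synthetic.SyntheticOracleConfig(noise_sigma=0.5, gain=1.0, seed=5),
        cal,
    )
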