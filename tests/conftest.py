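import numpy as np
import pytest

from bitterfp.molecule_io import Atom, Bond, Molecule
from bitterfp.synthetic_fixtures import FixtureSpec, generate_library


def make_molecule(name, spec, label=None):
    """Build a Molecule from [(element, sybyl, attached_h), ...] and bonds."""
    atoms_spec, bonds_spec = spec
    atoms = [
        Atom(i, el, sybyl, 0, h) for i, (el, sybyl, h) in enumerate(atoms_spec)
    ]
    bonds = [Bond(a, b, order) for a, b, order in bonds_spec]
    from bitterfp.molecule_io import _mark_rings

    atoms = _mark_rings(atoms, bonds)
    return Molecule(name, atoms, bonds, label)


@pytest.fixture
def ethanol():
    return make_molecule(
        "ethanol",
        ([("C", "C.3", 3), ("C", "C.3", 2), ("O", "O.3", 1)],
         [(0, 1, "single"), (1, 2, "single")]),
    )


@pytest.fixture
def methane():
    return make_molecule("methane", ([("C", "C.3", 4)], []))


@pytest.fixture
def propane():
    return make_molecule(
        "propane",
        ([("C", "C.3", 3), ("C", "C.3", 2), ("C", "C.3", 3)],
         [(0, 1, "single"), (1, 2, "single")]),
    )


@pytest.fixture
def water():
    return make_molecule("water", ([("O", "O.3", 2)], []))


@pytest.fixture
def benzene():
    atoms = [("C", "C.ar", 1)] * 6
    bonds = [(i, (i + 1) % 6, "aromatic") for i in range(6)]
    return make_molecule("benzene", (atoms, bonds))


@pytest.fixture(scope="session")
def clean_library():
    """Noise-free 40-molecule planted-motif library."""
    return generate_library(FixtureSpec(n_per_class=20, label_noise=0.0, seed=11))


@pytest.fixture(scope="session")
def study_library():
    """The 400-molecule noise-0.05 library used for the model-level checks."""
    return generate_library(FixtureSpec(n_per_class=200, label_noise=0.05, seed=7))


SMALL_GRIDS = {
    "KNN": {"n_neighbors": [3, 5], "weights": ["uniform"]},
    "RF": {"n_estimators": [100]},
    "GBM": {"n_estimators": [100], "learning_rate": [0.1]},
}


@pytest.fixture(scope="session")
def study_campaign(study_library):
    """Scaled training campaign on the 400-molecule library: 1024-bit
    diameter-4 fingerprints, KNN/RF/GBM, three splitting schemes."""
    from bitterfp.workflow import RunConfig, run_experiment

    config = RunConfig(
        fingerprints=[(4, 1024)],
        methods=["KNN", "RF", "GBM"],
        schemes_fast=3,
        schemes_dnn=1,
        feature_settings=["full"],
        base_seed=3,
        grid_overrides=SMALL_GRIDS,
    )
    return run_experiment(study_library, config)
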