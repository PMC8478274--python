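import numpy as np
import pytest

from barofold.contacts import build_contact_map
from barofold.fixtures import ToySpec, make_toy_structure
from barofold.model import ModelParams, native_conformation


@pytest.fixture(scope="session")
def compact_structure():
    """22-residue solenoid fixture used across the suite."""
    return make_toy_structure(
        ToySpec(n_residues=22, topology="compact", perturbation=0.1, seed=3)
    )


@pytest.fixture(scope="session")
def compact_model(compact_structure):
    """(structure, contact map, params, native conformation) bundle."""
    s = compact_structure
    cm = build_contact_map(s)
    p = ModelParams.from_structure(s)
    nat = native_conformation(s, cm, p)
    return s, cm, p, nat


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def compact_pt(compact_model):
    """Small replica-exchange run on the compact fixture, shared."""
    from barofold.engine import PTConfig, run_parallel_tempering
    from barofold.study import FIXTURE_LADDER

    s, cm, p, nat = compact_model
    cfg = PTConfig(
        temperatures=FIXTURE_LADDER,
        n_cycles=30_000,
        n_thermalization=10_000,
        thin=20,
        swap_every=5,
        n_runs=2,
        seed=5,
        mirror_symmetric_rmsd=True,
    )
    return run_parallel_tempering(cfg, cm, p, nat)


def brute_force_contacts(s, cutoff=4.5, min_separation=4):
    """O(N^2 * atoms^2) contact oracle, independent of the k-d tree path."""
    pairs = set()
    n = s.n_residues
    for i in range(n):
        ai = s.atom_xyz[s.atom_resi == i]
        for j in range(i + min_separation, n):
            aj = s.atom_xyz[s.atom_resi == j]
            d2 = ((ai[:, None, :] - aj[None, :, :]) ** 2).sum(axis=-1)
            if (d2 <= cutoff**2).any():
                pairs.add((i, j))
    return pairs
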