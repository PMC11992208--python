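import numpy as np
import pytest

from trsx import synthetic as syn


@pytest.fixture(scope="session")
def toy():
    """Six Gaussian atoms in a small orthorhombic P1 cell."""
    return syn.make_toy_crystal(n_atoms=6, cell=(14.0, 12.0, 10.0, 90, 90, 90),
                                d_min=1.5, seed=1)


@pytest.fixture(scope="session")
def toy_data(toy):
    """(dark reflections, phases, light reflections, deleted-atom index)."""
    dark, phases = syn.structure_factors_direct(toy)
    deleted = 2
    light, _ = syn.structure_factors_direct(
        syn.perturb_model(toy, "delete_atom", index=deleted)
    )
    return dark, phases, light, deleted


@pytest.fixture(scope="session")
def small_toy():
    """Cheaper toy (coarser resolution) for bootstrap-style loops."""
    return syn.make_toy_crystal(n_atoms=5, cell=(10.0, 9.0, 8.0, 90, 90, 90),
                                d_min=2.0, seed=2)


@pytest.fixture(scope="session")
def small_toy_data(small_toy):
    dark, phases = syn.structure_factors_direct(small_toy)
    deleted = 1
    light, _ = syn.structure_factors_direct(
        syn.perturb_model(small_toy, "delete_atom", index=deleted)
    )
    return dark, phases, light, deleted


@pytest.fixture
def helix():
    return syn.make_helix_structure(n_res=30)


def grid_scan_crossover(model, t_max, step=1e-3):
    """Brute-force first-crossing scan, the oracle for crossover_time."""
    t = np.arange(step, t_max, step)
    diff = model.c_m(t) - model.c_o(t)
    idx = np.flatnonzero(np.diff(np.sign(diff)) != 0)
    return None if idx.size == 0 else float(t[idx[0]])


def grid_scan_half_decay(model, t_max, step=1e-3):
    t = np.arange(step, t_max, step)
    tot = model.total(t)
    idx = np.flatnonzero(tot <= 0.5)
    return None if idx.size == 0 else float(t[idx[0]])
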