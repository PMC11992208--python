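"""Synthetic inputs with known ground truth for every pipeline stage.

Three families of generator live here:

* difference-spectrum series following the sequential M -> O -> ground
  photocycle model, built from Gaussian absorption bands (an intermediate
  band minus the depleted ground-state band) with optional Gaussian
  noise and repeat stacks;
* toy crystals of isotropic Gaussian atoms in a P1 cell, whose structure
  factors have an exact closed form evaluable by direct summation — the
  independent oracle for the Fourier difference-map machinery;
* redundant noisy amplitude observations and small synthetic C-alpha
  protein models, the fixtures for bootstrap error estimation and
  displacement analysis.

Every generator returns its ground truth next to the data, and all
randomness flows from an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .bootstrap import ObservationSet
from .diffmap import PhaseSet, ReflectionSet, _frac_matrix, _orth_matrix
from .kinetics import BasisSpectra, SequentialKineticModel, SpectralSeries

__all__ = [
    "SpectralGeneratorConfig",
    "SpectralGroundTruth",
    "make_spectral_series",
    "noise_sd_for_snr",
    "GaussianAtom",
    "ToyCrystal",
    "structure_factors_direct",
    "real_space_density_direct",
    "perturb_model",
    "make_observations",
    "make_toy_crystal",
    "make_helix_structure",
    "jitter_structure",
    "shift_residues",
]


# ---------------------------------------------------------------------------
# difference-spectrum series


@dataclass
class SpectralGeneratorConfig:
    """Conditions for the synthetic flash-photolysis experiment.

    The ground state absorbs at 498 nm; the M intermediate (deprotonated
    Schiff base) is strongly blue-shifted and the late O intermediate
    red-shifted — the 390/530 nm defaults are physically plausible
    choices for such a photocycle, not measured values.  Rates default to
    1/81 and 1/220 per ms, the sequential chain consistent with an M/O
    crossover near 63 ms and a half-decay of the total photoactivated
    population near 240 ms.
    """

    ground_peak_nm: float = 498.0
    m_peak_nm: float = 390.0
    o_peak_nm: float = 530.0
    band_widths_nm: tuple = (28.0, 25.0, 30.0)  # ground, M, O (Gaussian sd)
    amplitudes: tuple = (1.0, 0.9)              # M, O band heights (x scale)
    scale_delta_od: float = 0.02                # overall delta-OD magnitude
    rates: tuple = (1.0 / 81.0, 1.0 / 220.0)    # (k1, k2) in 1/ms
    wavelengths: np.ndarray = field(
        default_factory=lambda: np.linspace(350.0, 650.0, 101)
    )
    delays: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 500.0, 30)
    )
    noise_sd: float = 0.0
    n_repeats: int = 1
    seed: int = 0


@dataclass
class SpectralGroundTruth:
    basis: BasisSpectra
    model: SequentialKineticModel
    trace_m: np.ndarray
    trace_o: np.ndarray
    clean: np.ndarray


def _gauss(x, mu, sd):
    return np.exp(-((x - mu) ** 2) / (2.0 * sd**2))


def make_spectral_series(config: SpectralGeneratorConfig):
    """Generate a difference-spectrum series plus its ground truth.

    D = S_M c_M(t) + S_O c_O(t) + noise, with each basis difference
    spectrum built as (intermediate band - ground band).  When
    ``n_repeats > 1`` the returned series' ``D`` is the mean of the
    independently noisy repeats, which are kept in ``series.repeats``.
    """
    wl = np.asarray(config.wavelengths, dtype=float)
    delays = np.asarray(config.delays, dtype=float)
    w_g, w_m, w_o = config.band_widths_nm
    a_m, a_o = config.amplitudes
    bleach = _gauss(wl, config.ground_peak_nm, w_g)
    S_M = config.scale_delta_od * (a_m * _gauss(wl, config.m_peak_nm, w_m) - bleach)
    S_O = config.scale_delta_od * (a_o * _gauss(wl, config.o_peak_nm, w_o) - bleach)
    model = SequentialKineticModel(*config.rates)
    c_m = model.c_m(delays)
    c_o = model.c_o(delays)
    clean = np.outer(S_M, c_m) + np.outer(S_O, c_o)

    rng = np.random.default_rng(config.seed)
    repeats = None
    if config.n_repeats > 1:
        repeats = clean[None] + rng.normal(
            0.0, config.noise_sd, size=(config.n_repeats,) + clean.shape
        )
        D = repeats.mean(axis=0)
    elif config.noise_sd > 0:
        D = clean + rng.normal(0.0, config.noise_sd, size=clean.shape)
    else:
        D = clean.copy()

    series = SpectralSeries(wl, delays, D, repeats=repeats)
    truth = SpectralGroundTruth(
        basis=BasisSpectra(wl, S_M, S_O),
        model=model,
        trace_m=c_m,
        trace_o=c_o,
        clean=clean,
    )
    return series, truth


def noise_sd_for_snr(clean: np.ndarray, snr: float) -> float:
    """Noise sd giving rms(signal)/sd = snr for a noise-free matrix."""
    return float(np.sqrt(np.mean(np.asarray(clean) ** 2)) / snr)


# ---------------------------------------------------------------------------
# toy crystals with analytic structure factors


@dataclass
class GaussianAtom:
    """Isotropic Gaussian 'atom': unit-integral density w * N(x; sigma)."""

    frac: tuple            # fractional position
    width_A: float = 1.0   # real-space Gaussian sd (A)
    weight: float = 8.0    # integrated density (electrons)
    chain: str = "A"
    resid: int = 1
    name: str = "X"
    element: str = "O"
    serial: int = 1


@dataclass
class ToyCrystal:
    cell: tuple            # (a, b, c, alpha, beta, gamma), P1
    atoms: list            # of GaussianAtom
    d_min: float = 1.5

    def unit_cell(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(*self.cell)


def _half_sphere_indices(cell: gemmi.UnitCell, d_min: float) -> np.ndarray:
    """Unique-under-Friedel Miller indices with d >= d_min (000 excluded)."""
    abc = np.array([cell.a, cell.b, cell.c])
    hmax = np.ceil(abc / d_min).astype(int)
    rng = [np.arange(-m, m + 1) for m in hmax]
    H, K, L = np.meshgrid(*rng, indexing="ij")
    hkl = np.column_stack([H.ravel(), K.ravel(), L.ravel()])
    F = _frac_matrix(cell)
    s = hkl @ F
    inv_d = np.sqrt(np.sum(s * s, axis=1))
    keep = (inv_d <= 1.0 / d_min) & (inv_d > 0)
    hkl = hkl[keep]
    h, k, l = hkl.T
    unique = (h > 0) | ((h == 0) & (k > 0)) | ((h == 0) & (k == 0) & (l > 0))
    return hkl[unique]


def structure_factors_complex(toy: ToyCrystal, hkl: np.ndarray) -> np.ndarray:
    """Exact complex structure factors of the Gaussian-atom toy by direct sum.

    F(h) = sum_j w_j exp(-2 pi^2 sigma_j^2 |s|^2) exp(2 pi i h . x_j),
    the analytic Fourier transform of the periodic Gaussian density.
    """
    cell = toy.unit_cell()
    F = _frac_matrix(cell)
    s2 = np.sum((hkl @ F) ** 2, axis=1)
    out = np.zeros(len(hkl), dtype=complex)
    for a in toy.atoms:
        form = a.weight * np.exp(-2.0 * np.pi**2 * a.width_A**2 * s2)
        out += form * np.exp(2j * np.pi * (hkl @ np.asarray(a.frac, float)))
    return out


def structure_factors_direct(toy: ToyCrystal, d_min: float | None = None):
    """(ReflectionSet, PhaseSet) for the toy crystal, by direct summation."""
    cell = toy.unit_cell()
    hkl = _half_sphere_indices(cell, d_min or toy.d_min)
    Fc = structure_factors_complex(toy, hkl)
    amp = np.abs(Fc)
    phase = np.rad2deg(np.angle(Fc))
    return ReflectionSet(cell, hkl, amp), PhaseSet(hkl, phase)


def real_space_density_direct(toy: ToyCrystal, grid: tuple) -> np.ndarray:
    """Periodic Gaussian-sum density on a grid — real-space oracle.

    Sums each atom over the 27 neighbouring cell images, which is exact
    to machine precision for widths well below the cell edge.
    """
    cell = toy.unit_cell()
    M = _orth_matrix(cell)
    n = np.array(grid)
    axes = [np.arange(g) / g for g in grid]
    I, J, K = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([I.ravel(), J.ravel(), K.ravel()])
    rho = np.zeros(len(pts))
    shifts = np.array(
        [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    )
    for a in toy.atoms:
        norm = a.weight / ((2.0 * np.pi) ** 1.5 * a.width_A**3)
        for sh in shifts:
            d = (pts - np.asarray(a.frac) - sh) @ M.T
            rho += norm * np.exp(-np.sum(d * d, axis=1) / (2.0 * a.width_A**2))
    return rho.reshape(grid)


def perturb_model(toy: ToyCrystal, action: str, index: int = 0, delta=None,
                  factor: float = 0.5) -> ToyCrystal:
    """Modified copy of a toy crystal emulating a light-state change.

    ``delete_atom`` removes atom ``index`` (a disordering water);
    ``shift_atom`` translates it by fractional ``delta``; ``scale_weight``
    multiplies its weight by ``factor`` (partial occupancy).
    """
    atoms = [replace(a) for a in toy.atoms]
    if action == "delete_atom":
        del atoms[index]
    elif action == "shift_atom":
        d = np.zeros(3) if delta is None else np.asarray(delta, float)
        atoms[index] = replace(atoms[index], frac=tuple(np.asarray(atoms[index].frac) + d))
    elif action == "scale_weight":
        atoms[index] = replace(atoms[index], weight=atoms[index].weight * factor)
    else:
        raise ValueError("action must be delete_atom, shift_atom or scale_weight")
    return ToyCrystal(cell=toy.cell, atoms=atoms, d_min=toy.d_min)


def make_toy_crystal(n_atoms: int = 6, cell=(14.0, 12.0, 10.0, 90.0, 90.0, 90.0),
                     d_min: float = 1.5, seed: int = 0) -> ToyCrystal:
    """Random toy crystal with well-separated Gaussian atoms."""
    rng = np.random.default_rng(seed)
    atoms = []
    for i in range(n_atoms):
        atoms.append(
            GaussianAtom(
                frac=tuple(rng.uniform(0.1, 0.9, 3)),
                width_A=1.0,
                weight=float(rng.uniform(6.0, 10.0)),
                resid=i + 1,
                name="X",
                serial=i + 1,
            )
        )
    return ToyCrystal(cell=cell, atoms=atoms, d_min=d_min)


def make_observations(reflections: ReflectionSet, n_per_index: int,
                      noise_sd: float, seed: int = 0) -> ObservationSet:
    """Replicate each amplitude n times with Gaussian noise (floored at 0)."""
    if n_per_index < 1:
        raise ValueError("n_per_index must be >= 1")
    rng = np.random.default_rng(seed)
    hkl = np.repeat(reflections.hkl, n_per_index, axis=0)
    vals = np.repeat(reflections.amplitude, n_per_index)
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
    vals = np.maximum(vals, 0.0)
    return ObservationSet(cell=reflections.cell, hkl=hkl, values=vals)


# ---------------------------------------------------------------------------
# synthetic protein models (gemmi structures)


def make_helix_structure(
    n_res: int = 30,
    cell=(40.0, 40.0, 60.0, 90.0, 90.0, 90.0),
    chain_name: str = "A",
    first_resid: int = 1,
) -> gemmi.Structure:
    """Ideal C-alpha helix (2.3 A radius, 1.5 A rise, 100 deg/residue) in P1."""
    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(*cell)
    st.spacegroup_hm = "P 1"
    model = gemmi.Model("1")
    chain = gemmi.Chain(chain_name)
    center = np.array([cell[0], cell[1], cell[2]]) / 2.0
    for i in range(n_res):
        theta = np.deg2rad(100.0 * i)
        pos = center + np.array(
            [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i - 0.75 * n_res]
        )
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(first_resid + i, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*pos)
        atom.occ = 1.0
        atom.b_iso = 20.0
        atom.serial = i + 1
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    return st


def jitter_structure(structure: gemmi.Structure, sd_A: float, seed: int = 0) -> gemmi.Structure:
    """Copy with isotropic Gaussian displacement of every atom."""
    rng = np.random.default_rng(seed)
    st = structure.clone()
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    d = rng.normal(0.0, sd_A, 3)
                    atom.pos = gemmi.Position(
                        atom.pos.x + d[0], atom.pos.y + d[1], atom.pos.z + d[2]
                    )
    return st


def shift_residues(structure: gemmi.Structure, resids, delta) -> gemmi.Structure:
    """Copy with residues in ``resids`` translated by cartesian ``delta`` (A)."""
    ids = set(resids)
    d = np.asarray(delta, float)
    st = structure.clone()
    for model in st:
        for chain in model:
            for res in chain:
                if res.seqid.num in ids:
                    for atom in res:
                        atom.pos = gemmi.Position(
                            atom.pos.x + d[0], atom.pos.y + d[1], atom.pos.z + d[2]
                        )
    return st
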