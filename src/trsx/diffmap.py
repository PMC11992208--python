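"""Isomorphous difference Fourier maps from light/dark amplitude sets.

The light-minus-dark difference map is the Fourier synthesis

    d_rho(x) = (1/V) sum_h (F_light(h) - F_dark(h)) exp(i phi_dark(h))
                           exp(-2 pi i h . x)

with observed amplitudes from the two illumination states and phases
computed from the dark-state model.  Maps are reported in sigma units,
where sigma is the root-mean-square density over the unit cell, matching
the usual +-3 sigma contouring convention for such maps.

All computation is carried out in P1 (symmetry-expanded input is
accepted); Friedel mates are completed automatically so the synthesis is
real.  Extrema are reported on grid points — the default grid spacing of
d_min/3 makes interpolation unnecessary at the precision difference
features are quoted to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy import ndimage

__all__ = [
    "ReflectionSet",
    "PhaseSet",
    "RealSpaceMap",
    "DensityFeature",
    "scale_amplitudes",
    "compute_difference_map",
    "peak_search",
    "feature_at_site",
]


def _as_unit_cell(cell) -> gemmi.UnitCell:
    if isinstance(cell, gemmi.UnitCell):
        return cell
    return gemmi.UnitCell(*cell)


def _frac_matrix(cell: gemmi.UnitCell) -> np.ndarray:
    return np.array(cell.frac.mat.tolist())


def _orth_matrix(cell: gemmi.UnitCell) -> np.ndarray:
    return np.array(cell.orth.mat.tolist())


def _inv_d(cell: gemmi.UnitCell, hkl: np.ndarray) -> np.ndarray:
    """|s| = 1/d for an (N, 3) array of Miller indices."""
    F = _frac_matrix(cell)
    s = hkl @ F  # rows: reciprocal vectors in cartesian A^-1
    return np.sqrt(np.sum(s * s, axis=1))


@dataclass
class ReflectionSet:
    """Observed amplitudes |F| on a P1 unit cell."""

    cell: gemmi.UnitCell
    hkl: np.ndarray          # (N, 3) int
    amplitude: np.ndarray    # (N,)
    sigma_amp: np.ndarray | None = None

    def __post_init__(self):
        self.cell = _as_unit_cell(self.cell)
        self.hkl = np.asarray(self.hkl, dtype=int)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.hkl.ndim != 2 or self.hkl.shape[1] != 3:
            raise ValueError("hkl must be (N, 3)")
        if self.amplitude.shape != (self.hkl.shape[0],):
            raise ValueError("amplitude length must match hkl")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitudes must be non-negative")
        if len({tuple(h) for h in self.hkl}) != len(self.hkl):
            raise ValueError("duplicate Miller indices")
        if self.sigma_amp is not None:
            self.sigma_amp = np.asarray(self.sigma_amp, dtype=float)
            if self.sigma_amp.shape != self.amplitude.shape:
                raise ValueError("sigma_amp length must match hkl")

    def d_spacing(self) -> np.ndarray:
        return 1.0 / _inv_d(self.cell, self.hkl)

    def to_dict(self) -> dict:
        return {tuple(h): a for h, a in zip(map(tuple, self.hkl), self.amplitude)}


@dataclass
class PhaseSet:
    """Model phases (degrees, in [-180, 180)) for a set of Miller indices."""

    hkl: np.ndarray
    phase_deg: np.ndarray

    def __post_init__(self):
        self.hkl = np.asarray(self.hkl, dtype=int)
        self.phase_deg = np.asarray(self.phase_deg, dtype=float)
        # wrap into [-180, 180)
        self.phase_deg = (self.phase_deg + 180.0) % 360.0 - 180.0
        if self.phase_deg.shape != (self.hkl.shape[0],):
            raise ValueError("phase length must match hkl")

    def to_dict(self) -> dict:
        return {tuple(h): p for h, p in zip(map(tuple, self.hkl), self.phase_deg)}


@dataclass
class RealSpaceMap:
    """Gridded density over one P1 unit cell (fractional axes)."""

    cell: gemmi.UnitCell
    values: np.ndarray  # (n1, n2, n3)

    def __post_init__(self):
        self.cell = _as_unit_cell(self.cell)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D grid")

    @property
    def sigma(self) -> float:
        """Root-mean-square density — the map's contouring unit."""
        return float(np.sqrt(np.mean(self.values**2)))

    @property
    def shape(self):
        return self.values.shape

    def grid_spacing(self) -> np.ndarray:
        abc = np.array([self.cell.a, self.cell.b, self.cell.c])
        return abc / np.array(self.values.shape)

    def frac_coords(self, ijk: np.ndarray) -> np.ndarray:
        return np.asarray(ijk, float) / np.array(self.values.shape)


@dataclass
class DensityFeature:
    frac_position: tuple
    value_sigma: float
    nearest_atom: tuple | None = None  # (chain, residue id, atom name)
    distance_A: float = float("nan")


def scale_amplitudes(light: ReflectionSet, dark: ReflectionSet, mode: str = "global",
                     n_shells: int = 20) -> ReflectionSet:
    """Scale the light amplitudes onto the dark set.

    ``mode='global'``: one factor k minimising sum (F_dark - k F_light)^2
    over the common indices.  ``mode='shells'``: the same factor fit per
    resolution shell (equal-count shells in d-spacing, default 20).
    Returns a light set restricted to the common indices with k applied.
    """
    common = sorted({tuple(h) for h in light.hkl} & {tuple(h) for h in dark.hkl})
    if len(common) < 10:
        raise ValueError(f"only {len(common)} common indices (need >= 10)")
    ld = light.to_dict()
    dd = dark.to_dict()
    hkl = np.array(common, dtype=int)
    fl = np.array([ld[h] for h in common])
    fd = np.array([dd[h] for h in common])

    if mode == "global":
        k = np.full(len(common), np.dot(fd, fl) / np.dot(fl, fl))
    elif mode == "shells":
        inv_d = _inv_d(light.cell, hkl)
        order = np.argsort(inv_d)
        n_shells = min(n_shells, max(1, len(common) // 10))
        k = np.empty(len(common))
        for shell in np.array_split(order, n_shells):
            num = np.dot(fd[shell], fl[shell])
            den = np.dot(fl[shell], fl[shell])
            k[shell] = num / den if den > 0 else 1.0
    else:
        raise ValueError("mode must be 'global' or 'shells'")
    return ReflectionSet(light.cell, hkl, k * fl)


def _choose_grid(cell: gemmi.UnitCell, hkl: np.ndarray, d_min: float | None):
    """Grid with spacing <= d_min/3 on every axis and no coefficient aliasing."""
    if d_min is None:
        d_min = float(1.0 / _inv_d(cell, hkl).max())
    abc = np.array([cell.a, cell.b, cell.c])
    n_spacing = np.ceil(3.0 * abc / d_min).astype(int)
    n_alias = 2 * np.abs(hkl).max(axis=0) + 1
    return tuple(int(max(a, b)) for a, b in zip(n_spacing, n_alias))


def compute_difference_map(
    light: ReflectionSet,
    dark: ReflectionSet,
    phases: PhaseSet,
    d_min: float | None = None,
    grid: tuple | None = None,
) -> RealSpaceMap:
    """Fourier synthesis of (F_light - F_dark) exp(i phi_dark).

    Operates on the intersection of the two index sets (apply
    :func:`scale_amplitudes` first if the sets are on different scales).
    Friedel mates are completed with conjugate coefficients so the map is
    real; (0,0,0), which carries no difference signal for isomorphous
    data, is skipped if present.
    """
    ld = light.to_dict()
    dd = dark.to_dict()
    pd_ = phases.to_dict()
    common = sorted(set(ld) & set(dd))
    if not common:
        raise ValueError("light and dark sets share no Miller indices")
    missing = [h for h in common if h not in pd_ and (-h[0], -h[1], -h[2]) not in pd_]
    if missing:
        raise ValueError(f"missing phases for {len(missing)} indices, e.g. {missing[0]}")

    coeffs: dict[tuple, complex] = {}
    for h in common:
        if h == (0, 0, 0):
            continue
        if h in pd_:
            phi = np.deg2rad(pd_[h])
            c = (ld[h] - dd[h]) * np.exp(1j * phi)
        else:  # phase supplied for the Friedel mate
            phi = np.deg2rad(pd_[(-h[0], -h[1], -h[2])])
            c = (ld[h] - dd[h]) * np.exp(-1j * phi)
        mate = (-h[0], -h[1], -h[2])
        if mate in coeffs:
            continue
        coeffs[h] = c
        coeffs[mate] = np.conj(c)

    hkl = np.array(list(coeffs), dtype=int)
    if grid is None:
        grid = _choose_grid(light.cell, hkl, d_min)
    G = np.zeros(grid, dtype=complex)
    n = np.array(grid)
    if np.any(2 * np.abs(hkl).max(axis=0) + 1 > n):
        raise ValueError("grid too coarse to hold all Miller indices without aliasing")
    for h, c in coeffs.items():
        G[h[0] % grid[0], h[1] % grid[1], h[2] % grid[2]] = c
    # rho(x_j) = (1/V) sum_h G(h) exp(-2 pi i h.j/n) — the forward FFT convention
    rho = np.fft.fftn(G).real / light.cell.volume
    return RealSpaceMap(light.cell, rho)


def _min_image_cart_dist(cell: gemmi.UnitCell, frac_a: np.ndarray,
                         frac_b: np.ndarray) -> np.ndarray:
    """Pairwise minimum-image distances (A) between two fractional coord sets."""
    M = _orth_matrix(cell)
    d = frac_a[:, None, :] - frac_b[None, :, :]
    d -= np.round(d)
    cart = d @ M.T
    return np.sqrt(np.sum(cart * cart, axis=2))


def peak_search(
    rsmap: RealSpaceMap,
    threshold_sigma: float,
    model_atoms=None,
    merge_radius_A: float = 1.5,
) -> list[DensityFeature]:
    """Signed local extrema of a difference map above a sigma threshold.

    Local maxima (positive) and minima (negative) with |value| >=
    threshold * sigma are collected, merged greedily within
    ``merge_radius_A`` (strongest kept), optionally assigned to the
    nearest model atom, and returned sorted by |value| descending.

    ``model_atoms`` is an iterable of objects with ``frac`` (fractional
    position), ``chain``, ``resid`` and ``name`` attributes (see
    :mod:`trsx.projection1d`).
    """
    if threshold_sigma <= 0:
        raise ValueError("threshold must be positive")
    v = rsmap.values
    sigma = rsmap.sigma
    if sigma == 0:
        return []
    foot = np.ones((3, 3, 3), dtype=bool)
    is_max = (v == ndimage.maximum_filter(v, footprint=foot, mode="wrap"))
    is_min = (v == ndimage.minimum_filter(v, footprint=foot, mode="wrap"))
    cand = (is_max & (v >= threshold_sigma * sigma)) | (
        is_min & (v <= -threshold_sigma * sigma)
    )
    ijk = np.argwhere(cand)
    if ijk.size == 0:
        return []
    vals = v[cand]
    order = np.argsort(-np.abs(vals))
    ijk, vals = ijk[order], vals[order]
    frac = rsmap.frac_coords(ijk)

    kept_idx: list[int] = []
    for i in range(len(vals)):
        if kept_idx:
            d = _min_image_cart_dist(rsmap.cell, frac[i : i + 1], frac[kept_idx])
            if d.min() < merge_radius_A:
                continue
        kept_idx.append(i)

    atoms = list(model_atoms) if model_atoms is not None else []
    if atoms:
        atom_frac = np.array([a.frac for a in atoms])
    features = []
    for i in kept_idx:
        feat = DensityFeature(
            frac_position=tuple(frac[i]),
            value_sigma=float(vals[i] / sigma),
        )
        if atoms:
            d = _min_image_cart_dist(rsmap.cell, frac[i : i + 1], atom_frac)[0]
            j = int(np.argmin(d))
            feat.nearest_atom = (atoms[j].chain, atoms[j].resid, atoms[j].name)
            feat.distance_A = float(d[j])
        features.append(feat)
    return features


def feature_at_site(rsmap: RealSpaceMap, frac_position, radius_A: float) -> float:
    """Signed extremum of the map within ``radius_A`` of a site, in sigma units.

    The position is wrapped into the cell; the value returned is the grid
    value of largest magnitude within the sphere, divided by the map
    sigma (0 for an identically zero map).
    """
    spacing = rsmap.grid_spacing()
    if radius_A < spacing.max():
        raise ValueError(
            f"radius {radius_A} A below grid spacing {spacing.max():.3g} A"
        )
    pos = np.asarray(frac_position, dtype=float) % 1.0
    n = np.array(rsmap.shape)
    abc = np.array([rsmap.cell.a, rsmap.cell.b, rsmap.cell.c])
    # bounding box of the sphere in grid steps (over-covers for oblique cells)
    half = np.ceil(radius_A / abc * n).astype(int) + 1
    center = np.round(pos * n).astype(int)
    axes = [np.arange(c - h, c + h + 1) for c, h in zip(center, half)]
    I, J, K = np.meshgrid(*axes, indexing="ij")
    ijk = np.column_stack([I.ravel(), J.ravel(), K.ravel()])
    frac = ijk / n
    d = _min_image_cart_dist(rsmap.cell, frac, pos[None, :])[:, 0]
    inside = d <= radius_A
    if not np.any(inside):
        return 0.0
    vals = rsmap.values[
        ijk[inside, 0] % n[0], ijk[inside, 1] % n[1], ijk[inside, 2] % n[2]
    ]
    sigma = rsmap.sigma
    if sigma == 0:
        return 0.0
    return float(vals[np.argmax(np.abs(vals))] / sigma)
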