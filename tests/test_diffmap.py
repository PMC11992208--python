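"""Difference Fourier synthesis, scaling, and density features."""

import numpy as np
import pytest

from trsx import diffmap as dm
from trsx import projection1d as p1d
from trsx import synthetic as syn


def brute_force_synthesis(light, dark, phases, grid):
    """Direct summation over Miller indices — the oracle for the FFT path."""
    ld, dd, pd_ = light.to_dict(), dark.to_dict(), phases.to_dict()
    axes = [np.arange(g) / g for g in grid]
    I, J, K = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([I, J, K], axis=-1)
    rho = np.zeros(grid, dtype=complex)
    for h in sorted(set(ld) & set(dd)):
        if h == (0, 0, 0):
            continue
        c = (ld[h] - dd[h]) * np.exp(1j * np.deg2rad(pd_[h]))
        ph = pts @ np.array(h)
        rho += c * np.exp(-2j * np.pi * ph) + np.conj(c) * np.exp(2j * np.pi * ph)
    return rho.real / light.cell.volume


class TestScaling:
    def test_identical_sets(self, toy_data):
        dark, _, _, _ = toy_data
        scaled = dm.scale_amplitudes(dark, dark, mode="global")
        np.testing.assert_allclose(
            sorted(scaled.amplitude), sorted(dark.amplitude), rtol=1e-12
        )

    def test_factor_of_two(self, toy_data):
        dark, _, _, _ = toy_data
        halved = dm.ReflectionSet(dark.cell, dark.hkl, dark.amplitude / 2.0)
        scaled = dm.scale_amplitudes(halved, dark, mode="global")
        np.testing.assert_allclose(
            scaled.to_dict()[tuple(dark.hkl[0])],
            dark.to_dict()[tuple(dark.hkl[0])],
            rtol=1e-12,
        )

    def test_shell_scaling_beats_global_on_bfactor_falloff(self, toy_data):
        dark, _, _, _ = toy_data
        inv_d2 = (1.0 / dark.d_spacing()) ** 2
        light = dm.ReflectionSet(
            dark.cell, dark.hkl, dark.amplitude * np.exp(-5.0 * inv_d2 / 4.0)
        )
        dd = dark.to_dict()

        def residual(scaled):
            sd = scaled.to_dict()
            return sum((dd[h] - sd[h]) ** 2 for h in sd)

        r_global = residual(dm.scale_amplitudes(light, dark, mode="global"))
        r_shells = residual(dm.scale_amplitudes(light, dark, mode="shells"))
        assert r_shells < r_global

    def test_no_common_indices(self, toy_data):
        dark, _, _, _ = toy_data
        other = dm.ReflectionSet(dark.cell, dark.hkl + 100, dark.amplitude)
        with pytest.raises(ValueError, match="common"):
            dm.scale_amplitudes(other, dark)


class TestSynthesis:
    def test_light_equals_dark_gives_zero_map(self, toy_data):
        dark, phases, _, _ = toy_data
        m = dm.compute_difference_map(dark, dark, phases)
        assert np.max(np.abs(m.values)) < 1e-12
        assert m.sigma == 0.0

    def test_deleted_atom_minimum_at_site(self, toy, toy_data):
        dark, phases, light, deleted = toy_data
        m = dm.compute_difference_map(light, dark, phases)
        ijk = np.unravel_index(np.argmin(m.values), m.shape)
        frac = np.array(ijk) / np.array(m.shape)
        d = dm._min_image_cart_dist(
            m.cell, frac[None], np.array(toy.atoms[deleted].frac)[None]
        )[0, 0]
        assert m.values[ijk] < 0
        assert d <= np.linalg.norm(m.grid_spacing())  # within one grid step

    def test_parseval(self, toy_data):
        dark, phases, light, _ = toy_data
        m = dm.compute_difference_map(light, dark, phases)
        ld, dd = light.to_dict(), dark.to_dict()
        coeff_sq = sum(
            2 * (ld[h] - dd[h]) ** 2 for h in set(ld) & set(dd) if h != (0, 0, 0)
        )
        expected_var = coeff_sq / m.cell.volume**2
        assert np.mean(m.values**2) == pytest.approx(expected_var, rel=1e-6)

    def test_fft_matches_direct_summation(self, small_toy_data):
        dark, phases, light, _ = small_toy_data
        grid = (12, 10, 10)
        m = dm.compute_difference_map(light, dark, phases, grid=grid)
        oracle = brute_force_synthesis(light, dark, phases, grid)
        assert np.max(np.abs(m.values - oracle)) <= 1e-6 * np.max(np.abs(oracle))

    def test_linearity(self, toy_data):
        dark, phases, _, _ = toy_data
        rng = np.random.default_rng(7)
        d1 = rng.uniform(0, 0.5, dark.amplitude.shape)
        d2 = rng.uniform(0, 0.5, dark.amplitude.shape)

        def mk(delta):
            light = dm.ReflectionSet(dark.cell, dark.hkl, dark.amplitude + delta)
            return dm.compute_difference_map(light, dark, phases).values

        m12 = mk(d1 + d2)
        sum_maps = mk(d1) + mk(d2)
        assert np.max(np.abs(m12 - sum_maps)) <= 1e-10 * np.max(np.abs(m12))

    def test_missing_phase_is_error(self, toy_data):
        dark, phases, light, _ = toy_data
        short = dm.PhaseSet(phases.hkl[:-5], phases.phase_deg[:-5])
        with pytest.raises(ValueError, match="phase"):
            dm.compute_difference_map(light, dark, short)

    def test_sigma_is_rms(self, toy_data):
        dark, phases, light, _ = toy_data
        m = dm.compute_difference_map(light, dark, phases)
        assert m.sigma == pytest.approx(np.sqrt(np.mean(m.values**2)), rel=1e-14)


class TestPeakSearch:
    def test_zero_map_empty(self, toy):
        m = dm.RealSpaceMap(toy.unit_cell(), np.zeros((8, 8, 8)))
        assert dm.peak_search(m, 3.0) == []

    def test_deleted_atom_is_strongest_negative(self, toy, toy_data):
        dark, phases, light, deleted = toy_data
        m = dm.compute_difference_map(light, dark, phases)
        feats = dm.peak_search(m, 3.0, p1d.atoms_from_toy(toy))
        strongest_neg = next(f for f in feats if f.value_sigma < 0)
        assert strongest_neg.nearest_atom[1] == toy.atoms[deleted].resid
        assert strongest_neg.distance_A < 1.0

    def test_sign_flip_antisymmetry(self, toy_data):
        dark, phases, light, _ = toy_data
        m = dm.compute_difference_map(light, dark, phases)
        flipped = dm.RealSpaceMap(m.cell, -m.values)
        f1 = dm.peak_search(m, 3.0)
        f2 = dm.peak_search(flipped, 3.0)
        assert len(f1) == len(f2)
        for a, b in zip(f1, f2):
            assert a.frac_position == b.frac_position
            assert a.value_sigma == pytest.approx(-b.value_sigma, rel=1e-12)


class TestFeatureAtSite:
    def test_zero_map(self, toy):
        m = dm.RealSpaceMap(toy.unit_cell(), np.zeros((8, 8, 8)))
        assert dm.feature_at_site(m, (0.3, 0.3, 0.3), 2.0) == 0.0

    def test_matches_exhaustive_scan(self, toy, toy_data):
        dark, phases, light, deleted = toy_data
        m = dm.compute_difference_map(light, dark, phases)
        site = np.array(toy.atoms[deleted].frac)
        radius = 1.2
        val = dm.feature_at_site(m, site, radius)
        # oracle: scan every grid point
        n = np.array(m.shape)
        ijk = np.argwhere(np.ones(m.shape, bool))
        d = dm._min_image_cart_dist(m.cell, ijk / n, site[None])[:, 0]
        inside = m.values.ravel()[d <= radius]
        oracle = inside[np.argmax(np.abs(inside))] / m.sigma
        assert val == pytest.approx(oracle, rel=1e-12)
        assert val < 0

    def test_far_site_sees_little(self, toy, toy_data):
        dark, phases, light, deleted = toy_data
        m = dm.compute_difference_map(light, dark, phases)
        # site well away from the deleted atom on a noise-free map
        site = (np.array(toy.atoms[deleted].frac) + 0.5) % 1.0
        assert abs(dm.feature_at_site(m, site, 1.0)) < 3.0

    def test_radius_below_spacing_rejected(self, toy):
        m = dm.RealSpaceMap(toy.unit_cell(), np.zeros((8, 8, 8)))
        with pytest.raises(ValueError, match="radius"):
            dm.feature_at_site(m, (0, 0, 0), 0.1)
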