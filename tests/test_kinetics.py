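"""Sequential kinetic model, SVD decomposition and repeat handling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import grid_scan_crossover, grid_scan_half_decay
from trsx import kinetics as kin
from trsx import synthetic as syn

RATE = st.floats(min_value=1e-4, max_value=1.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(k1=RATE, k2=RATE)
def test_model_invariants(k1, k2):
    """c_M(0)=1, c_O(0)=0, c_O >= 0 and total non-increasing on a grid."""
    m = kin.SequentialKineticModel(k1, k2)
    t = np.linspace(0, 50.0 / min(k1, k2), 400)
    assert m.c_m(0) == 1.0
    assert m.c_o(0) == 0.0
    assert np.all(m.c_o(t) >= -1e-12)
    tot = m.total(t)
    assert np.all(np.diff(tot) <= 1e-12)
    assert np.all(tot <= 1.0 + 1e-12)


@pytest.mark.parametrize(
    "k1,k2,expected",
    [
        (0.01, 0.01, 100.0),            # equal rates: crossing at k t = 1
        (0.01, 0.0, 100.0 * np.log(2)),  # k2=0: c_O = 1 - c_M
    ],
)
def test_crossover_closed_forms(k1, k2, expected):
    m = kin.SequentialKineticModel(k1, k2)
    assert kin.crossover_time(m) == pytest.approx(expected, abs=1e-5)


def test_half_decay_closed_forms():
    assert kin.half_decay_time(kin.SequentialKineticModel(0.01, 0.0)) is None
    # instantaneous M: total decays as the O state alone
    m = kin.SequentialKineticModel(1000.0, 0.01)
    assert kin.half_decay_time(m) == pytest.approx(100.0 * np.log(2), rel=1e-3)


@pytest.mark.parametrize("k1,k2", [(1 / 81, 1 / 220), (0.05, 0.002), (0.003, 0.08)])
def test_timing_functions_match_grid_scan(k1, k2):
    """Bisection results agree with a dense 1e-3 ms scan within one step."""
    m = kin.SequentialKineticModel(k1, k2)
    t_max = 20.0 / min(k1, k2)
    t_cross = kin.crossover_time(m)
    oracle = grid_scan_crossover(m, t_max)
    if oracle is None:
        assert t_cross is None or t_cross > t_max
    else:
        assert t_cross == pytest.approx(oracle, abs=1e-3)
    t_half = kin.half_decay_time(m)
    assert t_half == pytest.approx(grid_scan_half_decay(m, t_max), abs=1e-3)


class TestAverageRepeats:
    def test_identical_repeats(self):
        wl = np.linspace(350, 650, 10)
        t = np.linspace(0, 100, 5)
        one = np.outer(np.sin(wl / 50), np.exp(-t / 40))
        stack = np.repeat(one[None], 10, axis=0)
        out = kin.average_repeats(stack, wl, t)
        assert out.n_retained == 10
        np.testing.assert_allclose(out.series.D, one)

    def test_outlier_rejected(self):
        rng = np.random.default_rng(0)
        wl, t = np.linspace(350, 650, 20), np.linspace(0, 100, 8)
        truth = np.outer(np.sin(wl / 50), np.exp(-t / 40))
        noise = 0.01
        stack = truth[None] + rng.normal(0, noise, (10, 20, 8))
        stack[7] += 10 * noise  # one repeat offset by 10x the noise level
        out = kin.average_repeats(stack, wl, t, rejection_k=3.0)
        assert out.n_retained == 9
        assert out.rejected == [7]

    def test_all_rejected_is_error(self):
        # equal-magnitude deviations with a sub-unit k reject everything
        rng = np.random.default_rng(1)
        stack = rng.normal(0, 1.0, (6, 5, 5))
        with pytest.raises(ValueError, match="reject"):
            kin.average_repeats(stack, np.arange(5), np.arange(5), rejection_k=0.2)

    def test_protocol_scale_roundtrip(self):
        """45 noisy repeats average back to the truth within noise/sqrt(45)."""
        cfg = syn.SpectralGeneratorConfig(noise_sd=5e-4, n_repeats=45, seed=3)
        series, truth = syn.make_spectral_series(cfg)
        out = kin.average_repeats(series)
        assert out.n_retained >= 40
        err = np.sqrt(np.mean((out.series.D - truth.clean) ** 2))
        assert err < 3 * 5e-4 / np.sqrt(45)


class TestSvdTruncate:
    def test_rank_one_exact(self):
        u, v = np.arange(1.0, 7.0), np.array([2.0, -1.0, 0.5, 3.0])
        U, s, Vt = kin.svd_truncate(np.outer(u, v), rank=1)
        np.testing.assert_allclose(U * s @ Vt, np.outer(u, v), atol=1e-12)
        _, s2, _ = kin.svd_truncate(np.outer(u, v), rank=2)
        assert s2[1] < 1e-12 * s2[0]

    def test_noise_free_series_is_rank_two(self):
        series, _ = syn.make_spectral_series(syn.SpectralGeneratorConfig())
        _, s, _ = kin.svd_truncate(series, rank=3)
        assert s[2] / s[1] < 1e-10

    def test_eckart_young_error(self):
        rng = np.random.default_rng(2)
        D = rng.normal(size=(15, 9))
        U, s, Vt = kin.svd_truncate(D, rank=2)
        err = np.sum((D - (U * s) @ Vt) ** 2)
        full_s = np.linalg.svd(D, compute_uv=False)
        assert err == pytest.approx(np.sum(full_s[2:] ** 2), rel=1e-10)

    def test_nonfinite_rejected(self):
        D = np.full((4, 4), np.nan)
        with pytest.raises(ValueError, match="finite"):
            kin.svd_truncate(D, rank=1)


class TestSequentialFit:
    def test_noise_free_recovery(self):
        series, truth = syn.make_spectral_series(syn.SpectralGeneratorConfig())
        res = kin.fit_sequential_decomposition(series)
        assert res.residual_rms < 1e-10
        assert res.model.k1 == pytest.approx(truth.model.k1, rel=1e-3)
        assert res.model.k2 == pytest.approx(truth.model.k2, rel=1e-3)
        # traces match the generator's up to the documented normalisation
        np.testing.assert_allclose(res.trace_m, truth.trace_m, atol=1e-8)
        np.testing.assert_allclose(res.trace_o, truth.trace_o, atol=1e-8)

    def test_noisy_recovery_median_error(self):
        """Median relative rate error <= 5% at SNR 20 over 50 seeds."""
        errs = []
        for seed in range(50):
            cfg = syn.SpectralGeneratorConfig(seed=seed)
            _, truth = syn.make_spectral_series(cfg)
            sd = syn.noise_sd_for_snr(truth.clean, 20.0)
            series, truth = syn.make_spectral_series(
                syn.SpectralGeneratorConfig(seed=seed, noise_sd=sd)
            )
            res = kin.fit_sequential_decomposition(series)
            errs.append(abs(res.model.k1 - truth.model.k1) / truth.model.k1)
            errs.append(abs(res.model.k2 - truth.model.k2) / truth.model.k2)
        assert np.median(errs) <= 0.05

    def test_non_identifiable_rejected(self):
        wl = np.linspace(350, 650, 20)
        t = np.linspace(0, 100, 10)
        D = np.outer(np.sin(wl / 40), np.exp(-t / 30))  # pure rank 1
        series = kin.SpectralSeries(wl, t, D)
        with pytest.raises(ValueError, match="rank"):
            kin.fit_sequential_decomposition(series)

    def test_degenerate_rates_use_analytic_limit(self):
        m = kin.SequentialKineticModel(0.01, 0.01 * (1 + 1e-12))
        t = np.linspace(0, 500, 50)
        expected = 0.01 * t * np.exp(-0.01 * t)
        np.testing.assert_allclose(m.c_o(t), expected, atol=1e-10)


class TestPhotostationary:
    @pytest.fixture
    def basis(self):
        _, truth = syn.make_spectral_series(syn.SpectralGeneratorConfig())
        return truth.basis

    def test_pure_m(self, basis):
        occ_m, occ_o, rms = kin.photostationary_decompose(0.4 * basis.S_M, basis)
        assert occ_m == pytest.approx(0.4, abs=1e-12)
        assert occ_o == pytest.approx(0.0, abs=1e-12)
        assert rms == pytest.approx(0.0, abs=1e-12)

    def test_noisy_mixture_within_standard_errors(self, basis):
        rng = np.random.default_rng(4)
        sd = 1e-4
        y = 0.25 * basis.S_M + 0.35 * basis.S_O + rng.normal(0, sd, basis.S_M.size)
        occ_m, occ_o, _ = kin.photostationary_decompose(y, basis)
        X = basis.matrix()
        se = sd * np.sqrt(np.diag(np.linalg.inv(X.T @ X)))
        assert abs(occ_m - 0.25) < 3 * se[0]
        assert abs(occ_o - 0.35) < 3 * se[1]

    def test_orthogonal_spectrum(self, basis):
        X = basis.matrix()
        rng = np.random.default_rng(5)
        y = rng.normal(size=X.shape[0])
        y -= X @ np.linalg.lstsq(X, y, rcond=None)[0]  # project out the basis
        occ_m, occ_o, rms = kin.photostationary_decompose(y, basis)
        assert abs(occ_m) < 1e-10 and abs(occ_o) < 1e-10
        assert rms == pytest.approx(np.sqrt(np.mean(y**2)), rel=1e-10)

    def test_collinear_basis_rejected(self, basis):
        bad = kin.BasisSpectra(basis.wavelengths, basis.S_M, basis.S_M * 2.0)
        with pytest.raises(ValueError, match="collinear"):
            kin.photostationary_decompose(basis.S_M, bad)


def test_occupancy_beam_correction():
    assert kin.occupancy_beam_correction(0.0, 760, 91.2, 5.0) == 1.0
    assert kin.occupancy_beam_correction(1000.0, 760, 91.2, 5.0) == 0.0
    # hand evaluation: (96.2 - 45.6) / 96.2
    val = kin.occupancy_beam_correction(60.0, 760, 91.2, 5.0)
    assert val == pytest.approx((96.2 - 45.6) / 96.2, abs=1e-3)


class TestBinFrames:
    def test_detector_binning_pools_three_frames(self):
        """24 frames of 10 ms pooled by 30 ms windows give 8 bins of 3."""
        t = np.arange(24) * 10.0
        v = np.arange(24.0)
        out = kin.bin_frames(t, v, 30.0)
        assert len(out.counts) == 8
        assert np.all(out.counts == 3)
        np.testing.assert_allclose(out.means, v.reshape(8, 3).mean(axis=1))

    def test_single_frame(self):
        out = kin.bin_frames([12.0], [7.0], 30.0)
        assert out.counts.tolist() == [1]
        assert out.means.tolist() == [7.0]

    def test_constant_values(self):
        t = np.arange(12) * 5.0
        out = kin.bin_frames(t, np.full(12, 2.5), 20.0)
        np.testing.assert_allclose(out.means, 2.5)

    def test_frame_outside_windows(self):
        with pytest.raises(ValueError, match="outside"):
            kin.bin_frames([-5.0, 10.0], [1.0, 2.0], 30.0)
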