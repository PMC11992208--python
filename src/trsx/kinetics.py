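"""Sequential-kinetics decomposition of time-resolved difference spectra.

A photocycle probed by flash photolysis produces a series of difference
absorption spectra D(lambda, t).  For a retinal protein whose late
photocycle is dominated by two spectrally distinct intermediates (a
blue-shifted M state and a red-shifted O state), the series is modelled as

    D(lambda, t) = S_M(lambda) * c_M(t) + S_O(lambda) * c_O(t)

with a sequential reaction chain  M --k1--> O --k2--> ground:

    c_M(t) = exp(-k1 t)
    c_O(t) = k1/(k2 - k1) * (exp(-k1 t) - exp(-k2 t))      (k1 != k2)
    c_O(t) = k1 t exp(-k1 t)                                (k1 == k2)

The basis spectra S_M and S_O are constrained to the span of the two
leading left singular vectors of D (variable projection): for each trial
rate pair the linear amplitudes are solved exactly by least squares, and
the rate pair minimising the residual is kept.

Time is in milliseconds throughout; wavelengths in nanometres; amplitudes
in difference optical density (delta OD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize

__all__ = [
    "SpectralSeries",
    "BasisSpectra",
    "SequentialKineticModel",
    "DecompositionResult",
    "RepeatAverage",
    "BinnedFrames",
    "average_repeats",
    "svd_truncate",
    "fit_sequential_decomposition",
    "crossover_time",
    "half_decay_time",
    "photostationary_decompose",
    "occupancy_beam_correction",
    "bin_frames",
]

# relative tolerance below which k1 and k2 are treated as equal and the
# analytic k1 == k2 limit of c_O is used
_RATE_DEGENERACY_RTOL = 1e-9


@dataclass
class SpectralSeries:
    """Wavelength x time matrix of difference absorbances.

    Parameters
    ----------
    wavelengths : array, nm, strictly increasing
    delays : array, ms, strictly increasing and non-negative
    D : array of shape (n_wavelengths, n_delays), delta OD
    repeats : optional array (n_repeats, n_wavelengths, n_delays) of the
        individual measurements that ``D`` averages.
    """

    wavelengths: np.ndarray
    delays: np.ndarray
    D: np.ndarray
    repeats: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.delays = np.asarray(self.delays, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if self.wavelengths.ndim != 1 or self.delays.ndim != 1:
            raise ValueError("wavelengths and delays must be 1-D")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be strictly increasing")
        if np.any(self.delays < 0):
            raise ValueError("delays must be non-negative")
        if self.D.shape != (self.wavelengths.size, self.delays.size):
            raise ValueError(
                f"D has shape {self.D.shape}, expected "
                f"({self.wavelengths.size}, {self.delays.size})"
            )
        if not np.all(np.isfinite(self.D)):
            raise ValueError("D contains non-finite entries")
        if self.repeats is not None:
            self.repeats = np.asarray(self.repeats, dtype=float)
            if self.repeats.ndim != 3 or self.repeats.shape[1:] != self.D.shape:
                raise ValueError("repeats must have shape (n_rep,) + D.shape")


@dataclass
class BasisSpectra:
    """Difference spectra of the M and O intermediates on a common axis."""

    wavelengths: np.ndarray
    S_M: np.ndarray
    S_O: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.S_M = np.asarray(self.S_M, dtype=float)
        self.S_O = np.asarray(self.S_O, dtype=float)
        n = self.wavelengths.size
        if self.S_M.shape != (n,) or self.S_O.shape != (n,):
            raise ValueError("basis spectra must match the wavelength axis")
        if not (np.all(np.isfinite(self.S_M)) and np.all(np.isfinite(self.S_O))):
            raise ValueError("basis spectra must be finite")

    def matrix(self) -> np.ndarray:
        """(n_wavelengths, 2) design matrix with columns S_M, S_O."""
        return np.column_stack([self.S_M, self.S_O])


@dataclass(frozen=True)
class SequentialKineticModel:
    """Rates of the sequential chain M -> O -> ground.

    ``k1`` (M decay into O) must be positive; ``k2`` (O decay to ground)
    may be zero, in which case the total photoactivated population is
    conserved.  Units are 1/ms.
    """

    k1: float
    k2: float

    def __post_init__(self) -> None:
        if not (self.k1 > 0):
            raise ValueError("k1 must be > 0")
        if self.k2 < 0:
            raise ValueError("k2 must be >= 0")

    @property
    def degenerate(self) -> bool:
        return abs(self.k1 - self.k2) < _RATE_DEGENERACY_RTOL * self.k1

    def c_m(self, t):
        t = np.asarray(t, dtype=float)
        return np.exp(-self.k1 * t)

    def c_o(self, t):
        t = np.asarray(t, dtype=float)
        if self.degenerate:
            return self.k1 * t * np.exp(-self.k1 * t)
        return (
            self.k1
            / (self.k2 - self.k1)
            * (np.exp(-self.k1 * t) - np.exp(-self.k2 * t))
        )

    def total(self, t):
        return self.c_m(t) + self.c_o(t)

    def concentration_matrix(self, t) -> np.ndarray:
        """(2, n_t) matrix with rows c_M(t), c_O(t)."""
        return np.vstack([self.c_m(t), self.c_o(t)])


@dataclass
class DecompositionResult:
    """Outcome of fitting the sequential two-intermediate model."""

    basis: BasisSpectra
    model: SequentialKineticModel
    scale: float
    trace_m: np.ndarray
    trace_o: np.ndarray
    crossover_ms: float | None
    half_decay_ms: float | None
    residual_rms: float
    svd_rank_gap: float

    def report(self) -> dict:
        return {
            "k1_per_ms": self.model.k1,
            "k2_per_ms": self.model.k2,
            "tau1_ms": 1.0 / self.model.k1,
            "tau2_ms": np.inf if self.model.k2 == 0 else 1.0 / self.model.k2,
            "crossover_ms": self.crossover_ms,
            "half_decay_ms": self.half_decay_ms,
            "scale": self.scale,
            "residual_rms": self.residual_rms,
            "svd_rank_gap": self.svd_rank_gap,
        }


@dataclass
class RepeatAverage:
    series: SpectralSeries
    n_retained: int
    rejected: list = field(default_factory=list)


def average_repeats(repeats, wavelengths=None, delays=None, rejection_k: float = 3.0) -> RepeatAverage:
    """Average a stack of repeated measurements with outlier rejection.

    A repeat is rejected when the RMS deviation of its matrix from the
    element-wise median matrix exceeds ``rejection_k`` times the median of
    all repeats' RMS deviations (a median-based analogue of a k-sigma
    cut, robust to the outliers it is meant to remove).

    ``repeats`` may be a :class:`SpectralSeries` carrying a repeat stack,
    or a raw (n_rep, n_wl, n_t) array with explicit axes.
    """
    if isinstance(repeats, SpectralSeries):
        if repeats.repeats is None:
            raise ValueError("series carries no repeat stack")
        wavelengths = repeats.wavelengths
        delays = repeats.delays
        stack = repeats.repeats
    else:
        stack = np.asarray(repeats, dtype=float)
        if wavelengths is None or delays is None:
            raise ValueError("raw stacks require explicit wavelengths and delays")
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a stack of at least 2 repeats")
    if rejection_k <= 0:
        raise ValueError("rejection_k must be positive")

    median_matrix = np.median(stack, axis=0)
    dev = np.sqrt(np.mean((stack - median_matrix) ** 2, axis=(1, 2)))
    threshold = rejection_k * np.median(dev)
    keep = dev <= threshold
    if not np.any(keep):
        raise ValueError(
            f"all {stack.shape[0]} repeats rejected at threshold "
            f"{threshold:.4g} (rejection_k={rejection_k})"
        )
    mean = stack[keep].mean(axis=0)
    series = SpectralSeries(wavelengths, delays, mean, repeats=stack)
    return RepeatAverage(
        series=series,
        n_retained=int(keep.sum()),
        rejected=list(np.flatnonzero(~keep)),
    )


def svd_truncate(series, rank: int):
    """Leading ``rank`` SVD components of a spectral series (or matrix).

    Returns ``(U, s, Vt)`` with shapes (n_wl, rank), (rank,), (rank, n_t).
    The truncated reconstruction ``U @ diag(s) @ Vt`` is the best rank-r
    approximation in the Frobenius norm (Eckart-Young).
    """
    D = series.D if isinstance(series, SpectralSeries) else np.asarray(series, float)
    if not np.all(np.isfinite(D)):
        raise ValueError("matrix contains non-finite entries")
    if not (1 <= rank <= min(D.shape)):
        raise ValueError(f"rank must be in [1, {min(D.shape)}]")
    U, s, Vt = np.linalg.svd(D, full_matrices=False)
    return U[:, :rank], s[:rank], Vt[:rank]


def _default_rate_grid(n: int = 40, lo: float = 1e-4, hi: float = 1.0):
    g = np.geomspace(lo, hi, n)
    return g, g


def _varpro_residual(k1: float, k2: float, delays: np.ndarray, D2: np.ndarray):
    """Least-squares amplitudes and residual for one trial rate pair.

    ``D2`` is the data projected onto the two leading left singular
    vectors (2 x n_t).  Returns (amplitudes A (2x2), in-subspace squared
    residual).  The component of the data outside the rank-2 subspace is
    a constant offset added by the caller.
    """
    model = SequentialKineticModel(k1, k2)
    C = model.concentration_matrix(delays)  # (2, n_t)
    # solve min ||D2 - A C||_F over A (2x2): normal equations on C
    G = C @ C.T
    try:
        A = np.linalg.solve(G, C @ D2.T).T
    except np.linalg.LinAlgError:
        return None, np.inf
    R = D2 - A @ C
    return A, float(np.sum(R * R))


def fit_sequential_decomposition(
    series: SpectralSeries,
    rate_grid=None,
    refine: bool = True,
) -> DecompositionResult:
    """Fit the sequential M -> O -> ground model to a difference-spectrum series.

    The two basis spectra are optimised as linear sums of the first two
    SVD components of the series (variable projection): for every trial
    ``(k1, k2)`` on a log-spaced grid the amplitudes are solved in closed
    form, and the best pair is optionally polished by Nelder-Mead in log
    rate space.  Occupancy traces are those of the kinetic model, whose
    total extrapolates to 1 at t = 0; the (degenerate) overall amplitude
    is absorbed into the basis spectra and ``scale`` records the trace
    renormalisation factor applied (1.0 in this parametrisation).
    """
    if series.delays.size < 4 or series.wavelengths.size < 4:
        raise ValueError("need at least 4 delays and 4 wavelengths")
    U, s, Vt = np.linalg.svd(series.D, full_matrices=False)
    if s[0] == 0 or s[1] / s[0] < 1e-6:
        raise ValueError(
            "series is not identifiably rank 2 (s2/s1 < 1e-6); "
            "two-component decomposition is ill-posed"
        )
    rank_gap = float(s[2] / s[1]) if s.size > 2 else 0.0
    U2 = U[:, :2]
    D2 = (s[:2, None] * Vt[:2])  # projection of D onto U2, shape (2, n_t)
    out_of_plane_sq = float(np.sum(s[2:] ** 2))

    if rate_grid is None:
        k1_grid, k2_grid = _default_rate_grid()
    else:
        k1_grid, k2_grid = rate_grid

    best = (np.inf, None, None)
    for k1 in k1_grid:
        for k2 in k2_grid:
            _, ss = _varpro_residual(k1, k2, series.delays, D2)
            if ss < best[0]:
                best = (ss, k1, k2)
    _, k1, k2 = best

    if refine:
        def objective(logk):
            kk1, kk2 = np.exp(logk)
            if kk1 <= 0 or kk2 < 0:
                return np.inf
            _, ss = _varpro_residual(kk1, kk2, series.delays, D2)
            return ss

        res = minimize(
            objective,
            x0=np.log([k1, k2]),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-30, "maxiter": 2000},
        )
        if res.success or res.fun <= best[0]:
            k1, k2 = np.exp(res.x)

    # Rate-exchange degeneracy: (k1, k2) and (k2, k1) span the same
    # two-exponential space and fit the data equally well (the swapped
    # solution absorbs the difference into its O basis spectrum).  The
    # assignment is resolved by spectral distinctness: keep the ordering
    # whose two basis spectra are least collinear, which selects the
    # physical pair whenever the intermediate spectra are less mutually
    # similar than their mixtures.
    def _basis_cos(kk1, kk2):
        A, _ = _varpro_residual(kk1, kk2, series.delays, D2)
        if A is None:
            return np.inf
        S = U2 @ A
        na, nb = np.linalg.norm(S[:, 0]), np.linalg.norm(S[:, 1])
        if na == 0 or nb == 0:
            return np.inf
        return abs(S[:, 0] @ S[:, 1]) / (na * nb)

    if abs(k1 - k2) >= _RATE_DEGENERACY_RTOL * max(k1, k2):
        if _basis_cos(k2, k1) < _basis_cos(k1, k2):
            k1, k2 = k2, k1

    model = SequentialKineticModel(float(k1), float(k2))
    A, in_plane_sq = _varpro_residual(model.k1, model.k2, series.delays, D2)
    S = U2 @ A  # columns: S_M, S_O
    basis = BasisSpectra(series.wavelengths, S[:, 0], S[:, 1])
    residual_rms = float(np.sqrt((in_plane_sq + out_of_plane_sq) / series.D.size))

    return DecompositionResult(
        basis=basis,
        model=model,
        scale=1.0,
        trace_m=model.c_m(series.delays),
        trace_o=model.c_o(series.delays),
        crossover_ms=crossover_time(model),
        half_decay_ms=half_decay_time(model),
        residual_rms=residual_rms,
        svd_rank_gap=rank_gap,
    )


def crossover_time(model: SequentialKineticModel, xtol: float = 1e-6) -> float | None:
    """Smallest t > 0 with c_M(t) = c_O(t), or None if the traces never cross.

    Found by scanning for a sign change of c_M - c_O on a dense log grid
    up to 100 times the slowest time constant, then bisecting (Brent).
    """
    tau = max(1.0 / model.k1, 1.0 / model.k2 if model.k2 > 0 else 1.0 / model.k1)
    t_max = 100.0 * tau

    def f(t):
        return model.c_m(t) - model.c_o(t)

    grid = np.geomspace(t_max * 1e-8, t_max, 4000)
    vals = f(grid)
    sign_change = np.flatnonzero(np.diff(np.sign(vals)) != 0)
    if sign_change.size == 0:
        return None
    i = sign_change[0]
    return float(brentq(f, grid[i], grid[i + 1], xtol=xtol))


def half_decay_time(model: SequentialKineticModel, xtol: float = 1e-6) -> float | None:
    """Time at which c_M + c_O has fallen to half its t = 0 value.

    Returns None when k2 = 0 (the total photoactivated population is then
    conserved and never decays).
    """
    if model.k2 == 0:
        return None

    def f(t):
        return model.total(t) - 0.5

    # total is monotone non-increasing (d/dt = -k2 c_O <= 0): bracket by doubling
    hi = 1.0 / model.k2
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            return None
    return float(brentq(f, 0.0, hi, xtol=xtol))


def rates_from_timings(crossover_ms: float, half_decay_ms: float,
                       x0=(1.0 / 80.0, 1.0 / 200.0)) -> SequentialKineticModel:
    """Solve (k1, k2) of the sequential chain from two observable timings.

    Inverts the pair of conditions c_M(t*) = c_O(t*) at the crossover and
    c_M(T) + c_O(T) = 1/2 at the half-decay by a Newton-type root search
    in log-rate space.
    """
    from scipy.optimize import root

    def f(logk):
        m = SequentialKineticModel(*np.exp(logk))
        tc = crossover_time(m)
        th = half_decay_time(m)
        if tc is None or th is None:
            return [1e6, 1e6]
        return [tc - crossover_ms, th - half_decay_ms]

    sol = root(f, np.log(x0), method="hybr")
    if not sol.success:
        raise RuntimeError(f"rate solve failed: {sol.message}")
    return SequentialKineticModel(*np.exp(sol.x))


def photostationary_decompose(diff_spectrum, basis: BasisSpectra):
    """Break a steady-state difference spectrum into M and O occupancies.

    Ordinary least squares of the spectrum on {S_M, S_O}; the fitted
    coefficients are the apparent occupancies of the two intermediates in
    the photostationary mixture.
    """
    y = np.asarray(diff_spectrum, dtype=float)
    X = basis.matrix()
    if y.shape != (X.shape[0],):
        raise ValueError("spectrum must be on the basis wavelength axis")
    if np.linalg.cond(X) > 1e8:
        raise ValueError("basis spectra are collinear (condition number > 1e8)")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(coef[0]), float(coef[1]), float(np.sqrt(np.mean(resid**2)))


def occupancy_beam_correction(
    t_ms: float,
    jet_velocity_um_per_s: float,
    column_height_um: float,
    beam_height_um: float,
) -> float:
    """Fraction of the X-ray footprint still overlapping the photoactivated column.

    The laser photoactivates a column of height H in the flowing jet; by
    delay t it has translated v*t downwards.  With a beam of vertical
    size h the geometric overlap decays linearly from 1 to 0 over the
    travel distance H + h:  clamp((H + h - v t) / (H + h), 0, 1).
    """
    if jet_velocity_um_per_s <= 0 or column_height_um <= 0 or beam_height_um <= 0:
        raise ValueError("geometric arguments must be positive")
    travel = jet_velocity_um_per_s * t_ms * 1e-3
    span = column_height_um + beam_height_um
    return float(np.clip((span - travel) / span, 0.0, 1.0))


@dataclass
class BinnedFrames:
    window_ms: float
    starts_ms: np.ndarray
    counts: np.ndarray
    means: np.ndarray


def bin_frames(frame_times_ms, frame_values, window_ms: float) -> BinnedFrames:
    """Pool per-frame values into consecutive half-open windows [k*w, (k+1)*w)."""
    t = np.asarray(frame_times_ms, dtype=float)
    v = np.asarray(frame_values, dtype=float)
    if t.shape != v.shape or t.ndim != 1:
        raise ValueError("times and values must be matching 1-D arrays")
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    if np.any(t < 0):
        raise ValueError(f"frame at t={t.min():.3g} ms lies outside all windows")
    k = np.floor(t / window_ms).astype(int)
    n_bins = int(k.max()) + 1
    counts = np.bincount(k, minlength=n_bins)
    sums = np.bincount(k, weights=v, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return BinnedFrames(
        window_ms=float(window_ms),
        starts_ms=np.arange(n_bins) * float(window_ms),
        counts=counts,
        means=means,
    )
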