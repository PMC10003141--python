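"""Weighted-histogram analysis of umbrella-window trajectories.

Implements the self-consistent WHAM equations for harmonically biased
windows, per-window fluctuation statistics (variance and normalized
integrated autocorrelation time), and a moving-block bootstrap over the
window time series for error estimation.

Conventions
-----------
* The first ``discard_fraction`` of each window series is dropped as
  equilibration; the default 0.48 mirrors keeping the last 130 ns of a
  250 ns production run.
* The autocorrelation integral is truncated at the first zero crossing of
  the autocovariance (Sokal-style windowing), integrated by trapezoid.
* Free energies are reported relative to the bin containing ``z_ref``
  (bulk water by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kt
from .dynamics import WindowTrajectory
from .exceptions import (
    ConvergenceError,
    CoverageError,
    GridError,
    InsufficientDataError,
    InvalidParameterError,
)

__all__ = [
    "FEPEstimate",
    "LocalDiffusionStats",
    "wham_fep",
    "bootstrap_fep",
    "symmetrize_fep",
    "window_statistics",
    "bootstrap_windows",
    "integrated_autocorrelation_time",
]


@dataclass(frozen=True)
class FEPEstimate:
    """Free-energy profile ΔG(z) = G(z) − G(z_ref) with per-bin errors."""

    grid: np.ndarray  # bin centers, nm
    values: np.ndarray  # kcal/mol
    errors: np.ndarray  # kcal/mol, standard errors (zeros when unavailable)
    z_ref: float
    temperature: float

    def __post_init__(self):
        if np.any(np.diff(self.grid) <= 0):
            raise GridError("FEP grid must be strictly increasing")
        if np.any(self.errors < 0):
            raise InvalidParameterError("FEP errors must be non-negative")

    def interp(self, z):
        """Linear interpolation of ΔG at arbitrary z."""
        return np.interp(z, self.grid, self.values)


@dataclass(frozen=True)
class LocalDiffusionStats:
    """Per-window fluctuation statistics feeding the local diffusion estimate."""

    centers: np.ndarray  # window centers z0, nm
    variances: np.ndarray  # sigma_z^2, nm^2
    tau: np.ndarray  # integrated autocorrelation times, ns
    variance_errors: np.ndarray
    tau_errors: np.ndarray

    def __post_init__(self):
        if np.any(self.variances <= 0) or np.any(self.tau <= 0):
            raise InvalidParameterError(
                "window variances and autocorrelation times must be positive"
            )


def _retained(series: np.ndarray, discard_fraction: float) -> np.ndarray:
    if not 0.0 <= discard_fraction < 1.0:
        raise InvalidParameterError(
            f"discard_fraction must be in [0, 1), got {discard_fraction}"
        )
    n0 = int(len(series) * discard_fraction)
    return series[n0:]


def wham_fep(
    windows,
    bin_width: float = 0.05,
    temperature: float = DEFAULT_TEMPERATURE,
    tol: float = 1e-7,
    max_iter: int = 200_000,
    discard_fraction: float = 0.48,
    z_ref: float | None = None,
    bin_edges: np.ndarray | None = None,
    initial_free_energies: np.ndarray | None = None,
    return_free_energies: bool = False,
) -> FEPEstimate:
    """Self-consistent WHAM solution over harmonically biased windows.

    Iterates the unbiased density  p(b) = sum_i h_ib / sum_i N_i
    exp(beta(F_i - w_i(b)))  with  F_i = -kT log sum_b p(b) exp(-beta w_i(b))
    until the largest change in any window free energy F_i falls below
    ``tol`` (kcal/mol).  ΔG = -kT log p, shifted to 0 at the bin containing
    ``z_ref`` (default: the largest window center, i.e. bulk water).

    ``initial_free_energies`` warm-starts the iteration (used by the
    bootstrap loop); ``return_free_energies`` additionally returns the
    converged F_i array.
    """
    if not windows:
        raise InvalidParameterError("no windows given")
    kT = kt(temperature)
    beta = 1.0 / kT

    data = [_retained(w.positions, discard_fraction) for w in windows]
    for w, d in zip(windows, data):
        if len(d) < 2:
            raise InsufficientDataError(
                f"window at {w.center}: fewer than 2 retained samples"
            )
    zmin = min(d.min() for d in data)
    zmax = max(d.max() for d in data)
    if bin_edges is None:
        lo = np.floor(zmin / bin_width) * bin_width
        hi = np.ceil(zmax / bin_width) * bin_width
        nbins = max(int(round((hi - lo) / bin_width)), 1)
        bin_edges = lo + np.arange(nbins + 1) * bin_width
    else:
        bin_edges = np.asarray(bin_edges, dtype=float)
        if zmin < bin_edges[0] or zmax > bin_edges[-1]:
            raise CoverageError(
                f"samples outside bins: data span [{zmin:.3f}, {zmax:.3f}], "
                f"bins span [{bin_edges[0]:.3f}, {bin_edges[-1]:.3f}]"
            )
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])

    n_win = len(windows)
    hist = np.empty((n_win, len(centers)))
    counts = np.empty(n_win)
    for i, d in enumerate(data):
        hist[i], _ = np.histogram(d, bins=bin_edges)
        counts[i] = len(d)
    total_hist = hist.sum(axis=0)

    # window overlap check: adjacent (by center) windows must share a
    # populated bin, otherwise WHAM cannot stitch the profile
    order = np.argsort([w.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        if windows[a].force_constant == 0 or windows[b].force_constant == 0:
            continue
        if not np.any((hist[a] > 0) & (hist[b] > 0)):
            raise CoverageError(
                f"windows at {windows[a].center:g} and {windows[b].center:g} nm "
                "share no populated bin"
            )

    # bias energies at bin centers
    bias = np.empty((n_win, len(centers)))
    for i, w in enumerate(windows):
        bias[i] = 0.5 * w.force_constant * (centers - w.center) ** 2
    boltz = np.exp(-beta * bias)  # (n_win, n_bins)

    f = (
        np.zeros(n_win)
        if initial_free_energies is None
        else np.array(initial_free_energies, dtype=float)
    )
    for iteration in range(max_iter):
        # p(b) up to normalization
        denom = (counts * np.exp(beta * f)) @ boltz
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, total_hist / denom, 0.0)
        norm = p.sum()
        if norm <= 0:
            raise ConvergenceError("WHAM density collapsed to zero")
        p /= norm
        f_new = -kT * np.log(np.maximum(boltz @ p, 1e-300))
        f_new -= f_new[0]
        resid = float(np.max(np.abs(f_new - f)))
        f = f_new
        if resid < tol:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations", residual=resid
        )

    with np.errstate(divide="ignore"):
        g = np.where(p > 0, -kT * np.log(np.maximum(p, 1e-300)), np.nan)

    if z_ref is None:
        z_ref = max(w.center for w in windows)
    iref = int(np.argmin(np.abs(centers - z_ref)))
    if not np.isfinite(g[iref]):
        raise CoverageError(f"reference bin at z_ref={z_ref:g} nm is unpopulated")
    g = g - g[iref]

    # drop unpopulated edge bins
    good = np.isfinite(g)
    fep = FEPEstimate(
        grid=centers[good],
        values=g[good],
        errors=np.zeros(int(good.sum())),
        z_ref=float(z_ref),
        temperature=float(temperature),
    )
    if return_free_energies:
        return fep, f
    return fep


def bootstrap_fep(
    windows,
    n_boot: int = 100,
    seed: int = 0,
    block_length: int | None = None,
    **wham_kwargs,
) -> FEPEstimate:
    """WHAM profile with per-bin standard errors from a block bootstrap.

    The profile values come from the full data; the errors are the standard
    deviation of the WHAM solution across ``n_boot`` moving-block bootstrap
    replicates of the window series, interpolated onto the original grid.
    Replicate solutions are warm-started from the converged window free
    energies for speed.
    """
    discard = wham_kwargs.pop("discard_fraction", 0.48)
    fep, f_conv = wham_fep(
        windows, discard_fraction=discard, return_free_energies=True, **wham_kwargs
    )
    replicates = bootstrap_windows(
        windows,
        n_boot=n_boot,
        seed=seed,
        block_length=block_length,
        discard_fraction=discard,
    )
    profiles = np.empty((n_boot, len(fep.grid)))
    for r, rep in enumerate(replicates):
        rep_fep = wham_fep(
            rep,
            discard_fraction=0.0,
            initial_free_energies=f_conv,
            **wham_kwargs,
        )
        profiles[r] = np.interp(fep.grid, rep_fep.grid, rep_fep.values)
    errors = profiles.std(axis=0, ddof=1) if n_boot > 1 else np.zeros(len(fep.grid))
    return FEPEstimate(
        grid=fep.grid,
        values=fep.values,
        errors=errors,
        z_ref=fep.z_ref,
        temperature=fep.temperature,
    )


def symmetrize_fep(fep: FEPEstimate) -> FEPEstimate:
    """Symmetrize a free-energy profile about z = 0.

    A half-profile (grid in [0, zmax] or [-zmax, 0]) is mirrored onto the
    full symmetric grid; a full profile is averaged with its reflection,
    G_sym(z) = (G(z) + G(-z)) / 2, with errors combined in quadrature / 2.
    """
    grid, vals, errs = fep.grid, fep.values, fep.errors
    if len(grid) < 2:
        raise GridError("cannot symmetrize a single-point profile")

    if np.allclose(grid, -grid[::-1], rtol=0.0, atol=1e-9):
        # grid already symmetric: average in place (exactly even result)
        sym_vals = 0.5 * (vals + vals[::-1])
        sym_errs = 0.5 * np.sqrt(errs**2 + errs[::-1] ** 2)
        return FEPEstimate(
            grid=grid,
            values=sym_vals,
            errors=sym_errs,
            z_ref=fep.z_ref,
            temperature=fep.temperature,
        )

    # general case: build a symmetric grid spanning the full extent and, at
    # each ±z pair, average whichever of G(z), G(-z) the data cover
    lim = max(grid[-1], -grid[0])
    dz = float(np.median(np.diff(grid)))
    n = max(int(round(lim / dz)), 1)
    half = np.arange(n + 1) * (lim / n)
    sym_grid = np.concatenate([-half[:0:-1], half])

    lo, hi = grid[0], grid[-1]
    m = len(half)
    half_vals = np.empty(m)
    half_errs = np.empty(m)
    for k, h in enumerate(half):
        have_p = lo <= h <= hi
        have_m = lo <= -h <= hi
        if have_p and have_m:
            vp = np.interp(h, grid, vals)
            vm = np.interp(-h, grid, vals)
            ep = np.interp(h, grid, errs)
            em = np.interp(-h, grid, errs)
            half_vals[k] = 0.5 * (vp + vm)
            half_errs[k] = 0.5 * np.sqrt(ep**2 + em**2)
        elif have_p:
            half_vals[k] = np.interp(h, grid, vals)
            half_errs[k] = np.interp(h, grid, errs)
        elif have_m:
            half_vals[k] = np.interp(-h, grid, vals)
            half_errs[k] = np.interp(-h, grid, errs)
        else:  # pragma: no cover - lim guarantees coverage of one side
            raise GridError(f"no data on either side at |z| = {h:g}")
    sym_vals = np.concatenate([half_vals[:0:-1], half_vals])
    sym_errs = np.concatenate([half_errs[:0:-1], half_errs])
    return FEPEstimate(
        grid=sym_grid,
        values=sym_vals,
        errors=sym_errs,
        z_ref=fep.z_ref,
        temperature=fep.temperature,
    )


def integrated_autocorrelation_time(series: np.ndarray, dt: float) -> float:
    """Normalized integrated autocorrelation time of a time series (ns).

    tau = (1 / sigma^2) * int_0^T C(t) dt with C the autocovariance,
    integrated by trapezoid up to the first zero crossing of C (windowed
    estimator).  For white noise this converges to dt/2.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 2:
        raise InsufficientDataError("series too short for autocorrelation")
    x = x - x.mean()
    var = float(np.dot(x, x) / n)
    if var <= 0:
        raise InsufficientDataError("zero-variance series")
    # FFT autocovariance, biased normalization (1/n)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(fx * np.conj(fx), nfft)[:n] / n
    crossings = np.nonzero(acov <= 0)[0]
    m = int(crossings[0]) if len(crossings) else n - 1
    # trapezoid over C(0..t_m), normalized by C(0)
    tau = float(np.trapezoid(acov[: m + 1], dx=dt) / acov[0])
    return tau


def window_statistics(
    window: WindowTrajectory,
    discard_fraction: float = 0.48,
    min_length: int = 1000,
):
    """Variance sigma_z^2 (nm^2) and autocorrelation time tau_zz (ns).

    Both are computed on the retained (post-discard) segment of the window
    series; tau_zz uses the zero-crossing-truncated trapezoid estimator.
    """
    z = _retained(window.positions, discard_fraction)
    if len(z) < min_length:
        raise InsufficientDataError(
            f"retained series has {len(z)} < {min_length} points"
        )
    var = float(np.var(z))
    if var <= 0:
        raise InsufficientDataError("constant series: zero variance")
    tau = integrated_autocorrelation_time(z, window.timestep)
    return var, tau


def bootstrap_windows(
    windows,
    n_boot: int,
    seed: int = 0,
    block_length: int | None = None,
    discard_fraction: float = 0.48,
):
    """Moving-block bootstrap replicates of a window set.

    Yields ``n_boot`` lists of WindowTrajectory whose retained series are
    resampled in contiguous blocks (preserving autocorrelation).  The block
    length defaults to 5x the estimated autocorrelation time of each window,
    in frames, rounded up.
    """
    if n_boot < 1:
        raise InvalidParameterError("n_boot must be >= 1")
    if block_length is not None and block_length < 1:
        raise InvalidParameterError("block_length must be >= 1")

    retained = [_retained(w.positions, discard_fraction) for w in windows]
    blocks = []
    for w, z in zip(windows, retained):
        if block_length is None:
            tau = integrated_autocorrelation_time(z, w.timestep)
            bl = int(np.ceil(5.0 * tau / w.timestep))
            bl = min(max(bl, 1), len(z))
        else:
            if block_length > len(z):
                raise InvalidParameterError(
                    f"block_length {block_length} exceeds series length {len(z)}"
                )
            bl = block_length
        blocks.append(bl)

    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_boot):
        replicate = []
        for w, z, bl in zip(windows, retained, blocks):
            n = len(z)
            if bl >= n:
                resampled = z.copy()
            else:
                n_blocks = int(np.ceil(n / bl))
                starts = rng.integers(0, n - bl + 1, size=n_blocks)
                resampled = np.concatenate([z[s : s + bl] for s in starts])[:n]
            replicate.append(
                WindowTrajectory(
                    center=w.center,
                    force_constant=w.force_constant,
                    times=w.times[: len(resampled)],
                    positions=resampled,
                    timestep=w.timestep,
                    seed=w.seed,
                )
            )
        out.append(replicate)
    return out
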