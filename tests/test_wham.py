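"""WHAM free-energy estimation, window statistics, bootstrap machinery."""

import numpy as np
import pytest

from permeakit import (
    CampaignConfig,
    WindowTrajectory,
    bootstrap_windows,
    generate_windows,
    integrated_autocorrelation_time,
    make_diffusion_profile,
    make_fep_profile,
    simulate_window,
    symmetrize_fep,
    wham_fep,
    window_statistics,
)
from permeakit.constants import kt
from permeakit.exceptions import (
    CoverageError,
    InsufficientDataError,
    InvalidParameterError,
)
from permeakit.wham import FEPEstimate, bootstrap_fep


def _window_from(positions, center=0.0, k=0.0, dt=1e-3):
    positions = np.asarray(positions, dtype=float)
    return WindowTrajectory(
        center=center,
        force_constant=k,
        times=np.arange(len(positions)) * dt,
        positions=positions,
        timestep=dt,
        seed=0,
    )


@pytest.fixture(scope="module")
def single_barrier_windows():
    """Umbrella campaign on a single 5 kcal/mol Gaussian barrier at z=0."""
    cfg = CampaignConfig(
        potential=dict(barrier_flip=5.0, barrier_interface=0.0, well_depth=0.0),
        diffusion=dict(d_water=0.1, d_membrane=0.1),
        master_seed=13,
        window_n_steps=800_000,
    )
    return cfg, generate_windows(cfg)


class TestWhamFep:
    def test_unbiased_single_window_matches_boltzmann_inversion(self):
        """With one zero-force window WHAM reduces to -kT log(histogram)."""
        rng = np.random.default_rng(0)
        samples = rng.uniform(0.0, 2.0, size=50_000)
        w = _window_from(samples)
        fep = wham_fep([w], bin_width=0.2, temperature=300.0,
                       discard_fraction=0.0, z_ref=1.9)
        # flat sampling => flat profile, up to shot noise
        assert np.max(np.abs(fep.values)) < 0.05
        kT = kt(300.0)
        hist, edges = np.histogram(samples, bins=np.arange(0, 2.0001, 0.2))
        g_ref = -kT * np.log(hist / hist.sum())
        g_ref -= g_ref[-1]
        assert np.allclose(fep.values, g_ref, atol=1e-9)

    def test_recovers_single_gaussian_barrier(self, single_barrier_windows):
        """Parameter recovery: the generator's 5 kcal/mol barrier is the oracle."""
        cfg, windows = single_barrier_windows
        fep = symmetrize_fep(wham_fep(windows, temperature=cfg.temperature))
        pot, _ = cfg.build_profiles()
        assert fep.interp(0.0) == pytest.approx(5.0, abs=0.3)
        z_check = np.arange(0.0, 3.80001, 0.25)
        dev = fep.interp(z_check) - pot.energy(z_check)
        assert np.max(np.abs(dev - dev.mean())) < 0.3

    def test_error_decreases_with_sampling(self):
        """WHAM consistency: more samples, smaller max-abs profile error."""
        devs = []
        for n_steps in (50_000, 400_000):
            cfg = CampaignConfig(
                potential=dict(barrier_flip=5.0, barrier_interface=0.0,
                               well_depth=0.0),
                diffusion=dict(d_water=0.1, d_membrane=0.1),
                master_seed=29,
                window_n_steps=n_steps,
            )
            fep = symmetrize_fep(wham_fep(generate_windows(cfg),
                                          temperature=cfg.temperature))
            pot, _ = cfg.build_profiles()
            z = np.arange(0.0, 3.80001, 0.25)
            dev = fep.interp(z) - pot.energy(z)
            devs.append(np.max(np.abs(dev - dev[-1])))
        assert devs[1] < devs[0]

    def test_nonoverlapping_windows_raise_coverage_error(self):
        rng = np.random.default_rng(1)
        w1 = _window_from(rng.normal(0.0, 0.02, 5000), center=0.0, k=200.0)
        w2 = _window_from(rng.normal(1.0, 0.02, 5000), center=1.0, k=200.0)
        with pytest.raises(CoverageError):
            wham_fep([w1, w2], discard_fraction=0.0)


class TestSymmetrize:
    def test_idempotent_on_even_profile(self):
        grid = np.linspace(-2, 2, 41)
        vals = grid**2
        fep = FEPEstimate(grid=grid, values=vals, errors=np.zeros_like(grid),
                          z_ref=2.0, temperature=300.0)
        sym = symmetrize_fep(fep)
        assert np.array_equal(sym.grid, grid)
        assert np.allclose(sym.values, vals)

    def test_odd_part_cancels(self):
        grid = np.linspace(-1, 1, 21)
        fep = FEPEstimate(grid=grid, values=grid.copy(),
                          errors=np.zeros_like(grid), z_ref=1.0,
                          temperature=300.0)
        sym = symmetrize_fep(fep)
        assert np.max(np.abs(sym.values)) < 1e-14

    def test_half_profile_mirrored_exactly(self):
        grid = np.linspace(0.0, 3.0, 31)
        vals = np.sin(grid)
        fep = FEPEstimate(grid=grid, values=vals, errors=np.zeros_like(grid),
                          z_ref=3.0, temperature=300.0)
        sym = symmetrize_fep(fep)
        assert sym.grid[0] == -3.0 and sym.grid[-1] == 3.0
        assert np.array_equal(sym.values, sym.values[::-1])
        # positive half reproduces the input
        pos = sym.grid >= 0
        assert np.allclose(sym.values[pos], np.interp(sym.grid[pos], grid, vals))


class TestWindowStatistics:
    def test_ou_closed_forms(self, flat_potential, constant_diffusion):
        """sigma^2 = kBT/k and tau = kBT/(kD) for a harmonic window."""
        k, d, temp = 10.0, 0.1, 300.0
        w = simulate_window(flat_potential, constant_diffusion, center=0.0,
                            force_constant=k, n_steps=1_000_000,
                            timestep=5e-4, save_stride=10, seed=20300,
                            temperature=temp)
        var, tau = window_statistics(w, discard_fraction=0.0)
        kT = kt(temp)
        assert var == pytest.approx(kT / k, rel=0.10)
        assert tau == pytest.approx(kT / (k * d), rel=0.10)

    def test_white_noise_limit_after_shuffling(self, flat_potential,
                                               constant_diffusion):
        """Shuffling destroys correlation: tau -> dt/2; variance is unchanged."""
        w = simulate_window(flat_potential, constant_diffusion, center=0.0,
                            force_constant=20.0, n_steps=500_000,
                            timestep=5e-4, save_stride=10, seed=8,
                            temperature=300.0)
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(w.positions)
        var0 = np.var(w.positions)
        tau = integrated_autocorrelation_time(shuffled, w.timestep)
        assert tau == pytest.approx(w.timestep / 2.0, rel=0.3)
        assert np.var(shuffled) == var0

    def test_degenerate_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            window_statistics(_window_from(np.ones(5000)), discard_fraction=0.0)
        with pytest.raises(InsufficientDataError):
            window_statistics(_window_from(np.arange(50.0)),
                              discard_fraction=0.0)


class TestBootstrap:
    def test_replicate_count_and_shapes(self, single_barrier_windows):
        _, windows = single_barrier_windows
        reps = bootstrap_windows(windows[:3], n_boot=5, seed=1)
        assert len(reps) == 5
        n_retained = len(windows[0].positions) - int(
            len(windows[0].positions) * 0.48
        )
        for rep in reps:
            assert len(rep) == 3
            assert all(len(w.positions) == n_retained for w in rep)

    def test_full_length_block_returns_original(self):
        z = np.random.default_rng(2).normal(size=2000)
        w = _window_from(z)
        reps = bootstrap_windows([w], n_boot=3, seed=0,
                                 block_length=2000, discard_fraction=0.0)
        for rep in reps:
            assert np.array_equal(rep[0].positions, z)

    def test_constant_series_gives_identical_replicates(self):
        w = _window_from(np.full(1000, 1.5))
        reps = bootstrap_windows([w], n_boot=4, seed=0, block_length=10,
                                 discard_fraction=0.0)
        for rep in reps:
            assert np.all(rep[0].positions == 1.5)

    def test_seed_determinism_and_block_validation(self):
        z = np.random.default_rng(3).normal(size=500)
        w = _window_from(z)
        a = bootstrap_windows([w], 2, seed=7, block_length=25,
                              discard_fraction=0.0)
        b = bootstrap_windows([w], 2, seed=7, block_length=25,
                              discard_fraction=0.0)
        assert np.array_equal(a[0][0].positions, b[0][0].positions)
        with pytest.raises(InvalidParameterError):
            bootstrap_windows([w], 1, block_length=501, discard_fraction=0.0)

    def test_bootstrap_errors_enclose_truth(self, single_barrier_windows):
        """1-sigma bootstrap bands cover the true profile in a solid majority
        of bins (nominal ~2/3)."""
        cfg, windows = single_barrier_windows
        fep = bootstrap_fep(windows, n_boot=30, seed=4,
                            temperature=cfg.temperature)
        pot, _ = cfg.build_profiles()
        truth = pot.energy(fep.grid)
        # align additive constants over well-sampled bins
        sel = fep.errors > 0
        shift = np.mean(fep.values[sel] - truth[sel])
        covered = np.abs(fep.values - truth - shift) <= fep.errors
        assert covered[sel].mean() >= 0.5
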