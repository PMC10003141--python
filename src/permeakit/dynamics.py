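"""Overdamped Langevin dynamics along the membrane normal.

Trajectories of the permeant's z coordinate are generated with an
Euler–Maruyama integrator for the overdamped (Brownian) equation of motion

    dz = [ -beta * D(z) * U'(z) + D'(z) ] dt + sqrt(2 D(z) dt) * xi,

where U(z) = G(z) + k/2 (z - z0)^2 includes an optional harmonic umbrella
restraint, and the D'(z) term is the Itô spurious-drift correction required
for position-dependent diffusion.  Boundaries at ±(zmax + margin) are
reflecting.  The integrator is JIT-compiled; trajectories are bit-reproducible
for a fixed seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from numba import njit

from .constants import DEFAULT_TEMPERATURE, kt
from .exceptions import IntegrationInstabilityError, InvalidParameterError
from .profiles import DiffusionProfile, PotentialProfile

__all__ = [
    "WindowTrajectory",
    "UnbiasedTrajectory",
    "simulate_window",
    "simulate_unbiased",
    "derive_seed",
]


@dataclass(frozen=True)
class WindowTrajectory:
    """Umbrella-window time series of z (nm) with its restraint metadata."""

    center: float
    force_constant: float  # kcal/mol/nm^2
    times: np.ndarray  # ns
    positions: np.ndarray  # nm
    timestep: float  # saved-frame spacing, ns
    seed: int

    def __post_init__(self):
        if len(self.positions) != len(self.times):
            raise InvalidParameterError("times and positions must match in length")


@dataclass(frozen=True)
class UnbiasedTrajectory:
    """Unconstrained time series of z (nm) from a given starting point."""

    start: float
    times: np.ndarray
    positions: np.ndarray
    timestep: float
    seed: int


def derive_seed(master_seed: int, kind: str, index: int) -> int:
    """Deterministic per-trajectory seed from a master seed.

    Combines the master seed with a CRC32 hash of (kind, index) so that
    window and unbiased streams are independent and stable across runs.
    """
    tag = zlib.crc32(f"{kind}:{index}".encode())
    return int((master_seed * 2654435761 + tag) % (2**31 - 1))


@njit(cache=True)
def _integrate(
    z0,
    n_steps,
    dt,
    save_stride,
    kT,
    k_umb,
    center,
    gc,
    gh,
    gw,
    d_water,
    d_membrane,
    z_if,
    w_if,
    z_bound,
    step_cap,
    seed,
):
    np.random.seed(seed)
    n_saved = n_steps // save_stride + 1
    out = np.empty(n_saved)
    out[0] = z0
    z = z0
    isave = 1
    dd = d_water - d_membrane
    for step in range(1, n_steps + 1):
        az = z if z >= 0.0 else -z
        x = (az - z_if) / w_if
        if x > 35.0:
            sig = 1.0
        elif x < -35.0:
            sig = 0.0
        else:
            sig = 1.0 / (1.0 + np.exp(-x))
        D = d_membrane + dd * sig
        dD = dd * sig * (1.0 - sig) / w_if
        if z < 0.0:
            dD = -dD
        # force = -dU/dz
        du = k_umb * (z - center)
        for i in range(gc.shape[0]):
            arg = (z - gc[i]) / gw[i]
            e2 = arg * arg
            if e2 < 60.0:
                du += -gh[i] * arg / gw[i] * np.exp(-0.5 * e2)
        dz = (-(D / kT) * du + dD) * dt + np.sqrt(2.0 * D * dt) * np.random.normal()
        if dz > step_cap or dz < -step_cap:
            return out[:isave], step, dz
        z = z + dz
        if z > z_bound:
            z = 2.0 * z_bound - z
        elif z < -z_bound:
            z = -2.0 * z_bound - z
        if step % save_stride == 0:
            out[isave] = z
            isave += 1
    return out, 0, 0.0


def _run(
    potential: PotentialProfile,
    diffusion: DiffusionProfile,
    start: float,
    force_constant: float,
    center: float,
    n_steps: int,
    timestep: float,
    seed: int,
    save_stride: int,
    temperature: float,
    boundary_margin: float,
    step_cap: float,
):
    if n_steps < 0 or save_stride < 1:
        raise InvalidParameterError("n_steps must be >= 0 and save_stride >= 1")
    if timestep <= 0:
        raise InvalidParameterError("timestep must be positive")
    kT = kt(temperature)

    # stability: the largest deterministic displacement per step must stay
    # well below the scale the trajectory is meant to resolve
    d_max = max(diffusion.d_water, diffusion.d_membrane)
    grad_cap = float(np.max(np.abs(potential.gradient(potential.grid)))) if len(
        potential.grid
    ) else 0.0
    if force_constant > 0:
        sigma_w = np.sqrt(kT / force_constant)
        grad_cap += force_constant * 5.0 * sigma_w
        resolve = max(sigma_w, 0.05)
    else:
        resolve = 0.1
    drift_step = d_max / kT * grad_cap * timestep
    if drift_step > 0.25 * resolve:
        raise InvalidParameterError(
            f"timestep {timestep} ns too large: deterministic step "
            f"{drift_step:.3g} nm is not small against the resolved scale "
            f"{resolve:.3g} nm"
        )

    positions, err_step, err_dz = _integrate(
        float(start),
        int(n_steps),
        float(timestep),
        int(save_stride),
        kT,
        float(force_constant),
        float(center),
        potential.centers,
        potential.heights,
        potential.widths,
        diffusion.d_water,
        diffusion.d_membrane,
        diffusion.z_interface,
        diffusion.interface_width,
        potential.zmax + boundary_margin,
        float(step_cap),
        int(seed),
    )
    if err_step:
        raise IntegrationInstabilityError(err_step, abs(err_dz), step_cap)
    times = np.arange(len(positions)) * (timestep * save_stride)
    return times, positions


def simulate_window(
    potential: PotentialProfile,
    diffusion: DiffusionProfile,
    center: float,
    force_constant: float,
    n_steps: int,
    timestep: float = 1e-4,
    seed: int = 0,
    save_stride: int = 10,
    temperature: float = DEFAULT_TEMPERATURE,
    boundary_margin: float = 0.5,
    step_cap: float = 0.5,
    start: float | None = None,
) -> WindowTrajectory:
    """Simulate one umbrella window restrained at ``center``.

    ``force_constant`` is in kcal/mol/nm²; the trajectory starts at the
    window center unless ``start`` is given.  Saved-frame spacing is
    ``timestep * save_stride`` ns.
    """
    if force_constant < 0:
        raise InvalidParameterError("force_constant must be non-negative")
    z0 = center if start is None else start
    times, positions = _run(
        potential,
        diffusion,
        z0,
        force_constant,
        center,
        n_steps,
        timestep,
        seed,
        save_stride,
        temperature,
        boundary_margin,
        step_cap,
    )
    return WindowTrajectory(
        center=float(center),
        force_constant=float(force_constant),
        times=times,
        positions=positions,
        timestep=float(timestep * save_stride),
        seed=int(seed),
    )


def simulate_unbiased(
    potential: PotentialProfile,
    diffusion: DiffusionProfile,
    start: float,
    n_steps: int,
    timestep: float = 1e-4,
    seed: int = 0,
    save_stride: int = 100,
    temperature: float = DEFAULT_TEMPERATURE,
    boundary_margin: float = 0.5,
    step_cap: float = 0.5,
) -> UnbiasedTrajectory:
    """Simulate an unconstrained trajectory started at ``start`` (nm)."""
    times, positions = _run(
        potential,
        diffusion,
        start,
        0.0,
        0.0,
        n_steps,
        timestep,
        seed,
        save_stride,
        temperature,
        boundary_margin,
        step_cap,
    )
    return UnbiasedTrajectory(
        start=float(start),
        times=times,
        positions=positions,
        timestep=float(timestep * save_stride),
        seed=int(seed),
    )
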