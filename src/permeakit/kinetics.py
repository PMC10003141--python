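"""Four-compartment liposome kinetics and the kinetic permeability estimate.

The permeation of a solute into a liposome is modelled as a linear chain of
four compartments — outer water (wo), outer leaflet (lo), inner leaflet (li),
inner water (wi) — with nearest-neighbor first-order kinetics

    dS_I/dt = sum_J [ -k_IJ S_I + k_JI S_J ],    S_wo(0) = S_tot.

The apparent rate constants follow from the planar-membrane rates k_in,
k_out, k_flip through the geometric mapping k = P (A / V): each planar rate
carries an intrinsic permeability (rate times donor volume per unit area)
which is preserved when transplanted onto the spherical geometry.  The
solution is a three-exponential relaxation; the fastest eigen-rate plays the
role of the fast phase of a luminescence-influx fit and yields
P = (r/3) * k_fast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

from .constants import NM_PER_NS_TO_CM_PER_S, PER_NS_TO_PER_S
from .exceptions import (
    DegenerateSpectrumError,
    FitError,
    InvalidParameterError,
)
from .isdm import PermeabilityResult
from .msm import RateSet

__all__ = [
    "PlanarGeometry",
    "LiposomeGeometry",
    "ApparentRates",
    "CompartmentTrajectory",
    "KineticSolution",
    "BiexpFit",
    "build_planar_geometry",
    "build_liposome_geometry",
    "apparent_rates",
    "solve_master_numeric",
    "solve_master_analytic",
    "fit_biexponential",
    "permeability_from_rate",
    "planar_permeability_from_rates",
]

COMPARTMENTS = ("wo", "lo", "li", "wi")


@dataclass(frozen=True)
class PlanarGeometry:
    """Areas and volumes of the simulated planar bilayer patch (nm², nm³)."""

    n_lipids_per_leaflet: int
    area_per_lipid: float
    volume_per_lipid: float
    waters_per_lipid: float
    water_molecular_volume: float

    @property
    def area(self) -> float:
        """Leaflet patch area A_L."""
        return self.n_lipids_per_leaflet * self.area_per_lipid

    @property
    def bilayer_volume(self) -> float:
        """Bilayer interior volume V_L (both leaflets)."""
        return 2.0 * self.n_lipids_per_leaflet * self.volume_per_lipid

    @property
    def leaflet_volume(self) -> float:
        """Per-leaflet volume V_L / 2."""
        return self.bilayer_volume / 2.0

    @property
    def water_volume(self) -> float:
        """Total bulk water volume V_W (both sides of the bilayer)."""
        return (
            2.0
            * self.n_lipids_per_leaflet
            * self.waters_per_lipid
            * self.water_molecular_volume
        )


@dataclass(frozen=True)
class LiposomeGeometry:
    """Compartment volumes (nm³) and layer area (nm²) of a spherical liposome."""

    radius: float
    v_wo: float
    v_lo: float
    v_li: float
    v_wi: float
    area: float  # A_l = 4 pi r^2, shared by both layers
    volume_ratio: tuple

    @property
    def volumes(self):
        return np.array([self.v_wo, self.v_lo, self.v_li, self.v_wi])


@dataclass(frozen=True)
class ApparentRates:
    """Nearest-neighbor rate constants of the liposome chain (ns^-1)."""

    k_wo_lo: float
    k_lo_wo: float
    k_lo_li: float
    k_li_lo: float
    k_li_wi: float
    k_wi_li: float

    def __post_init__(self):
        for name, v in self.as_dict().items():
            if v < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {v}")

    def as_dict(self):
        return {
            "k_wo_lo": self.k_wo_lo,
            "k_lo_wo": self.k_lo_wo,
            "k_lo_li": self.k_lo_li,
            "k_li_lo": self.k_li_lo,
            "k_li_wi": self.k_li_wi,
            "k_wi_li": self.k_wi_li,
        }

    def rate_matrix(self) -> np.ndarray:
        """Generator matrix K with dS/dt = K S, order (wo, lo, li, wi)."""
        k = np.zeros((4, 4))
        pairs = [
            (0, 1, self.k_wo_lo),
            (1, 0, self.k_lo_wo),
            (1, 2, self.k_lo_li),
            (2, 1, self.k_li_lo),
            (2, 3, self.k_li_wi),
            (3, 2, self.k_wi_li),
        ]
        for i, j, rate in pairs:
            k[j, i] += rate
            k[i, i] -= rate
        return k


@dataclass(frozen=True)
class CompartmentTrajectory:
    """Amounts S_I(t) per compartment (fractions of S_tot)."""

    times: np.ndarray
    amounts: np.ndarray  # shape (len(times), 4), order (wo, lo, li, wi)

    @property
    def s_wi(self):
        return self.amounts[:, 3]


@dataclass(frozen=True)
class KineticSolution:
    """Closed-form eigen-solution S_I(t) = sum_n a_In exp(-kappa_n t)."""

    eigen_rates: np.ndarray  # kappa_n >= 0, one exactly 0, ascending
    amplitudes: np.ndarray  # (4, 4): compartment x mode
    s0: np.ndarray

    def __call__(self, times):
        times = np.atleast_1d(np.asarray(times, dtype=float))
        decay = np.exp(-np.outer(times, self.eigen_rates))  # (t, mode)
        return decay @ self.amplitudes.T  # (t, 4)

    @property
    def equilibrium(self):
        """S_I(inf): amplitude of the zero eigen-rate mode."""
        izero = int(np.argmin(self.eigen_rates))
        return self.amplitudes[:, izero]

    @property
    def fastest_rate(self) -> float:
        """Largest eigen-rate kappa_n (ns^-1)."""
        return float(np.max(self.eigen_rates))


@dataclass(frozen=True)
class BiexpFit:
    """Two-exponential relaxation fit I(t) = plateau + a_f e^{-k_f t} + a_s e^{-k_s t}."""

    k_fast: float
    k_slow: float
    amp_fast: float
    amp_slow: float
    plateau: float
    residual_norm: float
    degenerate: bool = False

    def __post_init__(self):
        if not self.k_fast >= self.k_slow > 0:
            raise InvalidParameterError("require k_fast >= k_slow > 0")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return (
            self.plateau
            + self.amp_fast * np.exp(-self.k_fast * t)
            + self.amp_slow * np.exp(-self.k_slow * t)
        )


def build_planar_geometry(
    n_lipids_per_leaflet: int = 25,
    area_per_lipid: float = 0.656,
    volume_per_lipid: float = 1.2,
    waters_per_lipid: float = 89.0,
    water_molecular_volume: float = 0.0305,
) -> PlanarGeometry:
    """Planar-patch geometry from per-lipid constants (POPC defaults).

    Defaults: 25 lipids per leaflet, area 0.656 nm² and volume 1.2 nm³ per
    lipid, 89 waters per lipid of molecular volume 0.0305 nm³.
    """
    vals = dict(
        n_lipids_per_leaflet=n_lipids_per_leaflet,
        area_per_lipid=area_per_lipid,
        volume_per_lipid=volume_per_lipid,
        waters_per_lipid=waters_per_lipid,
        water_molecular_volume=water_molecular_volume,
    )
    for name, v in vals.items():
        if v <= 0:
            raise InvalidParameterError(f"{name} must be positive, got {v}")
    return PlanarGeometry(**vals)


def build_liposome_geometry(
    radius: float = 100.0,
    volume_ratio=(1000.0, 1.0, 1.0, 10.0),
) -> LiposomeGeometry:
    """Spherical liposome geometry (radius in nm).

    The inner water volume is anchored to the full sphere volume
    (4/3) pi r^3 — the only choice consistent with V_wi / A_l = r / 3 —
    and the other compartments are scaled by the
    V_wo : V_lo : V_li : V_wi ratio (default 1000:1:1:10).
    """
    if radius <= 0:
        raise InvalidParameterError(f"radius must be positive, got {radius}")
    ratio = tuple(float(x) for x in volume_ratio)
    if len(ratio) != 4 or any(x <= 0 for x in ratio):
        raise InvalidParameterError("volume_ratio needs four positive entries")
    v_wi = 4.0 / 3.0 * math.pi * radius**3
    scale = v_wi / ratio[3]
    return LiposomeGeometry(
        radius=radius,
        v_wo=ratio[0] * scale,
        v_lo=ratio[1] * scale,
        v_li=ratio[2] * scale,
        v_wi=v_wi,
        area=4.0 * math.pi * radius**2,
        volume_ratio=ratio,
    )


def apparent_rates(
    rates: RateSet,
    planar: PlanarGeometry,
    liposome: LiposomeGeometry,
) -> ApparentRates:
    """Map planar rates onto the liposome chain, preserving intrinsic P.

    Each planar rate k corresponds to an intrinsic permeability
    P = k V_donor / A_L (donor volume V_W for entry, V_L for exit and
    flip-flop); the apparent liposome rate is P A_l / V_donor' with the
    donor volume of the spherical compartment:

        k_wo,lo = (V_W / V_wo)(A_l / A_L) k_in
        k_wi,li = (V_W / V_wi)(A_l / A_L) k_in
        k_lo,wo = k_li,wi = (V_L / V_l)(A_l / A_L) k_out
        k_lo,li = k_li,lo = (V_L / V_l)(A_l / A_L) k_flip

    with V_l = V_lo = V_li the liposome leaflet-compartment volume.
    """
    a_ratio = liposome.area / planar.area
    if a_ratio <= 0:
        raise InvalidParameterError("zero geometry factor")
    v_w = planar.water_volume
    v_l_planar = planar.bilayer_volume
    return ApparentRates(
        k_wo_lo=(v_w / liposome.v_wo) * a_ratio * rates.k_in,
        k_wi_li=(v_w / liposome.v_wi) * a_ratio * rates.k_in,
        k_lo_wo=(v_l_planar / liposome.v_lo) * a_ratio * rates.k_out,
        k_li_wi=(v_l_planar / liposome.v_li) * a_ratio * rates.k_out,
        k_lo_li=(v_l_planar / liposome.v_lo) * a_ratio * rates.k_flip,
        k_li_lo=(v_l_planar / liposome.v_li) * a_ratio * rates.k_flip,
    )


def solve_master_numeric(
    rates: ApparentRates,
    s0=None,
    times=None,
    rtol: float = 1e-10,
    atol: float = 1e-13,
) -> CompartmentTrajectory:
    """Integrate the master equations with a stiff-capable ODE solver.

    Default initial condition: all solute in the outer water,
    S0 = (1, 0, 0, 0).  Times must be increasing (ns).
    """
    k = rates.rate_matrix()
    s0 = np.array([1.0, 0.0, 0.0, 0.0]) if s0 is None else np.asarray(s0, float)
    if np.any(s0 < 0):
        raise InvalidParameterError("initial amounts must be non-negative")
    if times is None:
        scale = max(np.max(np.abs(np.diag(k))), 1e-30)
        times = np.logspace(-2, 2, 200) / scale
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise InvalidParameterError("times must be strictly increasing")
    t0 = min(0.0, times[0])
    sol = solve_ivp(
        lambda _, y: k @ y,
        (t0, times[-1]),
        s0,
        t_eval=times,
        method="LSODA",
        jac=lambda _, y: k,
        rtol=rtol,
        atol=atol * max(s0.sum(), 1.0),
    )
    if not sol.success:
        raise InvalidParameterError(f"ODE integration failed: {sol.message}")
    return CompartmentTrajectory(times=times, amounts=sol.y.T)


def solve_master_analytic(rates: ApparentRates, s0=None) -> KineticSolution:
    """Closed-form eigen-solution of the master equations.

    Diagonalizes the 4x4 generator K; the eigen-rates are kappa_n = -Re
    lambda_n (exactly one zero for a connected chain, by mass conservation).
    Raises a degenerate-spectrum error when K is defective, in which case
    the numeric solver applies.
    """
    k = rates.rate_matrix()
    s0 = np.array([1.0, 0.0, 0.0, 0.0]) if s0 is None else np.asarray(s0, float)
    evals, evecs = scipy.linalg.eig(k)
    if np.max(np.abs(evals.imag)) > 1e-9 * max(np.max(np.abs(evals)), 1.0):
        raise DegenerateSpectrumError(
            f"complex eigenvalues {evals}; use solve_master_numeric"
        )
    evals = evals.real
    evecs = evecs.real
    cond = np.linalg.cond(evecs)
    if not np.isfinite(cond) or cond > 1e12:
        raise DegenerateSpectrumError(
            "defective rate matrix (repeated eigenvalue without full "
            "eigenspace); use solve_master_numeric"
        )
    coef = np.linalg.solve(evecs, s0)
    amplitudes = evecs * coef[None, :]  # (compartment, mode)
    kappa = -evals
    # snap the conserved mode to exactly zero
    scale = max(np.max(np.abs(kappa)), 1.0)
    izero = int(np.argmin(np.abs(kappa)))
    if abs(kappa[izero]) > 1e-9 * scale:
        raise DegenerateSpectrumError("no zero eigen-rate found")
    kappa[izero] = 0.0
    kappa = np.where(np.abs(kappa) < 1e-14 * scale, 0.0, kappa)
    order = np.argsort(kappa)
    return KineticSolution(
        eigen_rates=kappa[order], amplitudes=amplitudes[:, order], s0=s0
    )


def fit_biexponential(times, signal, p0=None) -> BiexpFit:
    """Nonlinear least-squares fit of a plateau-plus-two-exponentials decay.

    Initialization follows a log-linear fit of the tail (slow phase) and of
    the early residual (fast phase).  The faster recovered rate is labelled
    k_fast.  A near-degenerate fit (k_fast ~ k_slow or a vanishing
    amplitude) is flagged.
    """
    times = np.asarray(times, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if len(times) < 6:
        raise InvalidParameterError("need at least 6 points for a biexponential fit")
    if not np.all(np.isfinite(signal)):
        raise InvalidParameterError("signal must be finite")

    if p0 is None:
        plateau0 = signal[-1]
        resid = signal - plateau0
        span = max(times[-1] - times[0], 1e-30)
        # log-linear tail fit for the slow rate
        tail = slice(len(times) // 2, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            logr = np.log(np.abs(resid[tail]))
        good = np.isfinite(logr)
        if good.sum() >= 2:
            slope = np.polyfit(times[tail][good], logr[good], 1)[0]
            k_slow0 = max(-slope, 1e-3 / span)
        else:
            k_slow0 = 1.0 / span
        k_fast0 = 10.0 * k_slow0
        a0 = resid[0] if abs(resid[0]) > 0 else 1.0
        p0 = (plateau0, 0.5 * a0, k_fast0, 0.5 * a0, k_slow0)

    def model(t, c, a1, k1, a2, k2):
        return c + a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t)

    try:
        popt, _ = curve_fit(
            model,
            times,
            signal,
            p0=p0,
            maxfev=20000,
            bounds=(
                [-np.inf, -np.inf, 1e-300, -np.inf, 1e-300],
                [np.inf, np.inf, np.inf, np.inf, np.inf],
            ),
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"biexponential fit failed: {exc}") from exc
    c, a1, k1, a2, k2 = popt
    if k1 < k2:
        a1, k1, a2, k2 = a2, k2, a1, k1
    resid_norm = float(np.linalg.norm(model(times, *popt) - signal))
    degenerate = bool(
        k1 < 1.05 * k2
        or abs(a1) < 1e-6 * max(abs(a1) + abs(a2), 1e-30)
        or abs(a2) < 1e-6 * max(abs(a1) + abs(a2), 1e-30)
    )
    return BiexpFit(
        k_fast=float(k1),
        k_slow=float(k2),
        amp_fast=float(a1),
        amp_slow=float(a2),
        plateau=float(c),
        residual_norm=resid_norm,
        degenerate=degenerate,
    )


def permeability_from_rate(
    k_fast: float,
    liposome: LiposomeGeometry,
    unit: str = "ns^-1",
    method: str = "MSM-kinetics",
    metadata=None,
) -> PermeabilityResult:
    """P = (V_wi / A_l) k = (r/3) k, reported in cm/s.

    ``k_fast`` is the fast-phase rate constant (by default the largest
    eigen-rate of the analytic solution), in ns^-1 or s^-1 per ``unit``.
    """
    if k_fast <= 0:
        raise InvalidParameterError("k_fast must be positive")
    if unit == "ns^-1":
        k_ns = k_fast
    elif unit == "s^-1":
        k_ns = k_fast / PER_NS_TO_PER_S
    else:
        raise InvalidParameterError(f"unknown rate unit {unit!r}")
    p_nm_ns = liposome.radius / 3.0 * k_ns
    return PermeabilityResult.from_p(
        method,
        p_nm_ns * NM_PER_NS_TO_CM_PER_S,
        metadata=metadata or {"radius_nm": liposome.radius},
    )


def planar_permeability_from_rates(
    rates: RateSet, planar: PlanarGeometry, metadata=None
) -> PermeabilityResult:
    """Steady-state planar permeability implied by the three rates.

    Each kinetic step carries an intrinsic permeability P = k V_donor / A_L;
    crossing the whole bilayer traverses entry, flip-flop and exit in
    series, so the resistances add:

        1/P = 1/(k_in V_W / A_L) + 1/(k_flip V_L / A_L) + 1/(k_out V_L / A_L)

    This is the direct planar counterpart of the ISDM estimate and does not
    involve the liposome geometry.
    """
    p_in = rates.k_in * planar.water_volume / planar.area
    p_flip = rates.k_flip * planar.bilayer_volume / planar.area
    p_out = rates.k_out * planar.bilayer_volume / planar.area
    p = 1.0 / (1.0 / p_in + 1.0 / p_flip + 1.0 / p_out)  # nm/ns
    return PermeabilityResult.from_p(
        "MSM-planar",
        p * NM_PER_NS_TO_CM_PER_S,
        metadata=metadata or {},
    )
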