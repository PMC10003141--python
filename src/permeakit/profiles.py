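"""Parametric 1D free-energy and diffusion landscapes along the membrane normal.

The free-energy profile :math:`\\Delta G(z)` is modelled as a sum of Gaussian
bumps and wells on a zero baseline, mirrored about the bilayer center z = 0,
so that forces are analytic and individual features (barrier heights and
positions) can be controlled independently.  The default parameters emulate a
cyclic-decapeptide permeation landscape: a large flip-flop barrier at the
bilayer center, smaller interfacial barriers at the lipid headgroup surfaces,
and shallow minima inside each leaflet at roughly the bulk-water level.

The position-dependent diffusion coefficient D(z) is a smooth sigmoidal
interpolation between a bulk-water value far from the membrane and a smaller
value inside the bilayer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError

__all__ = [
    "PotentialProfile",
    "DiffusionProfile",
    "make_fep_profile",
    "make_diffusion_profile",
]


@dataclass(frozen=True)
class PotentialProfile:
    """Free-energy profile ΔG(z) in kcal/mol on a symmetric grid (nm).

    ``centers/heights/widths`` parameterize the Gaussian mixture (signed
    centers, already mirrored); ``offset`` is the constant subtracted so
    that ΔG(±zmax) = 0 exactly.
    """

    grid: np.ndarray
    values: np.ndarray
    centers: np.ndarray
    heights: np.ndarray
    widths: np.ndarray
    pair_centers: np.ndarray  # half-profile feature centers, >= 0
    pair_heights: np.ndarray
    pair_widths: np.ndarray
    offset: float
    zmax: float
    descriptor: dict = field(default_factory=dict)

    def energy(self, z):
        """ΔG(z) in kcal/mol at arbitrary positions (vectorized).

        Mirrored feature pairs are summed first so that G(-z) == G(z)
        exactly in floating point.
        """
        z = np.asarray(z, dtype=float)
        g = -self.offset * np.ones_like(z)
        for c, h, w in zip(self.pair_centers, self.pair_heights, self.pair_widths):
            if c == 0.0:
                g = g + h * np.exp(-(z * z) / (2.0 * w * w))
            else:
                g = g + h * (
                    np.exp(-((z - c) ** 2) / (2.0 * w * w))
                    + np.exp(-((z + c) ** 2) / (2.0 * w * w))
                )
        return g

    def gradient(self, z):
        """dG/dz in kcal/mol/nm at arbitrary positions (vectorized)."""
        z = np.asarray(z, dtype=float)
        dg = np.zeros_like(z)
        for c, h, w in zip(self.centers, self.heights, self.widths):
            dg = dg - h * (z - c) / (w * w) * np.exp(
                -((z - c) ** 2) / (2.0 * w * w)
            )
        return dg


@dataclass(frozen=True)
class DiffusionProfile:
    """Position-dependent diffusion coefficient D(z) in nm²/ns.

    Logistic interpolation in |z| between the membrane-interior value
    ``d_membrane`` and the bulk-water value ``d_water``, switching at
    ``z_interface`` over a width ``interface_width``.
    """

    grid: np.ndarray
    values: np.ndarray
    d_water: float
    d_membrane: float
    z_interface: float
    interface_width: float
    descriptor: dict = field(default_factory=dict)

    def value(self, z):
        z = np.asarray(z, dtype=float)
        x = (np.abs(z) - self.z_interface) / self.interface_width
        return self.d_membrane + (self.d_water - self.d_membrane) / (
            1.0 + np.exp(-x)
        )

    def gradient(self, z):
        """dD/dz in nm/ns (Itô drift correction term)."""
        z = np.asarray(z, dtype=float)
        x = (np.abs(z) - self.z_interface) / self.interface_width
        sig = 1.0 / (1.0 + np.exp(-x))
        return (
            (self.d_water - self.d_membrane)
            * sig
            * (1.0 - sig)
            / self.interface_width
            * np.sign(z)
        )


def _mirrored_features(features):
    """Expand (center>=0, height, width) triples into a signed, even list.

    Returns both the signed list (for the integrator kernel) and the
    half-profile pair list (for exactly-even energy evaluation).
    """
    centers, heights, widths = [], [], []
    pc, ph, pw = [], [], []
    for c, h, w in features:
        if w <= 0:
            raise InvalidParameterError(f"feature width must be positive, got {w}")
        if h == 0.0:
            continue
        pc.append(c)
        ph.append(h)
        pw.append(w)
        if c == 0.0:
            centers.append(0.0)
            heights.append(h)
            widths.append(w)
        else:
            centers.extend([-c, c])
            heights.extend([h, h])
            widths.extend([w, w])
    as_arr = lambda x: np.asarray(x, dtype=float)
    return (as_arr(centers), as_arr(heights), as_arr(widths),
            as_arr(pc), as_arr(ph), as_arr(pw))


def make_fep_profile(
    barrier_flip: float = 12.0,
    barrier_interface: float = 3.0,
    well_depth: float = 0.3,
    z_interface: float = 2.4,
    z_well: float = 1.4,
    flip_width: float = 0.4,
    interface_width: float = 0.3,
    well_width: float = 0.3,
    zmax: float = 4.0,
    spacing: float = 0.01,
) -> PotentialProfile:
    """Build an even double-barrier free-energy profile ΔG(z).

    Defaults place a ``barrier_flip`` = 12 kcal/mol flip-flop barrier at
    z = 0, ``barrier_interface`` = 3 kcal/mol headgroup barriers at
    |z| = 2.4 nm, and shallow wells (depth ~0 relative to bulk water) at
    |z| = 1.4 nm, with ΔG(±zmax) = 0.

    Parameters are heights in kcal/mol, positions/widths in nm.  Heights of 0
    remove the corresponding feature; all heights 0 gives a flat profile.
    """
    if zmax <= 0:
        raise InvalidParameterError(f"zmax must be positive, got {zmax}")
    if spacing <= 0:
        raise InvalidParameterError(f"grid spacing must be positive, got {spacing}")
    for name, val in (("z_interface", z_interface), ("z_well", z_well)):
        if not (0 < val < zmax):
            raise InvalidParameterError(f"{name} must lie in (0, zmax), got {val}")
    if not z_well < z_interface:
        raise InvalidParameterError(
            f"features overlap: z_well={z_well} must be < z_interface={z_interface}"
        )

    features = [
        (0.0, barrier_flip, flip_width),
        (z_interface, barrier_interface, interface_width),
        (z_well, -abs(well_depth), well_width),
    ]
    centers, heights, widths, pc, ph, pw = _mirrored_features(features)

    n = int(round(zmax / spacing))
    half = np.arange(n + 1) * spacing
    grid = np.concatenate([-half[:0:-1], half])

    raw = np.zeros_like(grid)
    for c, h, w in zip(pc, ph, pw):
        if c == 0.0:
            raw += h * np.exp(-(grid * grid) / (2.0 * w * w))
        else:
            raw += h * (
                np.exp(-((grid - c) ** 2) / (2.0 * w * w))
                + np.exp(-((grid + c) ** 2) / (2.0 * w * w))
            )
    # shift so the bulk-water edges are exactly 0
    offset = raw[-1]
    profile = PotentialProfile(
        grid=grid,
        values=raw - offset,
        centers=centers,
        heights=heights,
        widths=widths,
        pair_centers=pc,
        pair_heights=ph,
        pair_widths=pw,
        offset=offset,
        zmax=zmax,
        descriptor={
            "form": "mirrored_gaussian_mixture",
            "barrier_flip": barrier_flip,
            "barrier_interface": barrier_interface,
            "well_depth": well_depth,
            "z_interface": z_interface,
            "z_well": z_well,
            "flip_width": flip_width,
            "interface_width": interface_width,
            "well_width": well_width,
            "zmax": zmax,
        },
    )
    return profile


def make_diffusion_profile(
    d_water: float = 0.5,
    d_membrane: float = 0.1,
    z_interface: float = 2.4,
    interface_width: float = 0.3,
    zmax: float = 4.0,
    spacing: float = 0.01,
) -> DiffusionProfile:
    """Build a smooth, even D(z) interpolating bulk and membrane values.

    ``d_water`` applies for |z| >> z_interface, ``d_membrane`` inside the
    bilayer; both in nm²/ns.  ``d_water == d_membrane`` yields a constant
    profile.
    """
    if d_water <= 0 or d_membrane <= 0:
        raise InvalidParameterError(
            f"diffusion coefficients must be positive, got D_w={d_water}, "
            f"D_m={d_membrane}"
        )
    if interface_width <= 0:
        raise InvalidParameterError(
            f"interface_width must be positive, got {interface_width}"
        )
    if zmax <= 0 or spacing <= 0:
        raise InvalidParameterError("zmax and spacing must be positive")

    n = int(round(zmax / spacing))
    half = np.arange(n + 1) * spacing
    grid = np.concatenate([-half[:0:-1], half])
    prof = DiffusionProfile(
        grid=grid,
        values=np.empty_like(grid),
        d_water=d_water,
        d_membrane=d_membrane,
        z_interface=z_interface,
        interface_width=interface_width,
        descriptor={
            "form": "logistic_abs_z",
            "d_water": d_water,
            "d_membrane": d_membrane,
            "z_interface": z_interface,
            "interface_width": interface_width,
        },
    )
    object.__setattr__(prof, "values", prof.value(grid))
    return prof
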