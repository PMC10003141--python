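"""Synthetic simulation campaigns: umbrella ladders plus unbiased swarms.

A campaign reproduces the data layout of the reference membrane-permeation
study: an umbrella ladder of windows every 0.1 nm from the bulk water
(z = 4 nm) to the bilayer center (z = 0), and swarms of unconstrained
trajectories launched from the landscape's transition regions
(z = 0.0, 2.3, 2.4 and 2.6 nm, 75 replicas each by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .constants import DEFAULT_TEMPERATURE, KJ_TO_KCAL
from .dynamics import derive_seed, simulate_unbiased, simulate_window
from .exceptions import InvalidParameterError
from .fileio import write_manifest, write_xvg
from .profiles import make_diffusion_profile, make_fep_profile

__all__ = ["CampaignConfig", "run_campaign", "generate_windows", "generate_unbiased"]

#: umbrella stiffness: 1000 kJ/mol/nm^2 in kcal/mol/nm^2
DEFAULT_FORCE_CONSTANT = 1000.0 * KJ_TO_KCAL


@dataclass(frozen=True)
class CampaignConfig:
    """Layout and physical parameters of a synthetic campaign."""

    potential: dict = field(default_factory=dict)
    diffusion: dict = field(default_factory=dict)
    temperature: float = DEFAULT_TEMPERATURE
    master_seed: int = 2023

    window_centers: tuple = tuple(np.round(np.arange(0.0, 4.0001, 0.1), 10))
    force_constant: float = DEFAULT_FORCE_CONSTANT
    window_n_steps: int = 1_000_000
    window_save_stride: int = 10

    unbiased_starts: tuple = (0.0, 2.3, 2.4, 2.6)
    unbiased_replicas: int = 75
    unbiased_n_steps: int = 1_000_000
    unbiased_save_stride: int = 100

    timestep: float = 1e-4  # ns

    @classmethod
    def from_dict(cls, cfg: dict) -> "CampaignConfig":
        cfg = dict(cfg or {})
        if "force_constant_kj_per_nm2" in cfg:
            cfg["force_constant"] = cfg.pop("force_constant_kj_per_nm2") * KJ_TO_KCAL
        for key in ("window_centers", "unbiased_starts"):
            if key in cfg:
                cfg[key] = tuple(cfg[key])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise InvalidParameterError(f"unknown campaign config keys: {sorted(unknown)}")
        return cls(**cfg)

    def with_(self, **kwargs) -> "CampaignConfig":
        return replace(self, **kwargs)

    def build_profiles(self):
        return (
            make_fep_profile(**self.potential),
            make_diffusion_profile(**self.diffusion),
        )


def generate_windows(config: CampaignConfig):
    """Simulate all umbrella windows of the campaign (in memory)."""
    centers = list(config.window_centers)
    if len(set(centers)) != len(centers):
        raise InvalidParameterError("duplicate window centers in campaign config")
    potential, diffusion = config.build_profiles()
    windows = []
    for i, center in enumerate(centers):
        windows.append(
            simulate_window(
                potential,
                diffusion,
                center=center,
                force_constant=config.force_constant,
                n_steps=config.window_n_steps,
                timestep=config.timestep,
                seed=derive_seed(config.master_seed, "window", i),
                save_stride=config.window_save_stride,
                temperature=config.temperature,
            )
        )
    return windows


def generate_unbiased(config: CampaignConfig, starts=None, replicas=None):
    """Simulate the unbiased swarm (in memory), grouped in one flat list."""
    starts = list(config.unbiased_starts if starts is None else starts)
    replicas = config.unbiased_replicas if replicas is None else replicas
    potential, diffusion = config.build_profiles()
    trajs = []
    for j, start in enumerate(starts):
        for r in range(replicas):
            trajs.append(
                simulate_unbiased(
                    potential,
                    diffusion,
                    start=start,
                    n_steps=config.unbiased_n_steps,
                    timestep=config.timestep,
                    seed=derive_seed(
                        config.master_seed, f"unbiased:{start:g}", r
                    ),
                    save_stride=config.unbiased_save_stride,
                    temperature=config.temperature,
                )
            )
    return trajs


def run_campaign(config: CampaignConfig, outdir) -> Path:
    """Run the full campaign and write one .xvg per trajectory plus a manifest.

    Returns the manifest path.  Rerunning with the same master seed produces
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []

    centers = list(config.window_centers)
    if len(set(centers)) != len(centers):
        raise InvalidParameterError("duplicate window centers in campaign config")
    potential, diffusion = config.build_profiles()

    for i, center in enumerate(centers):
        seed = derive_seed(config.master_seed, "window", i)
        traj = simulate_window(
            potential,
            diffusion,
            center=center,
            force_constant=config.force_constant,
            n_steps=config.window_n_steps,
            timestep=config.timestep,
            seed=seed,
            save_stride=config.window_save_stride,
            temperature=config.temperature,
        )
        fname = f"window_{i:03d}.xvg"
        write_xvg(
            outdir / fname,
            traj.times,
            traj.positions,
            metadata={
                "kind": "window",
                "center": f"{center:g}",
                "force_constant": f"{config.force_constant:.10g}",
                "seed": seed,
                "timestep": f"{traj.timestep:g}",
            },
            comment="umbrella window trajectory: time (ns), z (nm)",
        )
        entries.append(
            {
                "file": fname,
                "kind": "window",
                "center": center,
                "force_constant": config.force_constant,
                "seed": seed,
                "timestep": traj.timestep,
            }
        )

    for j, start in enumerate(config.unbiased_starts):
        for r in range(config.unbiased_replicas):
            seed = derive_seed(config.master_seed, f"unbiased:{start:g}", r)
            traj = simulate_unbiased(
                potential,
                diffusion,
                start=start,
                n_steps=config.unbiased_n_steps,
                timestep=config.timestep,
                seed=seed,
                save_stride=config.unbiased_save_stride,
                temperature=config.temperature,
            )
            fname = f"unbiased_{j:02d}_{r:03d}.xvg"
            write_xvg(
                outdir / fname,
                traj.times,
                traj.positions,
                metadata={
                    "kind": "unbiased",
                    "start": f"{start:g}",
                    "seed": seed,
                    "timestep": f"{traj.timestep:g}",
                },
                comment="unbiased trajectory: time (ns), z (nm)",
            )
            entries.append(
                {
                    "file": fname,
                    "kind": "unbiased",
                    "start": start,
                    "seed": seed,
                    "timestep": traj.timestep,
                }
            )

    return write_manifest(outdir / "manifest.json", entries)
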