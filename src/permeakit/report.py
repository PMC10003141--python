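"""End-to-end method comparison: ISDM vs MSM-driven liposome kinetics.

Produces a per-method table of logP ± sigma (log10 of the permeability in
cm/s) from a campaign directory of umbrella windows and unbiased
trajectories, mirroring the grouping of unbiased starting points into
separate Markov models (one per starting-point subset plus one with all).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import DEFAULT_TEMPERATURE
from .dynamics import UnbiasedTrajectory, WindowTrajectory
from .exceptions import PermeakitError
from .fileio import read_manifest, read_xvg
from .isdm import PermeabilityResult, isdm_pipeline
from .kinetics import (
    apparent_rates,
    build_liposome_geometry,
    build_planar_geometry,
    permeability_from_rate,
    solve_master_analytic,
)
from .msm import (
    RateSet,
    discretize_trajectories,
    estimate_markov_model,
    pcca_partition,
    rates_from_mfpt,
    sample_rate_posterior,
)

__all__ = ["ComparisonReport", "compare_methods", "load_campaign", "msm_permeability"]


@dataclass(frozen=True)
class ComparisonReport:
    """Rows of (method, logP, sigma_logP) plus provenance and gaps."""

    rows: list = field(default_factory=list)
    gaps: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self):
        return {
            "schema_version": 1,
            "rows": self.rows,
            "gaps": self.gaps,
            "provenance": self.provenance,
        }

    def to_json(self, path=None):
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def load_campaign(campaign_dir):
    """Load windows and unbiased trajectories listed in a campaign manifest."""
    campaign_dir = Path(campaign_dir)
    entries = read_manifest(campaign_dir / "manifest.json")
    windows, unbiased = [], []
    for e in entries:
        times, positions, _ = read_xvg(campaign_dir / e["file"])
        if e["kind"] == "window":
            windows.append(
                WindowTrajectory(
                    center=float(e["center"]),
                    force_constant=float(e["force_constant"]),
                    times=times,
                    positions=positions,
                    timestep=float(e["timestep"]),
                    seed=int(e["seed"]),
                )
            )
        elif e["kind"] == "unbiased":
            unbiased.append(
                UnbiasedTrajectory(
                    start=float(e["start"]),
                    times=times,
                    positions=positions,
                    timestep=float(e["timestep"]),
                    seed=int(e["seed"]),
                )
            )
    return windows, unbiased


def msm_permeability(
    trajs,
    lag_time: float = 0.3,
    bin_width: float = 0.1,
    zmax: float = 4.0,
    boundary_margin: float = 0.5,
    z_threshold: float = 2.0,
    n_posterior: int = 100,
    seed: int = 0,
    planar=None,
    liposome=None,
    method: str = "MSM-kinetics",
):
    """Unbiased trajectories -> MSM -> rates -> liposome kinetics -> P.

    Returns (PermeabilityResult, RateSet summary).  sigma_logP is the
    standard deviation of logP over the transition-matrix posterior sample.
    """
    planar = planar or build_planar_geometry()
    liposome = liposome or build_liposome_geometry()

    dt = trajs[0].timestep
    lag = max(int(round(lag_time / dt)), 1)
    lim = zmax + boundary_margin
    n_half = int(np.ceil(lim / bin_width))
    edges = np.arange(-n_half, n_half + 1) * bin_width
    dtrajs = discretize_trajectories(trajs, edges)
    model = estimate_markov_model(dtrajs, lag, edges, dt=dt)
    partition = pcca_partition(model, n_sets=4, z_threshold=z_threshold)
    rates = rates_from_mfpt(model, partition)

    def one_log_p(rs: RateSet) -> float:
        sol = solve_master_analytic(apparent_rates(rs, planar, liposome))
        return math.log10(
            permeability_from_rate(sol.fastest_rate, liposome).p_cm_per_s
        )

    point_log_p = one_log_p(rates)
    sigma = None
    summary = rates
    if n_posterior > 0:
        samples, summary = sample_rate_posterior(
            model, partition, n_samples=n_posterior, seed=seed
        )
        logs = np.array([one_log_p(rs) for rs in samples])
        point_log_p = float(np.mean(logs))
        sigma = float(np.std(logs, ddof=1)) if len(logs) > 1 else 0.0

    result = PermeabilityResult.from_p(
        method,
        10.0**point_log_p,
        sigma_log_p=sigma,
        metadata={
            "lag_ns": model.lag,
            "n_states": model.n_states,
            "n_posterior": n_posterior,
            "seed": seed,
        },
    )
    return result, summary


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def compare_methods(campaign_dir, config: dict | None = None) -> ComparisonReport:
    """Run both permeability routes on a campaign and report logP per method.

    The ISDM row comes from the umbrella windows; one MSM row is produced
    per configured starting-point subset (default: each nonzero start paired
    with the barrier-top start, plus one model over all trajectories).
    Missing inputs yield gap entries instead of rows.
    """
    config = dict(config or {})
    seed = int(config.get("seed", 0))
    windows, unbiased = load_campaign(campaign_dir)
    rows, gaps = [], []

    if windows:
        isdm_cfg = dict(config.get("isdm", {}))
        isdm_cfg.setdefault("temperature", config.get("temperature", DEFAULT_TEMPERATURE))
        result = isdm_pipeline(
            windows,
            isdm_cfg,
            n_boot=int(config.get("n_boot", 0)),
            seed=seed,
        )
        rows.append(
            {
                "method": "ISDM",
                "log_p": result.log_p,
                "sigma_log_p": result.sigma_log_p,
                "n_windows": len(windows),
            }
        )
    else:
        gaps.append({"method": "ISDM", "reason": "no umbrella windows in campaign"})

    if unbiased:
        starts = sorted({t.start for t in unbiased})
        variants = config.get("msm_variants")
        if variants is None:
            anchor = min(starts, key=abs)
            variants = {}
            for s in starts:
                if s != anchor:
                    variants[f"MSM_{s:g}"] = [anchor, s]
            variants["MSM_all"] = list(starts)
        msm_cfg = dict(config.get("msm", {}))
        for name, subset in variants.items():
            group = [t for t in unbiased if any(math.isclose(t.start, s) for s in subset)]
            if not group:
                gaps.append({"method": name, "reason": "no trajectories for subset"})
                continue
            try:
                result, rates = msm_permeability(
                    group,
                    seed=seed,
                    n_posterior=int(config.get("n_posterior", 100)),
                    **msm_cfg,
                )
            except PermeakitError as exc:
                gaps.append({"method": name, "reason": str(exc)})
                continue
            rows.append(
                {
                    "method": name,
                    "log_p": result.log_p,
                    "sigma_log_p": result.sigma_log_p,
                    "n_trajectories": len(group),
                    "k_in": rates.k_in,
                    "k_out": rates.k_out,
                    "k_flip": rates.k_flip,
                }
            )
    else:
        gaps.append({"method": "MSM", "reason": "no unbiased trajectories in campaign"})

    return ComparisonReport(
        rows=rows,
        gaps=gaps,
        provenance={
            "campaign_dir": str(campaign_dir),
            "config_hash": _config_hash(config),
            "seed": seed,
        },
    )
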