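"""Markov State Models of membrane permeation along z.

Trajectories of the membrane-normal coordinate are discretized on a signed-z
grid, a transition matrix is estimated at a lag time in the implied-timescale
plateau, validated with a Chapman–Kolmogorov test, coarse-grained with PCCA+
into four metastable states (outer/inner water, outer/inner leaflet), and the
entry, exit and flip-flop rate constants are obtained as inverse mean first
passage times.  Uncertainties come from sampling row-wise Dirichlet
posteriors of the transition matrix given the observed transition counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .exceptions import (
    ConnectivityError,
    CoverageError,
    InvalidParameterError,
    PartitionError,
    UnreachableStateError,
)

__all__ = [
    "MarkovModel",
    "MetastablePartition",
    "RateSet",
    "discretize_trajectories",
    "estimate_markov_model",
    "implied_timescales",
    "chapman_kolmogorov",
    "pcca_partition",
    "mfpt",
    "rates_from_mfpt",
    "sample_rate_posterior",
    "stationary_fep",
]

SEMANTIC_LABELS = ("water_outer", "leaflet_outer", "leaflet_inner", "water_inner")


@dataclass(frozen=True)
class MarkovModel:
    """Transition matrix at lag tau over the visited (connected) z bins."""

    bin_edges: np.ndarray  # nm, over signed z
    lag: float  # ns
    lag_frames: int
    counts: np.ndarray  # (n, n) integer counts on the active set
    transition: np.ndarray  # row-stochastic
    stationary: np.ndarray  # pi
    eigenvalues: np.ndarray  # sorted descending by real part
    active_set: np.ndarray  # original bin index of each model state

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]

    @property
    def state_centers(self) -> np.ndarray:
        """Bin-center z (nm) of each model state."""
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return centers[self.active_set]


@dataclass(frozen=True)
class MetastablePartition:
    """PCCA+ soft memberships and crisp assignment of microstates to sets."""

    memberships: np.ndarray  # (n_states, n_sets), rows sum to 1
    assignment: np.ndarray  # argmax set per microstate
    labels: dict = field(default_factory=dict)  # semantic label -> set index
    mean_z: np.ndarray = None  # pi-weighted mean z per set

    @property
    def n_sets(self) -> int:
        return self.memberships.shape[1]

    def set_states(self, idx: int) -> np.ndarray:
        return np.nonzero(self.assignment == idx)[0]


@dataclass(frozen=True)
class RateSet:
    """Entry/exit/flip-flop rate constants (ns^-1) with standard errors."""

    k_in: float
    k_out: float
    k_flip: float
    err_in: float = 0.0
    err_out: float = 0.0
    err_flip: float = 0.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if min(self.k_in, self.k_out, self.k_flip) <= 0:
            raise InvalidParameterError("all rates must be positive")
        if min(self.err_in, self.err_out, self.err_flip) < 0:
            raise InvalidParameterError("rate errors must be non-negative")


def discretize_trajectories(trajs, bin_edges):
    """Map z time series to bin-index sequences.

    Bins are half-open [lo, hi); the last bin is closed.  ``trajs`` may be
    trajectory objects with a ``positions`` attribute or plain arrays.
    Samples outside the bins raise a coverage error.
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    if len(bin_edges) < 2 or np.any(np.diff(bin_edges) <= 0):
        raise InvalidParameterError("bin_edges must be strictly increasing, len >= 2")
    dtrajs = []
    for traj in trajs:
        z = np.asarray(getattr(traj, "positions", traj), dtype=float)
        if z.min() < bin_edges[0] or z.max() > bin_edges[-1]:
            raise CoverageError(
                f"samples outside bins: data span [{z.min():.4f}, {z.max():.4f}], "
                f"bins span [{bin_edges[0]:.4f}, {bin_edges[-1]:.4f}]"
            )
        idx = np.digitize(z, bin_edges) - 1
        idx[z == bin_edges[-1]] = len(bin_edges) - 2  # close the last bin
        dtrajs.append(idx.astype(np.int64))
    return dtrajs


def _count_matrix(dtrajs, lag, n_bins):
    c = np.zeros((n_bins, n_bins), dtype=np.int64)
    total = 0
    for d in dtrajs:
        if len(d) > lag:
            np.add.at(c, (d[:-lag], d[lag:]), 1)
            total += len(d) - lag
    return c, total


def _reversible_mle(c, tol=1e-12, max_iter=10_000):
    """Reversible maximum-likelihood transition matrix (fixed-point iteration)."""
    c = c.astype(float)
    c_sym = c + c.T
    row = c.sum(axis=1)
    x = c_sym.copy()
    x /= x.sum()
    for _ in range(max_iter):
        xs = x.sum(axis=1)
        denom = row[:, None] / xs[:, None] + row[None, :] / xs[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            x_new = np.where(c_sym > 0, c_sym / denom, 0.0)
        x_new /= x_new.sum()
        if np.max(np.abs(x_new - x)) < tol:
            x = x_new
            break
        x = x_new
    pi = x.sum(axis=1)
    t = x / pi[:, None]
    return t, pi


def estimate_markov_model(
    dtrajs,
    lag: int,
    bin_edges,
    dt: float = 1.0,
    reversible: bool = False,
    min_counts: int = 1,
) -> MarkovModel:
    """Estimate a Markov model at integer lag ``lag`` (in saved frames).

    Counts use the sliding-window convention; dead-end states and states
    outside the largest connected component of the count graph are dropped
    so every retained row normalizes.  ``dt`` is the
    saved-frame spacing in ns, so the model lag time is ``lag * dt``.  With
    ``reversible`` the transition matrix is the detailed-balance-constrained
    MLE; otherwise rows are normalized counts.
    """
    if lag < 1:
        raise InvalidParameterError(f"lag must be >= 1 frame, got {lag}")
    if all(len(d) <= lag for d in dtrajs):
        raise InvalidParameterError("lag exceeds every trajectory length")
    bin_edges = np.asarray(bin_edges, dtype=float)
    n_bins = len(bin_edges) - 1
    c_full, total = _count_matrix(dtrajs, lag, n_bins)
    if total < min_counts:
        raise InvalidParameterError(
            f"only {total} transition counts observed, need >= {min_counts}"
        )

    # keep the largest (weakly) connected component of visited states,
    # iteratively pruning dead ends (states entered but never left within
    # the lag) so that every retained row can be normalized
    active = np.nonzero(c_full.sum(axis=1) + c_full.sum(axis=0) > 0)[0]
    if len(active) == 0:
        raise ConnectivityError("no transitions observed")
    while True:
        c_sub = c_full[np.ix_(active, active)]
        dead = c_sub.sum(axis=1) == 0
        if not dead.any():
            break
        active = active[~dead]
        if len(active) == 0:
            raise ConnectivityError("all states are dead ends at this lag")
    c_sub = c_full[np.ix_(active, active)]
    adj = csr_matrix((c_sub > 0).astype(np.int8))
    n_comp, membership = connected_components(adj, directed=True, connection="weak")
    comp_sizes = np.bincount(membership, minlength=n_comp)
    largest = int(np.argmax(comp_sizes))
    active = active[membership == largest]
    if len(active) < 2:
        raise ConnectivityError("largest connected set has fewer than 2 states")
    c = c_full[np.ix_(active, active)]

    if reversible:
        t, pi = _reversible_mle(c)
    else:
        rows = c.sum(axis=1).astype(float)
        t = c / rows[:, None]
        evals, evecs = scipy.linalg.eig(t, left=True, right=False)
        i_one = int(np.argmin(np.abs(evals - 1.0)))
        pi = np.real(evecs[:, i_one])
        pi = np.abs(pi) / np.abs(pi).sum()

    evals = scipy.linalg.eigvals(t)
    order = np.argsort(-evals.real)
    evals = evals[order]

    return MarkovModel(
        bin_edges=bin_edges,
        lag=float(lag * dt),
        lag_frames=int(lag),
        counts=c,
        transition=t,
        stationary=pi,
        eigenvalues=evals,
        active_set=active,
    )


def implied_timescales(dtrajs, lags, bin_edges, dt=1.0, n_timescales=3,
                       reversible=False):
    """Implied relaxation timescales t_i(tau) = -tau / ln |lambda_{i+1}|.

    Returns an array of shape (len(lags), n_timescales) in the units of
    ``dt * lag``; non-positive or missing eigenvalues yield NaN.
    """
    out = np.full((len(lags), n_timescales), np.nan)
    for j, lag in enumerate(lags):
        model = estimate_markov_model(
            dtrajs, lag, bin_edges, dt=dt, reversible=reversible
        )
        evals = model.eigenvalues
        k = 0
        for lam in evals[1:]:
            if k >= n_timescales:
                break
            mod = abs(lam)
            if mod <= 0 or lam.real <= 0:
                k += 1
                continue
            if mod >= 1.0:
                warnings.warn(
                    f"eigenvalue modulus {mod:.6f} >= 1 at lag {lag}; "
                    "timescale reported as large finite"
                )
                out[j, k] = 1e12
            else:
                out[j, k] = -model.lag / np.log(mod)
            k += 1
    return out


def chapman_kolmogorov(model, dtrajs, factors=(2, 3, 4), partition=None):
    """Chapman–Kolmogorov test on metastable sets.

    For each factor k, compares the set-to-itself probability predicted by
    the model, [pi_A^T T(tau)^k 1_A] / pi(A), with the same quantity from a
    model estimated directly at lag k*tau.  Returns a dict
    {(k, set_index): (predicted, estimated, |deviation|)}.
    """
    if partition is None:
        sets = [np.arange(model.n_states)]
    else:
        sets = [partition.set_states(i) for i in range(partition.n_sets)]
    results = {}
    for k in factors:
        if k == 1:
            for a, states in enumerate(sets):
                w = model.stationary[states]
                w = w / w.sum()
                p = float(w @ model.transition[np.ix_(states, states)].sum(axis=1))
                results[(1, a)] = (p, p, 0.0)
            continue
        direct = estimate_markov_model(
            dtrajs, model.lag_frames * k, model.bin_edges,
            dt=model.lag / model.lag_frames,
        )
        t_pow = np.linalg.matrix_power(model.transition, k)
        # map model states into the direct model's active set
        pos = {s: i for i, s in enumerate(direct.active_set)}
        for a, states in enumerate(sets):
            w = model.stationary[states]
            w = w / w.sum()
            pred = float(w @ t_pow[np.ix_(states, states)].sum(axis=1))
            common = [
                (i, pos[model.active_set[s]])
                for i, s in enumerate(states)
                if model.active_set[s] in pos
            ]
            if not common:
                results[(k, a)] = (pred, np.nan, np.nan)
                continue
            _, didx = zip(*common)
            didx = np.asarray(didx)
            wd = direct.stationary[didx]
            wd = wd / wd.sum()
            est = float(
                wd @ direct.transition[np.ix_(didx, didx)].sum(axis=1)
            )
            results[(k, a)] = (pred, est, abs(pred - est))
    return results


def _pcca_memberships(t, n_sets):
    """PCCA+ memberships by the inner-simplex algorithm."""
    evals, evecs = scipy.linalg.eig(t)
    order = np.argsort(-evals.real)
    evals, evecs = evals[order], evecs[:, order]
    if np.max(np.abs(evals[:n_sets].imag)) > 1e-8:
        warnings.warn("complex eigenvalues among the dominant spectrum; "
                      "taking real parts (non-reversible estimate)")
    x = np.real(evecs[:, :n_sets]).copy()
    x[:, 0] = 1.0  # the Perron eigenvector is constant

    n = x.shape[0]
    # inner-simplex vertex search: farthest point, then Gram-Schmidt
    vertices = []
    ortho = x.copy()
    idx = int(np.argmax(np.linalg.norm(ortho, axis=1)))
    for _ in range(n_sets):
        vertices.append(idx)
        v = ortho[idx] / np.linalg.norm(ortho[idx])
        ortho = ortho - np.outer(ortho @ v, v)
        norms = np.linalg.norm(ortho, axis=1)
        idx = int(np.argmax(norms))
    a = np.linalg.inv(x[vertices])
    chi = x @ a
    chi = np.clip(chi, 0.0, None)
    rowsum = chi.sum(axis=1)
    rowsum[rowsum == 0] = 1.0
    return chi / rowsum[:, None]


def pcca_partition(model: MarkovModel, n_sets: int = 4,
                   z_threshold: float = 2.0,
                   gap_threshold: float = 1e-3) -> MetastablePartition:
    """Coarse-grain the model into metastable sets with PCCA+.

    Crisp assignment is the argmax of the soft memberships.  Sets are given
    the semantic labels water_outer / leaflet_outer / leaflet_inner /
    water_inner from their stationary-weighted mean z: |z| beyond
    ``z_threshold`` (headgroup surface) is water, the sign of z separates
    the outer (z > 0) from the inner side.
    """
    n = model.n_states
    if not 2 <= n_sets <= n:
        raise InvalidParameterError(
            f"n_sets must be between 2 and n_states={n}, got {n_sets}"
        )
    if n_sets == n:
        memberships = np.eye(n)
    else:
        lam = np.sort(model.eigenvalues.real)[::-1]
        if lam[n_sets - 1] - (lam[n_sets] if n_sets < n else -1.0) < gap_threshold:
            warnings.warn(
                f"weak spectral gap after {n_sets} eigenvalues; "
                "metastable partition may be ill-defined"
            )
        memberships = _pcca_memberships(model.transition, n_sets)
    assignment = np.argmax(memberships, axis=1)

    # guarantee non-empty sets: reassign the most-member state if needed
    for s in range(n_sets):
        if not np.any(assignment == s):
            idx = int(np.argmax(memberships[:, s]))
            assignment[idx] = s

    centers = model.state_centers
    pi = model.stationary
    mean_z = np.empty(n_sets)
    for s in range(n_sets):
        states = np.nonzero(assignment == s)[0]
        w = pi[states]
        mean_z[s] = float(np.average(centers[states], weights=w)) if w.sum() > 0 \
            else float(np.mean(centers[states]))

    labels = {}
    if n_sets == 4:
        water = np.abs(mean_z) > z_threshold
        for s in range(4):
            if water[s]:
                labels["water_outer" if mean_z[s] > 0 else "water_inner"] = s
            else:
                labels["leaflet_outer" if mean_z[s] > 0 else "leaflet_inner"] = s
        if len(labels) < 4:
            warnings.warn(
                f"could not assign all four semantic labels (mean z = {mean_z}); "
                "got " + ", ".join(sorted(labels))
            )
    return MetastablePartition(
        memberships=memberships,
        assignment=assignment,
        labels=labels,
        mean_z=mean_z,
    )


def mfpt(model: MarkovModel, source_states, target_states,
         transition: np.ndarray | None = None,
         stationary: np.ndarray | None = None) -> float:
    """Mean first passage time (ns) from source to target sets of states.

    Solves m_i = tau + sum_{j not in target} T_ij m_j with m = 0 on the
    target, then averages m over the source with stationary weights.
    ``transition``/``stationary`` override the model matrices (used by the
    posterior sampler).
    """
    t = model.transition if transition is None else transition
    pi = model.stationary if stationary is None else stationary
    source = np.asarray(source_states, dtype=int)
    target = np.asarray(target_states, dtype=int)
    if len(source) == 0 or len(target) == 0:
        raise InvalidParameterError("source and target must be non-empty")
    if np.intersect1d(source, target).size:
        raise InvalidParameterError("source and target sets must be disjoint")
    n = t.shape[0]
    keep = np.setdiff1d(np.arange(n), target)
    a = np.eye(len(keep)) - t[np.ix_(keep, keep)]
    b = np.full(len(keep), model.lag)
    try:
        m = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise UnreachableStateError(
            "target set unreachable from part of the chain"
        ) from exc
    if np.any(~np.isfinite(m)) or np.any(m < 0):
        raise UnreachableStateError("non-finite or negative MFPT solution")
    full = np.zeros(n)
    full[keep] = m
    w = pi[source]
    if w.sum() <= 0:
        raise InvalidParameterError("source set has zero stationary weight")
    return float(np.average(full[source], weights=w))


def _three_rates(model, partition, transition=None, stationary=None):
    req = set(SEMANTIC_LABELS)
    if not req.issubset(partition.labels):
        missing = sorted(req - set(partition.labels))
        raise PartitionError(f"partition lacks semantic labels: {missing}")
    sets = {
        lab: partition.set_states(partition.labels[lab]) for lab in SEMANTIC_LABELS
    }
    kw = dict(transition=transition, stationary=stationary)
    m_in = 0.5 * (
        mfpt(model, sets["water_outer"], sets["leaflet_outer"], **kw)
        + mfpt(model, sets["water_inner"], sets["leaflet_inner"], **kw)
    )
    m_out = 0.5 * (
        mfpt(model, sets["leaflet_outer"], sets["water_outer"], **kw)
        + mfpt(model, sets["leaflet_inner"], sets["water_inner"], **kw)
    )
    m_flip = 0.5 * (
        mfpt(model, sets["leaflet_outer"], sets["leaflet_inner"], **kw)
        + mfpt(model, sets["leaflet_inner"], sets["leaflet_outer"], **kw)
    )
    return 1.0 / m_in, 1.0 / m_out, 1.0 / m_flip


def rates_from_mfpt(model: MarkovModel, partition: MetastablePartition) -> RateSet:
    """Entry/exit/flip rates (ns^-1) as inverse MFPTs, leaflet-symmetrized.

    k_in averages the two water->leaflet MFPTs (outer and inner side),
    k_out the two reverse ones, and k_flip the two flip directions.
    """
    k_in, k_out, k_flip = _three_rates(model, partition)
    return RateSet(
        k_in=k_in,
        k_out=k_out,
        k_flip=k_flip,
        provenance={"lag_ns": model.lag, "n_states": model.n_states},
    )


def sample_rate_posterior(
    model: MarkovModel,
    partition: MetastablePartition,
    n_samples: int = 100,
    seed: int = 0,
):
    """Posterior sample of RateSets from row-wise Dirichlet transition matrices.

    Each transition-matrix row is drawn from Dirichlet(counts + 1/n_states);
    MFPTs and rates are recomputed per sample.  Returns (samples, summary)
    where summary is a RateSet whose values are posterior means and whose
    errors are posterior standard deviations.
    """
    if n_samples < 1:
        raise InvalidParameterError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    n = model.n_states
    alpha = model.counts + 1.0 / n
    if np.any(model.counts.sum(axis=1) == 0):
        warnings.warn("zero-count row: posterior row is prior-only")
    samples = []
    vals = np.empty((n_samples, 3))
    for s in range(n_samples):
        t = np.empty((n, n))
        for i in range(n):
            t[i] = rng.dirichlet(alpha[i])
        evals, evecs = scipy.linalg.eig(t, left=True, right=False)
        i_one = int(np.argmin(np.abs(evals - 1.0)))
        pi = np.abs(np.real(evecs[:, i_one]))
        pi = pi / pi.sum()
        k_in, k_out, k_flip = _three_rates(
            model, partition, transition=t, stationary=pi
        )
        vals[s] = (k_in, k_out, k_flip)
        samples.append(
            RateSet(k_in=k_in, k_out=k_out, k_flip=k_flip,
                    provenance={"sample": s, "seed": seed})
        )
    mean = vals.mean(axis=0)
    if n_samples > 1:
        std = vals.std(axis=0, ddof=1)
    else:
        warnings.warn("posterior sigma undefined for a single sample")
        std = np.zeros(3)
    summary = RateSet(
        k_in=float(mean[0]),
        k_out=float(mean[1]),
        k_flip=float(mean[2]),
        err_in=float(std[0]),
        err_out=float(std[1]),
        err_flip=float(std[2]),
        provenance={
            "lag_ns": model.lag,
            "n_samples": n_samples,
            "seed": seed,
        },
    )
    return samples, summary


def stationary_fep(model: MarkovModel, temperature: float):
    """Free-energy profile ΔG = -kBT log(pi) over the model states (kcal/mol).

    Returns (state_centers, dG) with dG shifted so its minimum is 0.
    """
    from .constants import kt

    g = -kt(temperature) * np.log(np.maximum(model.stationary, 1e-300))
    g = g - g.min()
    return model.state_centers, g
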