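"""Markov-model estimation and kinetics: hand oracles, Monte-Carlo MFPT
cross-checks, PCCA+ metastability, posterior uncertainty."""

import numpy as np
import pytest

from permeakit import (
    chapman_kolmogorov,
    discretize_trajectories,
    estimate_markov_model,
    implied_timescales,
    mfpt,
    pcca_partition,
    rates_from_mfpt,
    sample_rate_posterior,
    stationary_fep,
)
from permeakit.exceptions import (
    CoverageError,
    InvalidParameterError,
    PartitionError,
)
from permeakit.msm import MarkovModel, MetastablePartition


def _chain(T, n, seed=0, start=0):
    """Sample a discrete Markov chain trajectory of length n."""
    T = np.asarray(T, dtype=float)
    rng = np.random.default_rng(seed)
    cum = np.cumsum(T, axis=1)
    s = np.empty(n, dtype=np.int64)
    s[0] = start
    u = rng.random(n)
    for t in range(1, n):
        s[t] = np.searchsorted(cum[s[t - 1]], u[t])
    return s


def _model_from_matrix(T, lag=1.0):
    """Wrap an exact transition matrix in a MarkovModel (unit bins)."""
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    evals, evecs = np.linalg.eig(T.T)
    pi = np.real(evecs[:, np.argmin(np.abs(evals - 1.0))])
    pi = np.abs(pi) / np.abs(pi).sum()
    return MarkovModel(
        bin_edges=np.arange(n + 1, dtype=float),
        lag=lag,
        lag_frames=1,
        counts=np.zeros((n, n), dtype=np.int64),
        transition=T,
        stationary=pi,
        eigenvalues=np.sort(np.linalg.eigvals(T).real)[::-1].astype(complex),
        active_set=np.arange(n),
    )


def _mc_mfpt(T, source_pi, target, n_real, lag, seed, max_steps=100_000):
    """Brute-force Monte-Carlo mean first passage time (vectorized)."""
    rng = np.random.default_rng(seed)
    T = np.asarray(T, dtype=float)
    cum = np.cumsum(T, axis=1)
    state = rng.choice(len(source_pi), size=n_real, p=source_pi)
    steps = np.zeros(n_real, dtype=np.int64)
    active = ~np.isin(state, target)
    k = 0
    while active.any():
        k += 1
        if k > max_steps:
            raise RuntimeError("MC walkers did not absorb")
        idx = np.nonzero(active)[0]
        u = rng.random(len(idx))
        nxt = np.array(
            [np.searchsorted(cum[s], x) for s, x in zip(state[idx], u)]
        )
        state[idx] = nxt
        steps[idx] = k
        active[idx] = ~np.isin(nxt, target)
    return steps.mean() * lag


class TestDiscretize:
    def test_half_open_bin_convention(self):
        edges = [-0.1, 0.0, 0.1]
        (d,) = discretize_trajectories([np.array([-0.05, 0.05])], edges)
        assert d.tolist() == [0, 1]
        (d,) = discretize_trajectories([np.array([0.0])], edges)
        assert d.tolist() == [1]
        (d,) = discretize_trajectories([np.array([0.1])], edges)
        assert d.tolist() == [1]  # last bin closed

    def test_constant_series_constant_states(self):
        (d,) = discretize_trajectories([np.full(10, 0.05)], [-0.1, 0.0, 0.1])
        assert np.all(d == 1)

    def test_out_of_range_raises(self):
        with pytest.raises(CoverageError):
            discretize_trajectories([np.array([0.5])], [-0.1, 0.0, 0.1])


class TestEstimate:
    def test_hand_counted_transition_matrix(self):
        model = estimate_markov_model(
            [np.array([0, 0, 1, 1])], lag=1, bin_edges=[0.0, 1.0, 2.0]
        )
        assert model.counts.tolist() == [[1, 1], [0, 1]]
        assert model.transition.tolist() == [[0.5, 0.5], [0.0, 1.0]]

    def test_recovers_known_three_state_chain(self):
        T = np.array([[0.90, 0.08, 0.02],
                      [0.10, 0.80, 0.10],
                      [0.05, 0.15, 0.80]])
        s = _chain(T, 300_000, seed=1)
        model = estimate_markov_model([s], lag=1, bin_edges=np.arange(4.0))
        assert np.max(np.abs(model.transition - T)) < 0.02
        assert model.stationary @ model.transition == pytest.approx(
            model.stationary, abs=1e-10
        )

    def test_symmetric_two_state_stationary(self):
        s = _chain([[0.7, 0.3], [0.3, 0.7]], 100_000, seed=2)
        model = estimate_markov_model([s], lag=1, bin_edges=np.arange(3.0))
        assert model.stationary == pytest.approx([0.5, 0.5], abs=0.01)

    def test_reversible_estimate_satisfies_detailed_balance(self):
        s = _chain([[0.9, 0.1, 0.0], [0.2, 0.6, 0.2], [0.0, 0.3, 0.7]],
                   100_000, seed=3)
        model = estimate_markov_model([s], lag=1, bin_edges=np.arange(4.0),
                                      reversible=True)
        flux = model.stationary[:, None] * model.transition
        assert np.max(np.abs(flux - flux.T)) < 1e-8

    def test_row_sums_and_lag_validation(self):
        s = _chain([[0.5, 0.5], [0.5, 0.5]], 5000, seed=4)
        model = estimate_markov_model([s], lag=3, bin_edges=np.arange(3.0),
                                      dt=0.5)
        assert model.lag == 1.5
        assert np.allclose(model.transition.sum(axis=1), 1.0, atol=1e-12)
        with pytest.raises(InvalidParameterError):
            estimate_markov_model([s], lag=0, bin_edges=np.arange(3.0))
        with pytest.raises(InvalidParameterError):
            estimate_markov_model([s[:10]], lag=10, bin_edges=np.arange(3.0))


class TestImpliedTimescales:
    def test_two_state_closed_form(self):
        # lambda_2 = 0.5 at tau = 1 -> t_2 = 1/ln 2
        s = _chain([[0.75, 0.25], [0.25, 0.75]], 2_000_000, seed=5)
        its = implied_timescales([s], [1], np.arange(3.0), dt=1.0,
                                 n_timescales=1)
        assert its[0, 0] == pytest.approx(1.0 / np.log(2.0), rel=0.05)

    def test_constant_across_lags_for_markovian_data(self):
        T = np.array([[0.95, 0.05, 0.0],
                      [0.05, 0.90, 0.05],
                      [0.0, 0.05, 0.95]])
        s = _chain(T, 500_000, seed=6)
        its = implied_timescales([s], [1, 2, 4, 8], np.arange(4.0),
                                 n_timescales=2)
        ref = its[0]
        for row in its[1:]:
            assert row == pytest.approx(ref, rel=0.15)


class TestChapmanKolmogorov:
    def test_markovian_chain_passes(self):
        T = np.array([[0.97, 0.03], [0.05, 0.95]])
        s = _chain(T, 400_000, seed=7)
        model = estimate_markov_model([s], lag=1, bin_edges=np.arange(3.0))
        part = pcca_partition(model, n_sets=2)
        res = chapman_kolmogorov(model, [s], factors=(1, 2, 3, 4),
                                 partition=part)
        for (k, a), (_, _, dev) in res.items():
            if k == 1:
                assert dev == 0.0
            else:
                assert dev < 0.01

    def test_hidden_cycle_fails(self):
        """Deterministic 3-cycle observed through a 2-state lens is strongly
        non-Markovian: CK deviations far exceed sampling error."""
        hidden = np.arange(60_000) % 3
        observed = np.where(hidden == 0, 0, 1)
        model = estimate_markov_model([observed], lag=1,
                                      bin_edges=np.arange(3.0))
        part = MetastablePartition(
            memberships=np.eye(2), assignment=np.array([0, 1]),
            labels={}, mean_z=np.zeros(2),
        )
        res = chapman_kolmogorov(model, [observed], factors=(2,),
                                 partition=part)
        assert max(dev for (_, _, dev) in res.values()) > 0.1


class TestPcca:
    def test_block_structure_recovered(self):
        T = np.array([[0.93, 0.05, 0.01, 0.01],
                      [0.05, 0.93, 0.01, 0.01],
                      [0.01, 0.01, 0.93, 0.05],
                      [0.01, 0.01, 0.05, 0.93]])
        model = _model_from_matrix(T)
        part = pcca_partition(model, n_sets=2)
        assert part.assignment[0] == part.assignment[1]
        assert part.assignment[2] == part.assignment[3]
        assert part.assignment[0] != part.assignment[2]
        assert np.allclose(part.memberships.sum(axis=1), 1.0)

    def test_identity_partition_when_sets_equal_states(self):
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        part = pcca_partition(_model_from_matrix(T), n_sets=2)
        assert sorted(part.assignment.tolist()) == [0, 1]

    def test_four_wells_from_generator_landscape(self, low_barrier_model):
        """On the double-barrier landscape the four metastable sets are the
        two water slabs and the two leaflet wells, in z order."""
        model, part = low_barrier_model
        assert part.n_sets == 4
        assert set(part.labels) == {
            "water_outer", "leaflet_outer", "leaflet_inner", "water_inner"
        }
        mz = part.mean_z
        assert mz[part.labels["water_inner"]] < mz[part.labels["leaflet_inner"]]
        assert mz[part.labels["leaflet_inner"]] < mz[part.labels["leaflet_outer"]]
        assert mz[part.labels["leaflet_outer"]] < mz[part.labels["water_outer"]]


class TestMfpt:
    def test_two_state_closed_forms(self):
        model = _model_from_matrix([[0.9, 0.1], [0.2, 0.8]], lag=1.0)
        assert mfpt(model, [0], [1]) == pytest.approx(10.0, rel=1e-12)
        model = _model_from_matrix([[0.5, 0.5], [0.5, 0.5]], lag=1.0)
        assert mfpt(model, [0], [1]) == pytest.approx(2.0, rel=1e-12)

    @pytest.mark.parametrize("n_states,seed", [(2, 10), (3, 11), (4, 12), (4, 13)])
    def test_against_monte_carlo(self, n_states, seed):
        """Linear-system MFPT equals brute-force first-passage averages on
        random chains (2% at 1e5 realizations)."""
        rng = np.random.default_rng(seed)
        T = rng.dirichlet(np.ones(n_states) * 2.0, size=n_states)
        model = _model_from_matrix(T, lag=1.0)
        target = [n_states - 1]
        source = list(range(n_states - 1))
        exact = mfpt(model, source, target)
        pi = model.stationary[source] / model.stationary[source].sum()
        src_pi = np.zeros(n_states)
        src_pi[source] = pi
        mc = _mc_mfpt(T, src_pi, target, n_real=100_000, lag=1.0, seed=seed)
        assert mc == pytest.approx(exact, rel=0.02)

    def test_disjointness_enforced(self):
        model = _model_from_matrix([[0.9, 0.1], [0.2, 0.8]])
        with pytest.raises(InvalidParameterError):
            mfpt(model, [0], [0, 1])


class TestRates:
    def _labelled_partition(self, assignment, labels, n_sets=4):
        assignment = np.asarray(assignment)
        memberships = np.eye(n_sets)[assignment]
        return MetastablePartition(
            memberships=memberships,
            assignment=assignment,
            labels=labels,
            mean_z=np.zeros(n_sets),
        )

    def test_inverse_mfpt_definition(self):
        """Symmetric 4-state chain: k_in equals the inverse of the
        water->leaflet MFPT computed directly."""
        T = np.array([[0.8, 0.2, 0.0, 0.0],
                      [0.2, 0.6, 0.2, 0.0],
                      [0.0, 0.2, 0.6, 0.2],
                      [0.0, 0.0, 0.2, 0.8]])
        model = _model_from_matrix(T, lag=1.0)
        labels = {"water_outer": 0, "leaflet_outer": 1,
                  "leaflet_inner": 2, "water_inner": 3}
        part = self._labelled_partition([0, 1, 2, 3], labels)
        rates = rates_from_mfpt(model, part)
        m_in = 0.5 * (mfpt(model, [0], [1]) + mfpt(model, [3], [2]))
        assert rates.k_in == pytest.approx(1.0 / m_in, rel=1e-12)
        # symmetric chain: both flip directions agree
        assert mfpt(model, [1], [2]) == pytest.approx(
            mfpt(model, [2], [1]), rel=1e-10
        )

    def test_flip_symmetry_on_even_landscape(self, low_barrier_model):
        model, part = low_barrier_model
        sets = {lab: part.set_states(part.labels[lab]) for lab in part.labels}
        m1 = mfpt(model, sets["leaflet_outer"], sets["leaflet_inner"])
        m2 = mfpt(model, sets["leaflet_inner"], sets["leaflet_outer"])
        assert abs(m1 - m2) / (0.5 * (m1 + m2)) < 0.3

    def test_missing_label_raises(self):
        model = _model_from_matrix(np.full((4, 4), 0.25))
        part = self._labelled_partition([0, 1, 2, 3], {"water_outer": 0})
        with pytest.raises(PartitionError):
            rates_from_mfpt(model, part)


class TestPosterior:
    def _setup(self, count_scale=1):
        T = np.array([[0.8, 0.2, 0.0, 0.0],
                      [0.2, 0.6, 0.2, 0.0],
                      [0.0, 0.2, 0.6, 0.2],
                      [0.0, 0.0, 0.2, 0.8]])
        counts = (T * 500 * count_scale).astype(np.int64)
        model = _model_from_matrix(T, lag=1.0)
        object.__setattr__(model, "counts", counts)
        labels = {"water_outer": 0, "leaflet_outer": 1,
                  "leaflet_inner": 2, "water_inner": 3}
        memberships = np.eye(4)
        part = MetastablePartition(
            memberships=memberships, assignment=np.arange(4),
            labels=labels, mean_z=np.zeros(4),
        )
        return model, part

    def test_sample_count_and_positive_sigma(self):
        model, part = self._setup()
        samples, summary = sample_rate_posterior(model, part,
                                                 n_samples=100, seed=1)
        assert len(samples) == 100
        assert summary.err_in > 0 and summary.err_out > 0 and summary.err_flip > 0

    def test_posterior_concentrates_with_counts(self):
        """100x more counts shrinks the posterior spread roughly 10x."""
        _, part = self._setup()
        model1, _ = self._setup(count_scale=1)
        model2, _ = self._setup(count_scale=100)
        _, s1 = sample_rate_posterior(model1, part, n_samples=60, seed=2)
        _, s2 = sample_rate_posterior(model2, part, n_samples=60, seed=2)
        for a, b in [(s1.err_in, s2.err_in), (s1.err_flip, s2.err_flip)]:
            assert b < a / 4.0

    def test_single_sample_sigma_flagged(self):
        model, part = self._setup()
        with pytest.warns(UserWarning):
            _, summary = sample_rate_posterior(model, part, n_samples=1, seed=3)
        assert summary.err_in == 0.0


def test_stationary_fep_recovers_landscape(low_barrier_model,
                                           low_barrier_config):
    """-kBT log(pi) over the bins reproduces the generator potential within
    0.5 kcal/mol in well-sampled regions."""
    model, _ = low_barrier_model
    centers, g = stationary_fep(model, low_barrier_config.temperature)
    pot, _ = low_barrier_config.build_profiles()
    truth = pot.energy(centers)
    truth = truth - truth.min()
    sel = np.abs(centers) < 3.5
    assert np.max(np.abs((g - truth)[sel])) < 0.5
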