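"""Shared fixtures: reference landscapes and pre-simulated campaigns.

The low-barrier landscape (flip-flop barrier ~1 kcal/mol, interfacial
barriers 0.5 kcal/mol) is the workhorse for end-to-end checks: unbiased
trajectories equilibrate across the whole membrane within a few hundred ns,
so both permeability routes are well-posed and can be compared against the
generator's ground truth.
"""

import numpy as np
import pytest

from permeakit import (
    CampaignConfig,
    generate_unbiased,
    generate_windows,
    make_diffusion_profile,
    make_fep_profile,
    run_campaign,
)

LOW_BARRIER_POTENTIAL = dict(barrier_flip=1.0, barrier_interface=0.5, well_depth=0.3)
CONSTANT_DIFFUSION = dict(d_water=0.1, d_membrane=0.1)


@pytest.fixture(scope="session")
def flat_potential():
    return make_fep_profile(barrier_flip=0.0, barrier_interface=0.0, well_depth=0.0)


@pytest.fixture(scope="session")
def constant_diffusion():
    return make_diffusion_profile(0.1, 0.1)


@pytest.fixture(scope="session")
def low_barrier_config():
    return CampaignConfig(
        potential=LOW_BARRIER_POTENTIAL,
        diffusion=CONSTANT_DIFFUSION,
        master_seed=7,
        window_n_steps=500_000,
        unbiased_replicas=10,
        unbiased_n_steps=2_000_000,
        unbiased_save_stride=100,
    )


@pytest.fixture(scope="session")
def low_barrier_windows(low_barrier_config):
    return generate_windows(low_barrier_config)


@pytest.fixture(scope="session")
def low_barrier_unbiased(low_barrier_config):
    return generate_unbiased(low_barrier_config)


@pytest.fixture(scope="session")
def low_barrier_model(low_barrier_unbiased):
    """MSM at lag 0.3 ns on 0.1 nm signed-z bins, plus its 4-set partition."""
    from permeakit import discretize_trajectories, estimate_markov_model, pcca_partition

    edges = np.arange(-45, 46) * 0.1
    dtrajs = discretize_trajectories(low_barrier_unbiased, edges)
    model = estimate_markov_model(dtrajs, lag=30, bin_edges=edges, dt=0.01)
    partition = pcca_partition(model, n_sets=4)
    return model, partition


@pytest.fixture(scope="session")
def small_campaign_dir(tmp_path_factory):
    """A miniature default-landscape campaign on disk (windows + unbiased)."""
    cfg = CampaignConfig(
        master_seed=5,
        window_n_steps=50_000,
        unbiased_replicas=2,
        unbiased_n_steps=100_000,
        unbiased_save_stride=100,
    )
    out = tmp_path_factory.mktemp("campaign")
    run_campaign(cfg, out)
    return out
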