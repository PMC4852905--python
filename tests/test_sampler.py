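"""MCMC machinery: determinism, update switches, internal consistency."""

import datetime as dt

import numpy as np
import pytest

from searchscr.effort import EffortGrid
from searchscr.encounters import EncounterData
from searchscr.grids import build_trap_grid, distance_matrix
from searchscr.model import AugmentedState, ModelVariant, complete_data_loglik
from searchscr.sampler import (PARAM_NAMES, SamplerConfig, SECRSampler,
                               gibbs_update_psi, run_chains)

from conftest import D0, make_space, random_instance


def small_survey(seed=0):
    """A hand-sized survey: 6x6 km, 36 traps, 3 occasions, 3 animals."""
    rng = np.random.default_rng(seed)
    space = make_space(extent=(0, 0, 6, 6), side=1.0)
    traps = build_trap_grid((0, 0, 6, 6), side=1.0)
    occasions = [D0 + dt.timedelta(days=k) for k in range(3)]
    eff = rng.uniform(0.5, 3.0, size=(36, 3))
    eff[rng.random((36, 3)) < 0.25] = 0.0
    effort = EffortGrid(eff, occasions)
    act_j, act_k = np.nonzero(eff > 0)
    y = np.zeros((3, 36, 3), dtype=bool)
    for i in range(3):
        pick = rng.integers(0, act_j.size, size=3)
        y[i, act_j[pick], act_k[pick]] = True
    enc = EncounterData(y=y, sex=[0, 1, 0], ids=["a", "b", "c"])
    return enc, effort, space, traps


def short_config(**kw):
    base = dict(iterations=300, burn_in=100, thin=1, chains=2, seed=42)
    base.update(kw)
    return SamplerConfig(**base)


def test_config_validation():
    with pytest.raises(ValueError):
        SamplerConfig(iterations=100, burn_in=100).validate()
    with pytest.raises(ValueError):
        SamplerConfig(thin=0).validate()
    with pytest.raises(ValueError):
        SamplerConfig(chains=0).validate()
    assert SamplerConfig(iterations=11000, burn_in=1000, thin=2).n_retained == 5000
    assert SamplerConfig(iterations=301, burn_in=100, thin=2).n_retained == 101


def test_augmented_size_must_exceed_detected():
    enc, effort, space, traps = small_survey()
    with pytest.raises(ValueError, match="exceed"):
        SECRSampler(enc, effort, space, traps, ModelVariant(1),
                    short_config(), m_total=3)


def test_same_seed_reproduces_draws_exactly():
    enc, effort, space, traps = small_survey()
    a = run_chains(enc, effort, space, traps, ModelVariant(1),
                   short_config(), m_total=20)
    b = run_chains(enc, effort, space, traps, ModelVariant(1),
                   short_config(), m_total=20)
    for name in PARAM_NAMES:
        np.testing.assert_array_equal(a.params[name], b.params[name])
    np.testing.assert_array_equal(a.nsuper, b.nsuper)
    np.testing.assert_array_equal(a.traces["s"], b.traces["s"])


def test_chains_explore_independently():
    enc, effort, space, traps = small_survey()
    d = run_chains(enc, effort, space, traps, ModelVariant(1),
                   short_config(), m_total=20)
    assert not np.array_equal(d.params["lam0"][0], d.params["lam0"][1])


def test_draw_shapes_and_detected_pinned():
    enc, effort, space, traps = small_survey()
    cfg = short_config()
    d = run_chains(enc, effort, space, traps, ModelVariant(1), cfg, m_total=20)
    T = cfg.n_retained
    assert d.nsuper.shape == (2, T)
    assert d.density.shape == (2, T)
    assert d.traces["z"].shape == (2, T, 20)
    # detected individuals stay included with their observed sex
    assert np.all(d.traces["z"][:, :, :3] == 1)
    np.testing.assert_array_equal(
        d.traces["sex"][:, :, :3],
        np.broadcast_to([0, 1, 0], (2, T, 3)))
    assert np.all(d.nsuper >= 3)
    np.testing.assert_allclose(d.density, 100.0 * d.nsuper / space.suitable_area)
    assert d.pooled("lam0").shape == (2 * T,)


def test_store_traces_off():
    enc, effort, space, traps = small_survey()
    d = run_chains(enc, effort, space, traps, ModelVariant(1),
                   short_config(store_traces=False), m_total=20)
    assert d.traces is None


def test_acceptance_rates_recorded():
    enc, effort, space, traps = small_survey()
    d = run_chains(enc, effort, space, traps, ModelVariant(1),
                   short_config(), m_total=20)
    for rates in d.acceptance:
        for name in ("lam0", "sigma_f", "sigma_m", "s"):
            assert 0.0 <= rates[name] <= 1.0


def test_variant_constraints_respected_in_draws():
    enc, effort, space, traps = small_survey()
    d = run_chains(enc, effort, space, traps, ModelVariant(3),
                   short_config(), m_total=20)
    assert np.all(d.params["beta_sex"] == 0.0)
    assert np.all(d.params["theta"] == ModelVariant(3).theta_fixed_value)
    d4 = run_chains(enc, effort, space, traps,
                    ModelVariant(4, theta_fixed_value=0.9),
                    short_config(), m_total=20)
    assert np.all(d4.params["theta"] == 0.9)
    assert d4.params["beta_sex"].std() > 0


def test_update_switches_freeze_blocks():
    enc, effort, space, traps = small_survey()
    d = run_chains(enc, effort, space, traps, ModelVariant(1),
                   short_config(update_detection_params=False,
                                update_psi=False),
                   m_total=20)
    for name in ("lam0", "beta_eff", "beta_sex", "sigma_f", "sigma_m",
                 "theta", "psi"):
        assert np.ptp(d.params[name]) == 0.0, name
    # latent state still moves
    assert np.ptp(d.nsuper) > 0


def test_gibbs_update_psi_matches_beta_moments():
    rng = np.random.default_rng(7)
    draws = [gibbs_update_psi(np.ones(30), 100, rng) for _ in range(4000)]
    assert np.mean(draws) == pytest.approx(31 / 102, abs=0.01)


def test_individual_logliks_match_reference_loglik():
    rng = np.random.default_rng(11)
    for _ in range(10):
        params, state, enc, effort, space, traps, dm = random_instance(rng)
        cfg = short_config()
        sampler = SECRSampler(enc, effort, space, traps, ModelVariant(1), cfg,
                              m_total=state.m_total)
        ll, haz = sampler.individual_logliks(params, state.s, state.sex)
        ref = complete_data_loglik(params, state, enc, effort, dm)
        fast = float(ll[state.z == 1].sum())
        assert fast == pytest.approx(ref, abs=1e-9)
        assert np.all(haz >= 0)
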