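"""Probability-model building blocks against hand-computed values."""

import datetime as dt

import numpy as np
import pytest

from searchscr.effort import EffortGrid
from searchscr.encounters import EncounterData
from searchscr.grids import build_trap_grid, distance_matrix
from searchscr.model import (AugmentedState, ModelParams, ModelVariant,
                             complete_data_loglik, density_from_nsuper,
                             detection_kernel, encounter_prob, log_prior,
                             sex_ratio)

from conftest import D0, make_space


def params(**kw):
    base = dict(lam0=0.01, beta_eff=0.0, beta_sex=0.0, sigma_f=1.0,
                sigma_m=2.0, theta=0.75, psi=0.5, psi_sex=0.5)
    base.update(kw)
    return ModelParams(**base)


def test_detection_kernel_hand_values():
    assert detection_kernel(0.0, 2.0, 0.75) == 0.0
    assert detection_kernel(2.0, 2.0, 0.75) == pytest.approx(1.0)
    assert detection_kernel(3.0, 2.0, 1.0) == pytest.approx(2.25)  # (3/2)^2
    assert detection_kernel(3.0, 2.0, 0.5) == pytest.approx(1.5)   # 3/2


def test_detection_kernel_validation():
    with pytest.raises(ValueError):
        detection_kernel(1.0, 0.0, 0.75)
    with pytest.raises(ValueError):
        detection_kernel(1.0, 1.0, 0.4)
    with pytest.raises(ValueError):
        detection_kernel(-1.0, 1.0, 0.75)


def test_encounter_prob_at_distance_zero_unit_effort():
    p = params(lam0=0.004)
    assert encounter_prob(p, 0, 0.0, 1.0) == pytest.approx(1 - np.exp(-0.004))


def test_encounter_prob_zero_effort_is_zero():
    assert encounter_prob(params(), 0, 0.5, 0.0) == 0.0


def test_encounter_prob_effort_covariate():
    p = params(beta_eff=0.5)
    # eta gains 0.5 * ln 4 = ln 2 -> hazard doubles
    pi1 = encounter_prob(p, 0, 0.0, 1.0)
    pi4 = encounter_prob(p, 0, 0.0, 4.0)
    assert -np.log1p(-pi4) == pytest.approx(-2 * np.log1p(-pi1))


def test_encounter_prob_sex_effect_and_sigma():
    p = params(beta_sex=0.3)
    pi_f = encounter_prob(p, 0, 0.0, 1.0)
    pi_m = encounter_prob(p, 1, 0.0, 1.0)
    assert -np.log1p(-pi_m) == pytest.approx(-np.exp(0.3) * np.log1p(-pi_f))
    # at equal distance males use sigma_m = 2 > sigma_f = 1
    assert encounter_prob(p, 1, 1.5, 1.0) > encounter_prob(
        params(beta_sex=0.0), 0, 1.5, 1.0)


def test_encounter_prob_monotone_in_distance():
    d = np.linspace(0, 5, 40)
    pi = encounter_prob(params(), np.zeros_like(d, int), d, np.ones_like(d))
    assert np.all(np.diff(pi) <= 0)


def test_complete_data_loglik_hand_computed():
    # 1 suitable pixel at (0.5, 0.5); 2 traps; 1 occasion; 1 detected animal
    space = make_space(extent=(0, 0, 2, 1), side=1.0,
                       suitable=[True, False])
    traps = build_trap_grid((0, 0, 2, 1), side=1.0)
    dm = distance_matrix(space, traps)  # (1, 2): d = [0, 1]
    effort = EffortGrid(np.array([[2.0], [3.0]]), [D0])
    enc = EncounterData(y=np.array([[[True], [False]]]), sex=[0], ids=["a"])
    p = params(lam0=0.05, beta_eff=0.2, sigma_f=1.0, theta=1.0)
    st = AugmentedState(z=[1], sex=[0], s=[0], n_detected=1)
    ll = complete_data_loglik(p, st, enc, effort, dm)
    mu0 = 0.05 * 2.0 ** 0.2            # detection cell, d=0
    mu1 = 0.05 * 3.0 ** 0.2 * np.exp(-1.0)  # miss cell, d=1
    expect = np.log(1 - np.exp(-mu0)) - mu1
    assert ll == pytest.approx(expect, abs=1e-12)


def test_complete_data_loglik_excluded_individuals_contribute_nothing():
    space = make_space(extent=(0, 0, 2, 1), side=1.0)
    traps = build_trap_grid((0, 0, 2, 1), side=1.0)
    dm = distance_matrix(space, traps)
    effort = EffortGrid(np.ones((2, 1)), [D0])
    enc = EncounterData(y=np.array([[[True], [False]]]), sex=[0], ids=["a"])
    p = params()
    st1 = AugmentedState(z=[1, 0], sex=[0, 1], s=[0, 1], n_detected=1)
    st2 = AugmentedState(z=[1, 0], sex=[0, 0], s=[0, 3], n_detected=1)
    assert complete_data_loglik(p, st1, enc, effort, dm) == pytest.approx(
        complete_data_loglik(p, st2, enc, effort, dm))


def test_complete_data_loglik_detection_in_inactive_cell_rejected():
    space = make_space(extent=(0, 0, 2, 1), side=1.0)
    traps = build_trap_grid((0, 0, 2, 1), side=1.0)
    dm = distance_matrix(space, traps)
    effort = EffortGrid(np.array([[0.0], [1.0]]), [D0])
    enc = EncounterData(y=np.array([[[True], [False]]]), sex=[0], ids=["a"])
    st = AugmentedState(z=[1], sex=[0], s=[0], n_detected=1)
    with pytest.raises(ValueError, match="inactive"):
        complete_data_loglik(params(), st, enc, effort, dm)


def test_model_params_validation():
    with pytest.raises(ValueError):
        params(lam0=0.0).validate()
    with pytest.raises(ValueError):
        params(theta=0.3).validate()
    with pytest.raises(ValueError):
        params(psi=1.0).validate()
    np.testing.assert_allclose(params().sigma_for([0, 1, 0]), [1.0, 2.0, 1.0])


def test_model_variants():
    v1, v2, v3, v4 = (ModelVariant(i) for i in (1, 2, 3, 4))
    assert not v1.fix_beta_sex and not v1.fix_theta
    assert v2.fix_beta_sex and not v2.fix_theta
    assert v3.fix_beta_sex and v3.fix_theta
    assert not v4.fix_beta_sex and v4.fix_theta
    assert "beta_sex" in v1.free_parameters and "theta" in v1.free_parameters
    assert "beta_sex" not in v3.free_parameters
    assert "theta" not in v4.free_parameters
    p = v3.constrain(params(beta_sex=0.4, theta=0.9))
    assert p.beta_sex == 0.0 and p.theta == v3.theta_fixed_value
    with pytest.raises(ValueError):
        ModelVariant(5)


def test_augmented_state_validation():
    with pytest.raises(ValueError, match="z = 1"):
        AugmentedState(z=[0, 1], sex=[0, 0], s=[0, 0], n_detected=1)
    st = AugmentedState(z=[1, 0, 1], sex=[0, 1, 0], s=[0, 1, 2], n_detected=1)
    assert st.m_total == 3 and st.n_super == 2


def test_log_prior_supports():
    v = ModelVariant(1)
    assert log_prior(params(), v) == 0.0
    assert log_prior(params(lam0=-1), v) == -np.inf
    assert log_prior(params(theta=1.2), v) == -np.inf
    assert log_prior(params(theta=1.2), ModelVariant(4)) == 0.0  # theta fixed


def test_sex_ratio_and_density():
    assert sex_ratio(0.25) == pytest.approx(3.0)
    with pytest.raises(ValueError):
        sex_ratio(0.0)
    assert density_from_nsuper(50, 2500.0) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        density_from_nsuper(50, 0.0)
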