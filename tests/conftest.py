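"""Shared fixtures and oracle helpers for the test suite."""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np
import pytest

from searchscr.effort import EffortGrid
from searchscr.encounters import EncounterData
from searchscr.grids import (StateSpace, build_state_space, build_trap_grid,
                             distance_matrix)
from searchscr.model import AugmentedState, ModelParams, encounter_prob

D0 = dt.date(2014, 8, 1)


def make_space(extent=(0.0, 0.0, 3.0, 3.0), side=0.5, suitable=None) -> StateSpace:
    """All-suitable (or custom-masked) state space for small tests."""
    space = build_state_space(extent, side)
    if suitable is not None:
        space = dataclasses.replace(space, suitable=np.asarray(suitable, bool))
    return space


def naive_loglik(params: ModelParams, state: AugmentedState, enc, effort,
                 distmat) -> float:
    """Triple-loop Bernoulli log-likelihood, the slow reference oracle."""
    total = 0.0
    n = enc.n_individuals
    for i in range(state.m_total):
        if state.z[i] != 1:
            continue
        for j in range(effort.n_traps):
            for k in range(effort.n_occasions):
                e = effort.effort[j, k]
                if e <= 0:
                    continue
                pi = encounter_prob(params, int(state.sex[i]),
                                    distmat[state.s[i], j], e)
                y = bool(enc.y[i, j, k]) if i < n else False
                total += np.log(pi) if y else np.log1p(-pi)
    return float(total)


def random_instance(rng: np.random.Generator):
    """One random small survey instance for likelihood-oracle checks."""
    nx = ny = int(rng.integers(3, 6))
    side = 0.5
    space = build_state_space((0.0, 0.0, nx * side, ny * side), side)
    # random habitat mask keeping at least two suitable pixels
    suit = rng.random(space.n_pixels) > 0.2
    if suit.sum() < 2:
        suit[:2] = True
    space = dataclasses.replace(space, suitable=suit)
    traps = build_trap_grid((0.0, 0.0, nx * side, ny * side), side=1.0)
    J = traps.n_traps
    K = int(rng.integers(1, 4))
    effort = rng.uniform(0.0, 5.0, size=(J, K))
    effort[rng.random((J, K)) < 0.3] = 0.0  # inactive cells
    n = int(rng.integers(1, 4))
    M = n + int(rng.integers(1, 4))
    y = np.zeros((n, J, K), dtype=bool)
    act_j, act_k = np.nonzero(effort > 0)
    if act_j.size == 0:  # guarantee at least one active cell
        effort[0, 0] = 1.0
        act_j, act_k = np.array([0]), np.array([0])
    for i in range(n):
        hits = rng.integers(1, 4)
        pick = rng.integers(0, act_j.size, size=hits)
        y[i, act_j[pick], act_k[pick]] = True
    occasions = [D0 + dt.timedelta(days=int(k)) for k in range(K)]
    eff = EffortGrid(effort, occasions)
    enc = EncounterData(y=y, sex=rng.integers(0, 2, size=n),
                        ids=[f"id{i}" for i in range(n)])
    G = int(space.n_suitable)
    state = AugmentedState(
        z=np.concatenate([np.ones(n, int), rng.integers(0, 2, size=M - n)]),
        sex=rng.integers(0, 2, size=M),
        s=rng.integers(0, G, size=M),
        n_detected=n,
    )
    params = ModelParams(
        lam0=float(rng.uniform(0.001, 0.05)),
        beta_eff=float(rng.uniform(-0.3, 0.3)),
        beta_sex=float(rng.uniform(-0.5, 0.5)),
        sigma_f=float(rng.uniform(0.5, 3.0)),
        sigma_m=float(rng.uniform(0.5, 3.0)),
        theta=float(rng.uniform(0.5, 1.0)),
        psi=float(rng.uniform(0.1, 0.9)),
        psi_sex=float(rng.uniform(0.1, 0.9)),
    )
    distmat = distance_matrix(space, traps)
    return params, state, enc, eff, space, traps, distmat


@pytest.fixture
def flat_space():
    return make_space()


@pytest.fixture
def traps33():
    return build_trap_grid((0.0, 0.0, 3.0, 3.0), side=1.0)
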