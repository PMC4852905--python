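"""Convergence and adequacy diagnostics."""

import json

import numpy as np
import pytest

from searchscr.diagnostics import (DiagnosticsReport, bayesian_pvalue,
                                   density_surface, diagnose, gelman_rubin,
                                   max_psrf, summarize_posterior)
from searchscr.model import ModelVariant
from searchscr.sampler import run_chains

from test_sampler import short_config, small_survey


@pytest.fixture(scope="module")
def fitted():
    enc, effort, space, traps = small_survey()
    draws = run_chains(enc, effort, space, traps, ModelVariant(1),
                       short_config(chains=3), m_total=20)
    return draws, enc, effort, space, traps


def test_gelman_rubin_hand_value():
    # W = 1, B = 3 * var({2, 3}) = 1.5, varhat = (2/3)*1 + 0.5 = 7/6
    chains = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0]])
    assert gelman_rubin(chains) == pytest.approx(np.sqrt(7.0 / 6.0))


def test_gelman_rubin_floor_and_degenerate_cases():
    assert gelman_rubin([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]) == 1.0  # floored
    assert gelman_rubin([[5.0, 5.0], [5.0, 5.0]]) == 1.0  # zero variance
    # permutation of the chain axis changes nothing
    c = np.random.default_rng(0).normal(size=(4, 50))
    assert gelman_rubin(c) == pytest.approx(gelman_rubin(c[::-1]))


def test_gelman_rubin_detects_divergent_chains():
    rng = np.random.default_rng(1)
    chains = rng.normal(size=(4, 500)) + np.array([[0.0], [0.0], [5.0], [5.0]])
    assert gelman_rubin(chains) > 1.2


def test_gelman_rubin_validation():
    with pytest.raises(ValueError):
        gelman_rubin(np.ones((1, 10)))
    with pytest.raises(ValueError):
        gelman_rubin(np.ones((2, 1)))


def test_max_psrf_covers_free_params_and_nsuper(fitted):
    draws = fitted[0]
    mx, per = max_psrf(draws)
    expect = set(ModelVariant(1).free_parameters) | {"nsuper"}
    assert set(per) == expect
    assert mx == max(per.values())


def test_summarize_posterior_matches_pooled_moments(fitted):
    draws = fitted[0]
    s = summarize_posterior(draws)
    x = draws.pooled("sigma_f")
    assert s.loc["sigma_f", "mean"] == pytest.approx(x.mean())
    assert s.loc["sigma_f", "sd"] == pytest.approx(x.std(ddof=1))
    psx = draws.pooled("psi_sex")
    assert s.loc["sex_ratio", "mean"] == pytest.approx(((1 - psx) / psx).mean())
    assert {"nsuper", "density"} <= set(s.index)


def test_density_surface_conserves_abundance(fitted):
    draws, _, _, space, _ = fitted
    surface = density_surface(draws, space)
    assert surface.shape == (space.n_pixels,)
    assert np.all(surface >= 0)
    total = surface.sum() * space.pixel_area
    assert total == pytest.approx(draws.pooled("nsuper").mean())


def test_density_surface_requires_traces(fitted):
    import dataclasses
    draws, _, _, space, _ = fitted
    bare = dataclasses.replace(draws, traces=None)
    with pytest.raises(ValueError, match="traces"):
        density_surface(bare, space)
    with pytest.raises(ValueError, match="traces"):
        bayesian_pvalue(bare, *fitted[1:], rng=np.random.default_rng(0))


def test_bayesian_pvalue_range_and_determinism(fitted):
    draws, enc, effort, space, traps = fitted
    p1 = bayesian_pvalue(draws, enc, effort, space, traps,
                         np.random.default_rng(5), max_draws=100)
    p2 = bayesian_pvalue(draws, enc, effort, space, traps,
                         np.random.default_rng(5), max_draws=100)
    assert 0.0 <= p1 <= 1.0
    assert p1 == p2


def test_diagnose_report_and_json(fitted, tmp_path):
    draws, enc, effort, space, traps = fitted
    rep = diagnose(draws, enc, effort, space, traps,
                   rng=np.random.default_rng(3))
    assert isinstance(rep, DiagnosticsReport)
    assert rep.bayes_pvalue is not None
    assert rep.converged == (rep.max_psrf < 1.2)
    assert rep.adequate == (0.15 < rep.bayes_pvalue < 0.85)
    rep.to_json(tmp_path / "diag.json")
    d = json.loads((tmp_path / "diag.json").read_text())
    assert d["max_psrf"] == pytest.approx(rep.max_psrf)
    assert "density" in d["posterior"]
    # without survey data the predictive check is skipped, not failed
    rep2 = diagnose(draws)
    assert rep2.bayes_pvalue is None and rep2.adequate is None
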