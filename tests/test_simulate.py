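"""The synthetic-survey generator."""

import dataclasses

import numpy as np
import pytest

from searchscr.simulate import (ScenarioConfig, load_bundled_scenario,
                                make_state_space, simulate_population,
                                simulate_survey, simulate_tracks)

SMALL = ScenarioConfig(search_extent=(0, 0, 8, 8), buffer_km=3,
                       state_pixel_km=0.65, n_true=12, k_occasions=5,
                       n_searcher_days=10, daily_km=20, fix_spacing_km=0.2)


def test_scenario_geometry_properties():
    sc = ScenarioConfig(search_extent=(0, 0, 10, 10), buffer_km=4)
    assert sc.state_extent == pytest.approx((-4, -4, 14, 14))
    assert len(sc.occasions) == sc.k_occasions
    assert (sc.occasions[1] - sc.occasions[0]).days == 1
    p = sc.true_params
    assert p.sigma_m == sc.sigma_m and p.lam0 == sc.lam0


def test_scenario_yaml_round_trip(tmp_path):
    path = tmp_path / "sc.yaml"
    SMALL.to_yaml(path)
    back = ScenarioConfig.from_yaml(path)
    assert back == SMALL
    path.write_text(path.read_text() + "bogus_key: 1\n")
    with pytest.raises(ValueError, match="bogus_key"):
        ScenarioConfig.from_yaml(path)


def test_mask_fraction_exact():
    rng = np.random.default_rng(0)
    sc = dataclasses.replace(SMALL, frac_unsuitable=0.3)
    space = make_state_space(sc, rng)
    n_bad = int(round(0.3 * space.n_pixels))
    assert (~space.suitable).sum() == n_bad
    # zero fraction -> everything suitable
    space2 = make_state_space(dataclasses.replace(SMALL, frac_unsuitable=0.0),
                              np.random.default_rng(0))
    assert space2.suitable.all()


def test_mask_is_spatially_clustered():
    rng = np.random.default_rng(3)
    sc = dataclasses.replace(SMALL, frac_unsuitable=0.4)
    space = make_state_space(sc, rng)
    # neighbouring pixels agree far more often than the ~52% expected if the
    # mask were i.i.d. with p = 0.4
    suit2d = space.suitable.reshape(space.ny, space.nx)
    agree = (suit2d[:, 1:] == suit2d[:, :-1]).mean()
    assert agree > 0.8


def test_population_uniform_over_suitable_pixels():
    rng = np.random.default_rng(1)
    sc = dataclasses.replace(SMALL, frac_unsuitable=0.4, n_true=200)
    space = make_state_space(sc, rng)
    pop = simulate_population(space, sc, rng)
    assert len(pop) == 200
    assert pop["pixel"].max() < space.n_suitable
    # centres sit on suitable-pixel centroids
    np.testing.assert_allclose(pop["x"], space.suitable_xy[pop["pixel"], 0])
    assert set(pop["sex"]) <= {0, 1}


def test_tracks_respect_extent_and_budget():
    rng = np.random.default_rng(2)
    tracks = simulate_tracks(SMALL, rng)
    assert len(tracks) == SMALL.n_searcher_days
    for tr in tracks:
        assert tr.x.min() >= 0 and tr.x.max() <= 8
        assert tr.y.min() >= 0 and tr.y.max() <= 8
        assert tr.length_km <= SMALL.daily_km + 1e-6
        # reflection keeps every step at the fix spacing, so the day's
        # driven distance stays close to the budget
        assert tr.length_km == pytest.approx(SMALL.daily_km, rel=0.05)


def test_hotspot_bias_concentrates_effort():
    base = dataclasses.replace(SMALL, n_searcher_days=20)
    rng = np.random.default_rng(4)
    uniform = simulate_tracks(dataclasses.replace(base, hotspot_bias=0.0), rng)
    rng = np.random.default_rng(4)
    pulled = simulate_tracks(dataclasses.replace(base, hotspot_bias=0.2), rng)

    def mean_dist_to_centre(tracks):
        xs = np.concatenate([t.x for t in tracks])
        ys = np.concatenate([t.y for t in tracks])
        return np.hypot(xs - 4.0, ys - 4.0).mean()

    assert mean_dist_to_centre(pulled) < mean_dist_to_centre(uniform)


def test_simulate_survey_deterministic_and_consistent():
    a = simulate_survey(SMALL, seed=9)
    b = simulate_survey(SMALL, seed=9)
    assert a.truth.equals(b.truth)
    np.testing.assert_array_equal(a.effort.effort, b.effort.effort)
    assert len(a.sightings) == len(b.sightings)
    c = simulate_survey(SMALL, seed=10)
    assert not a.truth.equals(c.truth)

    # internal consistency of one survey
    assert a.effort.total_km == pytest.approx(
        sum(t.length_km for t in a.tracks), rel=0.02)
    n_det = int(a.truth["detected"].sum())
    if a.enc is not None:
        assert a.enc.n_individuals == n_det
        assert sorted(a.enc.ids) == sorted(
            a.truth.loc[a.truth["detected"], "individual_id"])
        # every sighting is consistent with the encounter array support
        assert len(a.sightings) >= a.enc.n_individuals
        assert not np.any(a.enc.y & ~a.effort.active[None, :, :])
    assert a.true_density == pytest.approx(
        100.0 * SMALL.n_true / a.space.suitable_area)


def test_default_scenario_detects_a_usable_sample():
    sv = simulate_survey(ScenarioConfig(), seed=0)
    n_det = int(sv.truth["detected"].sum())
    assert sv.enc is not None
    assert 5 <= n_det <= ScenarioConfig().n_true


def test_bundled_scenario_loads():
    sc = load_bundled_scenario("mara_like")
    assert sc.k_occasions == 92
    assert sc.frac_unsuitable == pytest.approx(0.4258)
    assert sc.buffer_km == pytest.approx(40.0)
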