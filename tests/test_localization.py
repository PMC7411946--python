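"""Error surfaces, emission probabilities, Viterbi decoding, full pipeline."""

import itertools

import numpy as np
import pytest

from barntrack import (
    DEFAULT_MODEL,
    ErrorSurface,
    GridLocalizer,
    ObservationWindow,
    best_point,
    emission_probabilities,
    error_surface,
    localize,
    viterbi_decode,
)
from barntrack.simulate import (
    MotionSpec,
    NoiseSpec,
    simulate_rss,
    simulate_trajectory,
)


def window(rss_by_station, t0=0.0, tag="t0"):
    return ObservationWindow(
        t_start=t0, t_end=t0 + 5.0, tag_id=tag, rss_by_station=rss_by_station
    )


class TestErrorSurface:
    def test_exact_match_gives_zero_error(self, mini_map):
        k = 7
        obs = window(dict(zip(mini_map.station_ids, mini_map.rss_map_[k])))
        for shifted in (True, False):
            surf = error_surface(obs, mini_map, shifted=shifted)
            assert surf.errs[k] == pytest.approx(0.0, abs=1e-18)
            assert best_point(surf) == k

    def test_constant_offset_cancelled_only_by_shifting(self, mini_map):
        k, c = 7, 6.5
        obs = window(
            {s: v + c for s, v in zip(mini_map.station_ids, mini_map.rss_map_[k])}
        )
        shifted = error_surface(obs, mini_map, shifted=True)
        unshifted = error_surface(obs, mini_map, shifted=False)
        assert shifted.errs[k] == pytest.approx(0.0, abs=1e-18)
        assert unshifted.errs[k] == pytest.approx(len(obs.heard) * c**2)

    def test_hand_computed_two_station_surfaces(self, mini_map):
        """Pencil-and-paper oracle on a 2-station subset."""
        obs = window({"a": -50.0, "b": -58.0})
        surf_u = error_surface(obs, mini_map, shifted=False, min_stations=2)
        surf_s = error_surface(obs, mini_map, shifted=True, min_stations=2)
        ids = mini_map.station_ids
        ia, ib = ids.index("a"), ids.index("b")
        for k in (0, 5):
            ra, rb = mini_map.rss_map_[k, ia], mini_map.rss_map_[k, ib]
            exp_u = (-50.0 - ra) ** 2 + (-58.0 - rb) ** 2
            mes_c = np.array([-50.0, -58.0]) - (-54.0)
            row_c = np.array([ra, rb]) - (ra + rb) / 2
            exp_s = ((mes_c - row_c) ** 2).sum()
            assert surf_u.errs[k] == pytest.approx(exp_u)
            assert surf_s.errs[k] == pytest.approx(exp_s)

    def test_too_few_stations_is_unlocatable(self, mini_map):
        with pytest.raises(ValueError, match="unlocatable"):
            error_surface(window({"a": -50.0, "b": -52.0}), mini_map)


class TestBestPointAndEmissions:
    def test_argmin_with_tie_to_lowest_index(self):
        assert best_point(ErrorSurface(np.array([3.0, 1.0, 2.0]), 3)) == 1
        assert best_point(ErrorSurface(np.array([2.0, 2.0, 2.0]), 3)) == 0

    def test_reciprocal_error_probabilities(self):
        p = emission_probabilities(ErrorSurface(np.array([1.0, 2.0, 4.0]), 3))
        np.testing.assert_allclose(p, [4 / 7, 2 / 7, 1 / 7])

    def test_zero_error_attracts_all_mass(self):
        p = emission_probabilities(ErrorSurface(np.array([0.0, 1.0, 1.0]), 3))
        assert p[0] > 0.9999
        assert p.sum() == pytest.approx(1.0)

    def test_flat_surface_is_uniform(self):
        p = emission_probabilities(ErrorSurface(np.full(5, 3.0), 3))
        np.testing.assert_allclose(p, 0.2)


def brute_force_path(emissions, tm, prior):
    """Exhaustive MAP path enumeration (the independent oracle)."""
    t, k = emissions.shape
    best, best_p = None, -1.0
    for path in itertools.product(range(k), repeat=t):
        p = prior[path[0]] * emissions[0, path[0]]
        for a, b, e in zip(path, path[1:], emissions[1:]):
            p *= tm[a, b] * e[b]
        if p > best_p:
            best, best_p = path, p
    return np.array(best)


class TestViterbi:
    def test_single_window_is_posterior_argmax(self):
        em = np.array([[0.1, 0.7, 0.2]])
        tm = np.eye(3)
        assert viterbi_decode(em, tm)[0] == 1

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(30):
            k = int(rng.integers(2, 6))
            t = int(rng.integers(2, 6))
            em = rng.random((t, k)) + 1e-3
            em /= em.sum(axis=1, keepdims=True)
            tm = rng.random((k, k)) + 1e-3
            # sprinkle structural zeros while keeping the diagonal alive
            tm[rng.random((k, k)) < 0.3] = 0.0
            np.fill_diagonal(tm, np.maximum(np.diag(tm), 0.2))
            tm /= tm.sum(axis=1, keepdims=True)
            prior = np.full(k, 1.0 / k)
            got = viterbi_decode(em, tm, prior)
            np.testing.assert_array_equal(got, brute_force_path(em, tm, prior))

    def test_all_zero_emission_window_treated_uniform(self):
        em = np.array([[0.0, 1.0], [0.0, 0.0], [0.0, 1.0]])
        tm = np.array([[0.9, 0.1], [0.1, 0.9]])
        path = viterbi_decode(em, tm)
        assert path.tolist() == [1, 1, 1]

    def test_forbidden_transitions_never_used(self, rng):
        k = 5
        tm = np.eye(k) * 0.5
        for i in range(k - 1):  # chain topology: only i <-> i+1
            tm[i, i + 1] = tm[i + 1, i] = 0.25
        tm /= tm.sum(axis=1, keepdims=True)
        em = rng.random((40, k))
        em /= em.sum(axis=1, keepdims=True)
        path = viterbi_decode(em, tm)
        assert np.all(np.abs(np.diff(path)) <= 1)


class TestPipeline:
    def test_stationary_tag_low_noise_decodes_nearby(self, mini_map):
        track = simulate_trajectory(
            mini_map,
            motion=MotionSpec(dwell_fraction=1.0),
            duration_s=300,
            seed=3,
            start=8,
        )
        noise = NoiseSpec(1.0, 0.0, 0.0, 0.0)
        rss = simulate_rss(track, mini_map, noise=noise, seed=4)
        out = localize(rss, mini_map, filter_method=None)["tag00"]
        d = np.linalg.norm(
            mini_map.coords[out.points] - mini_map.coords[8], axis=1
        )
        assert d.max() <= 1.5  # the true point or a grid neighbour

    def test_deterministic_for_identical_input(self, mini_map):
        track = simulate_trajectory(mini_map, duration_s=120, seed=5)
        rss = simulate_rss(track, mini_map, seed=6)
        a = localize(rss, mini_map)["tag00"]
        b = localize(rss.copy(), mini_map)["tag00"]
        np.testing.assert_array_equal(a.points, b.points)

    def test_interleaved_tags_decode_independently(self, mini_map):
        t1 = simulate_trajectory(mini_map, duration_s=120, seed=7, tag_id="cowA")
        t2 = simulate_trajectory(mini_map, duration_s=120, seed=8, tag_id="cowB")
        import pandas as pd

        both = pd.concat(
            [
                simulate_rss(t1, mini_map, seed=9),
                simulate_rss(t2, mini_map, seed=10),
            ]
        ).sort_values("timestamp", ignore_index=True)
        merged = localize(both, mini_map)
        assert set(merged) == {"cowA", "cowB"}
        solo = localize(simulate_rss(t1, mini_map, seed=9), mini_map)["cowA"]
        np.testing.assert_array_equal(merged["cowA"].points, solo.points)

    def test_estimator_interface_round_trip(self, mini_map):
        loc = GridLocalizer(barn_map=mini_map).fit()
        assert loc.rss_map_.shape == (len(mini_map.points), 4)
        params = loc.get_params()
        assert params["shifted"] is True
        loc.set_params(shifted=False)
        assert loc.shifted is False
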