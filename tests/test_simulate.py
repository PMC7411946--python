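"""Synthetic telemetry: range experiments, trajectories, noisy RSS streams."""

import numpy as np
import pytest

from barntrack import (
    DEFAULT_MODEL,
    MotionSpec,
    NoiseSpec,
    Track,
    localize,
    make_reference,
    motion_chain,
    simulate_open_space,
    simulate_rss,
    simulate_trajectory,
)
from barntrack.simulate import simulate_barn


class TestOpenSpace:
    def test_sample_count_matches_recording_protocol(self):
        df = simulate_open_space(distances=[1, 5, 10], seed=0)
        counts = df.groupby("distance_m").size()
        assert (counts == 600).all()  # 120 s at 5 Hz

    def test_zero_noise_reproduces_model_exactly(self):
        df = simulate_open_space(
            distances=[2.0], noise=NoiseSpec.noiseless(), seed=0
        )
        np.testing.assert_allclose(df["rss_db"], DEFAULT_MODEL.predict(2.0))

    def test_seeded_reruns_bit_identical(self):
        a = simulate_open_space(distances=[1, 2], seed=11)
        b = simulate_open_space(distances=[1, 2], seed=11)
        assert a.equals(b)


class TestTrajectory:
    def test_full_dwell_is_stationary(self, mini_map):
        tr = simulate_trajectory(
            mini_map, MotionSpec(dwell_fraction=1.0), duration_s=200, seed=1
        )
        assert np.unique(tr.points).size == 1

    def test_steps_respect_limit_and_obstacles(self, barn):
        tr = simulate_trajectory(barn, duration_s=4000, seed=2)
        coords = barn.coords
        steps = np.linalg.norm(np.diff(coords[tr.points], axis=0), axis=1)
        assert steps.max() <= barn.transition.max_step + 1e-9
        moved = tr.points[1:] != tr.points[:-1]
        for a, b in zip(tr.points[:-1][moved], tr.points[1:][moved]):
            assert barn.tm_[a, b] > 0  # passage exists in the barn structure

    def test_occupancy_converges_to_stationary_distribution(self, mini_map):
        """Long-run occupancy approaches the chain's leading eigenvector."""
        chain = motion_chain(mini_map, dwell_fraction=0.5)
        w, v = np.linalg.eig(chain.T)
        pi = np.real(v[:, np.argmax(np.real(w))])
        pi /= pi.sum()
        tr = simulate_trajectory(
            mini_map, MotionSpec(dwell_fraction=0.5), duration_s=150000, seed=3
        )
        occ = np.bincount(tr.points, minlength=len(mini_map.points)) / len(tr)
        assert np.abs(occ - pi).max() < 1e-2

    def test_dwell_fraction_validated(self):
        with pytest.raises(ValueError):
            MotionSpec(dwell_fraction=1.4)


class TestRssStream:
    def test_noiseless_static_tag_equals_lookup_row(self, mini_map):
        tr = simulate_trajectory(
            mini_map, MotionSpec(dwell_fraction=1.0), duration_s=20, seed=4, start=5
        )
        df = simulate_rss(tr, mini_map, noise=NoiseSpec.noiseless(), seed=5)
        for si, sid in enumerate(mini_map.station_ids):
            vals = df.loc[df["station_id"] == sid, "rss_db"]
            np.testing.assert_allclose(vals, mini_map.rss_map_[5, si], atol=1e-9)

    def test_advertisement_rate(self, mini_map):
        tr = simulate_trajectory(mini_map, duration_s=60, seed=6)
        df = simulate_rss(tr, mini_map, noise=NoiseSpec.noiseless(), seed=7)
        per_station = df.groupby("station_id").size()
        assert (per_station == 60 * 5).all()

    def test_orientation_term_spans_its_amplitude(self, mini_map):
        """Across dwells, per-station RSS varies within the configured
        peak-to-peak orientation amplitude."""
        # short dwells separated by moves: every dwell redraws the heading
        pts = np.tile(np.repeat(np.array([0, 5], dtype=np.intp), 2), 30)
        tr = Track(
            tag_id="t0",
            t_starts=np.arange(pts.size) * 5.0,
            points=pts,
        )
        amp = 6.0
        df = simulate_rss(
            tr,
            mini_map,
            noise=NoiseSpec(0.0, 0.0, 0.0, orientation_amp=amp),
            seed=8,
        )
        sid = mini_map.station_ids[0]
        dev = df[df["station_id"] == sid]["rss_db"].to_numpy() - np.where(
            np.repeat(pts, 25) == 0,
            mini_map.rss_map_[0, 0],
            mini_map.rss_map_[5, 0],
        )
        assert np.abs(dev).max() <= amp / 2 + 1e-9
        assert dev.max() - dev.min() > amp / 2  # headings explore the pattern

    def test_packet_loss_thins_the_stream(self, mini_map):
        tr = simulate_trajectory(mini_map, duration_s=100, seed=9)
        full = simulate_rss(tr, mini_map, seed=10)
        lossy = simulate_rss(
            tr, mini_map, noise=NoiseSpec(drop_prob=0.5), seed=10
        )
        assert 0.4 < len(lossy) / len(full) < 0.6

    def test_seeded_determinism(self, mini_map):
        tr = simulate_trajectory(mini_map, duration_s=50, seed=11)
        a = simulate_rss(tr, mini_map, seed=12)
        b = simulate_rss(tr, mini_map, seed=12)
        assert a.equals(b)


class TestReferenceEvents:
    def test_stationary_track_single_event(self, mini_map):
        tr = Track("t0", np.arange(10) * 5.0, np.full(10, 3, dtype=np.intp))
        ev = make_reference(tr, mini_map)
        assert len(ev) == 1
        assert ev.loc[0, "t_start"] == 0.0 and ev.loc[0, "t_end"] == 50.0

    def test_short_visit_not_registered(self, mini_map):
        tr = Track(
            "t0", np.arange(5) * 1.0, np.array([3, 3, 4, 3, 3]), fold=1.0
        )
        ev = make_reference(tr, mini_map, min_dwell_s=5.0)
        assert (ev["point_index"] != 4).all()

    def test_alternating_dwells_one_event_each(self, mini_map):
        pts = np.repeat([2, 9, 2, 9], 2)  # 10 s dwells at 5 s folds
        tr = Track("t0", np.arange(pts.size) * 5.0, pts)
        ev = make_reference(tr, mini_map, min_dwell_s=5.0)
        assert len(ev) == 4
        assert ev["point_index"].tolist() == [2, 9, 2, 9]


class TestExactModelConsistency:
    def test_noise_free_simulation_decodes_to_truth(self, mini_map):
        tr = simulate_trajectory(mini_map, duration_s=300, seed=13)
        rss = simulate_rss(tr, mini_map, noise=NoiseSpec.noiseless(), seed=14)
        out = localize(rss, mini_map, filter_method=None)["tag00"]
        np.testing.assert_array_equal(out.points, tr.points[: len(out)])


class TestHerd:
    def test_station_offsets_shared_across_tags(self, mini_map):
        rss, tracks, refs = simulate_barn(
            mini_map,
            n_tags=2,
            duration_s=60,
            noise=NoiseSpec(0.0, 0.0, 4.14, 0.0),
            seed=15,
        )
        # with only station offsets active, both tags see the same per-station
        # bias: difference of (observed - lookup) between tags is zero
        biases = {}
        for tag, tr in tracks.items():
            sub = rss[rss["tag_id"] == tag]
            per_sta = {}
            for si, sid in enumerate(mini_map.station_ids):
                vals = sub[sub["station_id"] == sid]["rss_db"].to_numpy()
                truth = mini_map.rss_map_[tr.points[0], si]
                per_sta[sid] = np.mean(vals[:25]) - truth
            biases[tag] = per_sta
        for sid in mini_map.station_ids:
            assert biases["tag00"][sid] == pytest.approx(
                biases["tag01"][sid], abs=1e-9
            )
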