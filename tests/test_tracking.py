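"""Spot linking, instantaneous speeds and interaction-event detection."""

import numpy as np
import pytest

import punctakit as pk

from conftest import (brute_force_events, events_as_tuples, random_tracks,
                      tracks_from_truth)


def spot(x, y, frame, channel=""):
    return pk.Spot(x=float(x), y=float(y), frame=frame, channel=channel)


class TestLinkSpots:
    def test_static_spot_links_into_one_track(self):
        spots = [spot(20, 20, f) for f in range(10)]
        tracks = pk.link_spots(spots, pk.LinkParams(max_displacement=2.0))
        assert len(tracks) == 1
        assert tracks[0].frames == list(range(10))

    def test_displacement_gate_splits_fast_movement(self):
        spots = [spot(10 + f, 10, f) for f in range(10)]  # 1 px/frame
        tracks = pk.link_spots(spots, pk.LinkParams(max_displacement=0.5))
        assert len(tracks) == 10
        assert all(len(t) == 1 for t in tracks)

    def test_parallel_tracks_recovered_exactly(self):
        a = [spot(10 + 0.4 * f, 10, f) for f in range(15)]
        b = [spot(10 + 0.4 * f, 40, f) for f in range(15)]
        tracks = pk.link_spots(a + b, pk.LinkParams(max_displacement=1.0))
        assert len(tracks) == 2
        ys = sorted(t.ys[0] for t in tracks)
        assert ys == [10, 40]
        for t in tracks:
            assert len(t) == 15 and len(set(t.ys)) == 1

    def test_every_spot_in_exactly_one_track(self, rng):
        spots = [spot(*rng.uniform(0, 80, 2), frame=f)
                 for f in range(12) for _ in range(rng.integers(0, 8))]
        tracks = pk.link_spots(spots, pk.LinkParams(max_displacement=4.0))
        linked = sum(len(t) for t in tracks)
        assert linked == len(spots)

    def test_empty_input(self):
        assert pk.link_spots([], pk.LinkParams()) == []


class TestInstantaneousSpeed:
    def test_static_track_speed_zero(self):
        t = pk.Track(0, frames=[0, 1, 2], xs=[5, 5, 5], ys=[5, 5, 5],
                     intensities=[1, 1, 1])
        assert np.allclose(pk.instantaneous_speed(t, 0.1, 10.0), 0.0)

    def test_unit_step_conversion_to_um_per_min(self):
        # 1 px/frame at 0.1 um/px and 10 s/frame = 0.6 um/min
        t = pk.Track(0, frames=[0, 1, 2], xs=[0, 1, 2], ys=[0, 0, 0],
                     intensities=[1, 1, 1])
        assert np.allclose(pk.instantaneous_speed(t, 0.1, 10.0), 0.6)

    def test_short_track_rejected(self):
        t = pk.Track(0, frames=[0], xs=[1], ys=[1], intensities=[1])
        with pytest.raises(ValueError):
            pk.instantaneous_speed(t, 0.1, 10.0)


class TestDetectInteractions:
    IC = pk.InteractionConfig(vicinity=3.0, min_frames=3, frame_interval=10.0)

    @staticmethod
    def pair_tracks(near_frames, n_frames=10, sep_near=1.0, sep_far=10.0):
        red = pk.Track(0, channel="red")
        green = pk.Track(1, channel="green")
        for f in range(n_frames):
            sep = sep_near if f in near_frames else sep_far
            red.frames.append(f); red.xs.append(20.0); red.ys.append(20.0)
            green.frames.append(f); green.xs.append(20.0 + sep)
            green.ys.append(20.0)
            red.intensities.append(1.0); green.intensities.append(1.0)
        return [red], [green]

    def test_two_frame_vicinity_is_no_event(self):
        red, green = self.pair_tracks({4, 5})
        assert pk.detect_interactions(red, green, self.IC) == []

    def test_five_frame_vicinity_is_one_event(self):
        red, green = self.pair_tracks({3, 4, 5, 6, 7})
        events = pk.detect_interactions(red, green, self.IC)
        assert len(events) == 1
        assert (events[0].start_frame, events[0].n_frames) == (3, 5)

    def test_broken_run_is_not_bridged(self):
        # 2 near + 1 far + 2 near: neither run reaches min_frames
        red, green = self.pair_tracks({2, 3, 5, 6})
        assert pk.detect_interactions(red, green, self.IC) == []

    def test_events_are_maximal(self):
        red, green = self.pair_tracks(set(range(1, 9)))
        events = pk.detect_interactions(red, green, self.IC)
        assert len(events) == 1
        assert (events[0].start_frame, events[0].n_frames) == (1, 8)

    def test_matches_brute_force_on_random_track_sets(self, rng):
        for _ in range(40):
            red = random_tracks(rng, int(rng.integers(1, 12)), 30,
                                channel="red")
            green = random_tracks(rng, int(rng.integers(1, 12)), 30,
                                  channel="green")
            got = events_as_tuples(
                pk.detect_interactions(red, green, self.IC, pixel_size=0.1))
            want = brute_force_events(red, green, self.IC, 0.1)
            assert [g[:4] for g in got] == [w[:4] for w in want]
            assert np.allclose([g[4] for g in got], [w[4] for w in want],
                               equal_nan=True)

    def test_monotone_in_vicinity_and_min_frames(self, rng):
        red = random_tracks(rng, 8, 25, channel="red")
        green = random_tracks(rng, 8, 25, channel="green")

        def count(vic, mf):
            ic = pk.InteractionConfig(vicinity=vic, min_frames=mf)
            return len(pk.detect_interactions(red, green, ic))

        for mf in (1, 2, 3, 5):
            counts = [count(v, mf) for v in (1.0, 2.0, 4.0, 8.0)]
            assert counts == sorted(counts)
        for v in (2.0, 4.0):
            counts = [count(v, mf) for mf in (6, 4, 3, 2, 1)]
            assert counts == sorted(counts)

    def test_constructed_scene_yields_exactly_k_events(self):
        for k in (0, 1, 5):
            p = pk.SceneParams(n_frames=20, rng_seed=40 + k)
            inters = [pk.InteractionTruth(start_frame=2 + 3 * i, duration=4)
                      for i in range(k)]
            pops = ([] if k else [pk.PunctaPopulation(
                n_spots=4, channel_profile="red_only")])
            scene = pk.make_scene(p, pops, inters,
                                  no_chance_proximity=True)
            tracks = tracks_from_truth(scene)
            events = pk.detect_interactions(tracks["red"], tracks["green"],
                                            self.IC, pixel_size=p.pixel_size)
            assert len(events) == k

    def test_joint_speed_recovers_drift(self):
        # 0.05 um/s shared drift at 10 s/frame = 3.0 um/min
        p = pk.SceneParams(n_frames=12, rng_seed=50)
        scene = pk.make_scene(
            p, [], [pk.InteractionTruth(start_frame=2, duration=8,
                                        drift_velocity=0.05)],
            interaction_diffusion_coeff=0.0)
        tracks = tracks_from_truth(scene, noise_px=0.3)
        events = pk.detect_interactions(tracks["red"], tracks["green"],
                                        self.IC, pixel_size=p.pixel_size)
        assert len(events) == 1
        assert events[0].mean_joint_speed == pytest.approx(3.0, rel=0.10)


class TestInteractionSummary:
    def test_empty_events_flagged(self):
        out = pk.interaction_summary([], n_red_tracks=5)
        assert out["n_events"] == 0 and not out["speed_defined"]
        assert np.isnan(out["mean_joint_speed"])

    def test_mean_of_two_events(self):
        evs = [pk.InteractionEvent(0, 1, 0, 3, 1.0),
               pk.InteractionEvent(0, 2, 5, 3, 3.0)]
        out = pk.interaction_summary(evs)
        assert out["mean_joint_speed"] == 2.0
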