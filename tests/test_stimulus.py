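"""Synthetic event-camera generation, event I/O, spike binning."""

import numpy as np
import pytest

from plasticnet.network import ConfigurationError
from plasticnet.stimulus import (DEAD_TIME_US, EventStream, FormatError,
                                 SceneSpec, events_to_spikes,
                                 generate_events, read_events,
                                 write_events)


def small_scene(**kw):
    defaults = dict(width=16, height=16, duration_s=1.0, seed=3,
                    n_objects=1)
    defaults.update(kw)
    return SceneSpec(**defaults)


class TestGenerator:
    def test_static_scene_emits_nothing(self):
        scene = small_scene(speed_frac=0.0, gravity_frac=0.0)
        stream = generate_events(scene)
        assert len(stream) == 0

    def test_per_pixel_dead_time(self):
        scene = SceneSpec(width=32, height=32, duration_s=3.0, seed=7,
                          n_objects=4, speed_frac=1.2)
        stream = generate_events(scene)
        assert len(stream) > 1000
        gap = stream.min_pixel_gap_us()
        assert gap is not None and gap >= DEAD_TIME_US

    def test_determinism(self):
        a = generate_events(small_scene())
        b = generate_events(small_scene())
        assert np.array_equal(a.t, b.t)
        assert np.array_equal(a.x, b.x)
        assert np.array_equal(a.p, b.p)

    def test_event_rate_scales_linearly_with_speed(self):
        counts = []
        speeds = (0.2, 0.4, 0.8)
        for s in speeds:
            scene = small_scene(width=32, height=32, speed_frac=s,
                                gravity_frac=0.0, duration_s=2.0)
            counts.append(len(generate_events(scene)))
        r1 = counts[1] / counts[0]
        r2 = counts[2] / counts[1]
        assert r1 == pytest.approx(2.0, rel=0.25)
        assert r2 == pytest.approx(2.0, rel=0.25)

    def test_matches_bruteforce_pixelwise_threshold_oracle(self):
        """A dumb per-pixel reference implementation of the threshold rule
        must produce the identical event stream."""
        scene = small_scene(duration_s=0.5, speed_frac=0.7)
        stream = generate_events(scene)
        oracle = _bruteforce_events(scene)
        assert len(stream) == len(oracle[0])
        assert np.array_equal(stream.t, oracle[0])
        assert np.array_equal(stream.x, oracle[1])
        assert np.array_equal(stream.y, oracle[2])
        assert np.array_equal(stream.p, oracle[3])


def _bruteforce_events(scene):
    rng = np.random.default_rng(np.random.SeedSequence(scene.seed))
    w, h = scene.width, scene.height
    n_frames = int(round(scene.duration_s * 1e6 / scene.frame_dt_us))
    dt_s = scene.frame_dt_us * 1e-6
    sigma = scene.radius_frac * w
    pos = rng.uniform([0.2 * w, 0.2 * h], [0.8 * w, 0.6 * h],
                      size=(scene.n_objects, 2))
    speed = scene.speed_frac * w
    ang = rng.uniform(0, 2 * np.pi, scene.n_objects)
    vel = speed * np.column_stack((np.cos(ang), np.sin(ang)))
    grav = scene.gravity_frac * w

    def logI(p, x, y):
        v = scene.background
        for cx, cy in p:
            v += scene.intensity * np.exp(
                -((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma * sigma))
        return np.log(v)

    ref = {(x, y): logI(pos, x, y) for x in range(w) for y in range(h)}
    last = {}
    max_per_frame = scene.frame_dt_us // DEAD_TIME_US - 1
    ev = []
    for f in range(1, n_frames + 1):
        vel[:, 1] += grav * dt_s
        pos += vel * dt_s
        for dim, hi in ((0, w - 1.0), (1, h - 1.0)):
            for o in range(scene.n_objects):
                if pos[o, dim] < 0:
                    pos[o, dim] *= -1
                    vel[o, dim] *= -1
                if pos[o, dim] > hi:
                    pos[o, dim] = 2 * hi - pos[o, dim]
                    vel[o, dim] *= -1
        tf = f * scene.frame_dt_us
        for y in range(h):
            for x in range(w):
                L = logI(pos, x, y)
                d = L - ref[(x, y)]
                n = int(abs(d) // scene.threshold)
                n = min(n, max_per_frame)
                if n == 0:
                    continue
                s = 1 if d > 0 else -1
                ref[(x, y)] += s * n * scene.threshold
                for k in range(n):
                    t = tf + k * DEAD_TIME_US
                    if (x, y) in last:
                        t = max(t, last[(x, y)] + DEAD_TIME_US)
                    last[(x, y)] = t
                    ev.append((t, x, y, s))
    ev.sort(key=lambda e: e[0])
    t = np.array([e[0] for e in ev], dtype=np.int64)
    x = np.array([e[1] for e in ev], dtype=np.int16)
    y = np.array([e[2] for e in ev], dtype=np.int16)
    p = np.array([e[3] for e in ev], dtype=np.int8)
    return t, x, y, p


class TestEventIO:
    def test_roundtrip_identical(self, tmp_path):
        stream = generate_events(small_scene())
        path = tmp_path / "ev.txt"
        write_events(stream, path)
        back = read_events(path)
        assert back.width == stream.width
        assert np.array_equal(back.t, stream.t)
        assert np.array_equal(back.x, stream.x)
        assert np.array_equal(back.y, stream.y)
        assert np.array_equal(back.p, stream.p)

    def test_out_of_range_pixel_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("# dvs-events width=128 height=128\n"
                        "100 128 0 1\n")
        with pytest.raises(FormatError, match="x=128"):
            read_events(path)

    def test_timestamp_regression_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("# dvs-events width=16 height=16\n"
                        "100 0 0 1\n50 1 1 -1\n")
        with pytest.raises(FormatError, match="regression"):
            read_events(path)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "no.txt"
        path.write_text("100 0 0 1\n")
        with pytest.raises(FormatError):
            read_events(path)


class TestBinningProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(t_us=st.integers(0, 10_000_000), x=st.integers(0, 15),
           y=st.integers(0, 15))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_single_event_floor_binning(self, t_us, x, y):
        stream = EventStream(
            t=np.array([t_us], dtype=np.int64),
            x=np.array([x], dtype=np.int16),
            y=np.array([y], dtype=np.int16),
            p=np.array([1], dtype=np.int8),
            width=16, height=16, duration_us=t_us + 1)
        spikes = events_to_spikes(stream, 0.1, (16, 16))
        step = t_us // 100
        assert np.array_equal(spikes.indices_at(step), [y * 16 + x])

    @given(n=st.integers(1, 40))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_spikes_plus_collisions_equals_events(self, n):
        rng = np.random.default_rng(n)
        t = np.sort(rng.integers(0, 5000, n) * 20).astype(np.int64)
        stream = EventStream(
            t=t,
            x=rng.integers(0, 4, n).astype(np.int16),
            y=rng.integers(0, 4, n).astype(np.int16),
            p=np.ones(n, dtype=np.int8),
            width=4, height=4, duration_us=int(t[-1]) + 1)
        spikes = events_to_spikes(stream, 0.1, (4, 4))
        assert spikes.total_spikes() + spikes.collisions == n


class TestEventsToSpikes:
    def test_floor_binning(self):
        stream = EventStream(
            t=np.array([123_456], dtype=np.int64),
            x=np.array([3], dtype=np.int16),
            y=np.array([2], dtype=np.int16),
            p=np.array([1], dtype=np.int8),
            width=16, height=16, duration_us=200_000)
        spikes = events_to_spikes(stream, 0.1, (16, 16))
        assert np.array_equal(spikes.indices_at(1234), [2 * 16 + 3])
        assert spikes.total_spikes() == 1

    def test_same_step_collision_collapses(self):
        stream = EventStream(
            t=np.array([100, 115], dtype=np.int64),
            x=np.array([0, 0], dtype=np.int16),
            y=np.array([0, 0], dtype=np.int16),
            p=np.array([1, -1], dtype=np.int8),
            width=8, height=8, duration_us=1000)
        spikes = events_to_spikes(stream, 0.1, (8, 8))
        assert spikes.total_spikes() == 1
        assert spikes.collisions == 1

    def test_empty_stream_is_silent(self):
        stream = EventStream(
            t=np.empty(0, dtype=np.int64), x=np.empty(0, dtype=np.int16),
            y=np.empty(0, dtype=np.int16), p=np.empty(0, dtype=np.int8),
            width=8, height=8, duration_us=1000)
        spikes = events_to_spikes(stream, 0.1, (8, 8))
        assert spikes.total_spikes() == 0
        assert spikes.n_steps == 10

    def test_dimension_mismatch_rejected(self):
        stream = generate_events(small_scene())
        with pytest.raises(ConfigurationError):
            events_to_spikes(stream, 0.1, (32, 32))

    def test_both_polarities_drive_one_neuron(self):
        stream = EventStream(
            t=np.array([100, 5000], dtype=np.int64),
            x=np.array([1, 1], dtype=np.int16),
            y=np.array([0, 0], dtype=np.int16),
            p=np.array([1, -1], dtype=np.int8),
            width=8, height=8, duration_us=10_000)
        spikes = events_to_spikes(stream, 0.1, (8, 8))
        assert np.array_equal(np.unique(spikes.neuron), [1])
        assert spikes.total_spikes() == 2
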