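"""Synthetic event-camera (DVS-style) stimulus generation and I/O.

An event camera reports per-pixel events whenever the log-intensity on a
pixel changes by more than a contrast threshold since the pixel's last
event, with microsecond timestamps and a per-pixel dead time — here 15 µs,
matching a 128x128 sensor.  The generator renders a simple dynamic scene
(bright moving discs on a dark background, juggled under gravity by
default) on a fine time grid and applies exactly that threshold rule, so
a static scene emits nothing and event rate scales with object speed.

Events map onto the stimulus population one pixel = one neuron; ON and
OFF polarities both drive the pixel's neuron, and timestamps are floor-
binned to simulation steps with at most one spike per neuron per step
(collisions are collapsed and counted).

Event files are columnar text::

    # dvs-events width=128 height=128
    t_us x y p
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import ConfigurationError

__all__ = [
    "EventStream",
    "SceneSpec",
    "StimulusSpikes",
    "FormatError",
    "generate_events",
    "read_events",
    "write_events",
    "events_to_spikes",
]

DEAD_TIME_US = 15


class FormatError(ValueError):
    pass


@dataclass
class EventStream:
    """Columnar event stream: integer µs timestamps, pixel coords, ±1."""

    t: np.ndarray          # int64 µs, non-decreasing
    x: np.ndarray          # int16
    y: np.ndarray          # int16
    p: np.ndarray          # int8, ±1
    width: int
    height: int
    duration_us: int

    def __len__(self) -> int:
        return self.t.size

    def validate(self) -> None:
        if self.t.size == 0:
            return
        if np.any(np.diff(self.t) < 0):
            k = int(np.flatnonzero(np.diff(self.t) < 0)[0])
            raise FormatError(f"timestamp regression at event {k + 1}")
        for name, arr, hi in (("x", self.x, self.width),
                              ("y", self.y, self.height)):
            bad = (arr < 0) | (arr >= hi)
            if np.any(bad):
                k = int(np.flatnonzero(bad)[0])
                raise FormatError(
                    f"{name}={arr[k]} out of range [0, {hi}) at event {k}"
                )
        if not np.all(np.isin(self.p, (-1, 1))):
            raise FormatError("polarity must be +1 or -1")
        gap = self.min_pixel_gap_us()
        if gap is not None and gap < DEAD_TIME_US:
            raise FormatError(
                f"per-pixel inter-event gap {gap} µs below the "
                f"{DEAD_TIME_US} µs dead time"
            )

    def min_pixel_gap_us(self) -> int | None:
        """Smallest timestamp difference between consecutive events on the
        same pixel, or None if no pixel has two events."""
        if self.t.size < 2:
            return None
        pix = self.y.astype(np.int64) * self.width + self.x
        order = np.lexsort((self.t, pix))
        ps, ts = pix[order], self.t[order]
        same = ps[1:] == ps[:-1]
        if not np.any(same):
            return None
        return int(np.diff(ts)[same].min())

    def rate_per_pixel(self) -> float:
        """Mean event rate per pixel in Hz."""
        return len(self) / (self.width * self.height) / \
            (self.duration_us * 1e-6)


@dataclass
class SceneSpec:
    """A juggling-like scene: bright discs moving ballistically under
    gravity, bouncing off the frame edges, over a dark background.

    ``threshold`` is the log-intensity contrast step per event;
    ``frame_dt_us`` the rendering grid.  Generation is deterministic
    given the seed.
    """

    width: int = 128
    height: int = 128
    duration_s: float = 10.0
    seed: int = 7
    n_objects: int = 3
    radius_frac: float = 0.06        # disc sigma as a fraction of width
    speed_frac: float = 0.55         # initial speed, frame widths / s
    gravity_frac: float = 0.8        # downward acceleration, widths / s^2
    intensity: float = 1.0           # disc peak intensity
    background: float = 0.05
    threshold: float = 0.3
    frame_dt_us: int = 1000

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ConfigurationError("contrast threshold must be positive")
        if self.width <= 0 or self.height <= 0:
            raise ConfigurationError("sensor dimensions must be positive")
        if self.duration_s <= 0:
            raise ConfigurationError("duration must be positive")
        if not np.isfinite([self.speed_frac, self.gravity_frac]).all():
            raise ConfigurationError("velocities must be finite")


def generate_events(scene: SceneSpec) -> EventStream:
    """Render the scene and emit threshold-crossing events.

    Per pixel, an event fires whenever the accumulated log-intensity
    change since that pixel's last event exceeds the contrast threshold
    (polarity = sign of the change); multiple threshold crossings within
    one rendered frame are emitted 15 µs apart, and the per-pixel dead
    time is enforced across frames too.
    """
    rng = np.random.default_rng(np.random.SeedSequence(scene.seed))
    w, h = scene.width, scene.height
    n_frames = int(round(scene.duration_s * 1e6 / scene.frame_dt_us))
    dt_s = scene.frame_dt_us * 1e-6
    sigma = scene.radius_frac * w
    # object state in pixel units
    pos = rng.uniform([0.2 * w, 0.2 * h], [0.8 * w, 0.6 * h],
                      size=(scene.n_objects, 2))
    speed = scene.speed_frac * w
    angle = rng.uniform(0, 2 * np.pi, scene.n_objects)
    vel = speed * np.column_stack((np.cos(angle), np.sin(angle)))
    grav = scene.gravity_frac * w  # +y is down
    xs = np.arange(w)
    ys = np.arange(h)
    X, Y = np.meshgrid(xs, ys)  # (h, w)

    def render_log(p: np.ndarray) -> np.ndarray:
        img = np.full((h, w), scene.background)
        for cx, cy in p:
            d2 = (X - cx) ** 2 + (Y - cy) ** 2
            img += scene.intensity * np.exp(-d2 / (2 * sigma * sigma))
        return np.log(img)

    ref = render_log(pos)  # reference level at each pixel's last event
    last_t = np.full((h, w), -np.inf)
    max_per_frame = scene.frame_dt_us // DEAD_TIME_US - 1
    out_t: list[np.ndarray] = []
    out_x: list[np.ndarray] = []
    out_y: list[np.ndarray] = []
    out_p: list[np.ndarray] = []
    theta = scene.threshold
    for f in range(1, n_frames + 1):
        # ballistic update with elastic bounces
        vel[:, 1] += grav * dt_s
        pos += vel * dt_s
        for dim, hi in ((0, w - 1.0), (1, h - 1.0)):
            low = pos[:, dim] < 0
            pos[low, dim] *= -1
            vel[low, dim] *= -1
            high = pos[:, dim] > hi
            pos[high, dim] = 2 * hi - pos[high, dim]
            vel[high, dim] *= -1
        L = render_log(pos)
        delta = L - ref
        n_ev = np.floor(np.abs(delta) / theta).astype(np.int64)
        np.clip(n_ev, 0, max_per_frame, out=n_ev)
        active = n_ev > 0
        if not np.any(active):
            continue
        ay, ax = np.nonzero(active)
        counts = n_ev[ay, ax]
        sign = np.sign(delta[ay, ax]).astype(np.int8)
        ref[ay, ax] += sign * counts * theta
        t_frame = f * scene.frame_dt_us
        total = int(counts.sum())
        px = np.repeat(ax, counts)
        py = np.repeat(ay, counts)
        pp = np.repeat(sign, counts)
        # within-frame offsets 0, 15, 30, ... µs per pixel
        offs = np.arange(total) - np.repeat(
            np.concatenate(([0], np.cumsum(counts)[:-1])), counts)
        ts = t_frame + offs * DEAD_TIME_US
        # dead time across frames (never binds: the per-frame cap leaves
        # >= 25 µs before the next frame, but keep the guard explicit)
        lt = last_t[py, px]
        ts = np.maximum(ts, lt + DEAD_TIME_US)
        idx_last = np.cumsum(counts) - 1
        last_t[ay, ax] = ts[idx_last]
        out_t.append(ts.astype(np.int64))
        out_x.append(px.astype(np.int16))
        out_y.append(py.astype(np.int16))
        out_p.append(pp)
    if out_t:
        t = np.concatenate(out_t)
        x = np.concatenate(out_x)
        y = np.concatenate(out_y)
        p = np.concatenate(out_p)
        order = np.argsort(t, kind="stable")
        t, x, y, p = t[order], x[order], y[order], p[order]
    else:
        t = np.empty(0, dtype=np.int64)
        x = np.empty(0, dtype=np.int16)
        y = np.empty(0, dtype=np.int16)
        p = np.empty(0, dtype=np.int8)
    duration_us = n_frames * scene.frame_dt_us
    if t.size and int(t[-1]) >= duration_us:
        # the final frame's burst offsets spill past the nominal end
        duration_us = int(t[-1]) + 1
    stream = EventStream(t, x, y, p, w, h, duration_us=duration_us)
    stream.validate()
    return stream


def write_events(stream: EventStream, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# dvs-events width={stream.width} "
                 f"height={stream.height} duration_us={stream.duration_us}\n")
        df = pd.DataFrame({"t_us": stream.t, "x": stream.x,
                           "y": stream.y, "p": stream.p})
        df.to_csv(fh, sep=" ", index=False, header=False)


def read_events(path) -> EventStream:
    with open(path) as fh:
        header = fh.readline().strip()
    if not header.startswith("# dvs-events"):
        raise FormatError(f"{path}: missing '# dvs-events' header")
    meta = dict(kv.split("=") for kv in header.split()[2:])
    width = int(meta["width"])
    height = int(meta["height"])
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                     names=["t_us", "x", "y", "p"])
    if df.empty:
        t = np.empty(0, dtype=np.int64)
        stream = EventStream(t, t.astype(np.int16), t.astype(np.int16),
                             t.astype(np.int8), width, height,
                             int(meta.get("duration_us", 0)))
        return stream
    stream = EventStream(
        df["t_us"].to_numpy(np.int64),
        df["x"].to_numpy(np.int16),
        df["y"].to_numpy(np.int16),
        df["p"].to_numpy(np.int8),
        width,
        height,
        int(meta.get("duration_us", df["t_us"].iloc[-1] + 1)),
    )
    try:
        stream.validate()
    except FormatError as err:
        raise FormatError(f"{path}: {err}") from err
    return stream


@dataclass
class StimulusSpikes:
    """Per-step stimulus spike trains (CSR over steps)."""

    n_steps: int
    indptr: np.ndarray
    neuron: np.ndarray
    n_neurons: int
    collisions: int = 0
    dt: float = 0.1

    def indices_at(self, step: int) -> np.ndarray:
        return self.neuron[self.indptr[step]:self.indptr[step + 1]]

    def total_spikes(self) -> int:
        return int(self.neuron.size)

    def trains(self) -> list[np.ndarray]:
        """Per-neuron sorted spike times (ms, end-of-step convention)."""
        steps = np.repeat(np.arange(self.n_steps), np.diff(self.indptr))
        out: list[np.ndarray] = []
        order = np.argsort(self.neuron, kind="stable")
        nn, ss = self.neuron[order], steps[order]
        starts = np.searchsorted(nn, np.arange(self.n_neurons + 1))
        for k in range(self.n_neurons):
            out.append((ss[starts[k]:starts[k + 1]] + 1) * self.dt)
        return out


def events_to_spikes(stream: EventStream, dt: float,
                     grid: tuple[int, int]) -> StimulusSpikes:
    """Bin events onto the stimulus population's spike trains.

    ``grid`` is (rows, cols) of the stimulus population and must equal the
    sensor's (height, width).  Both polarities land on the pixel's single
    neuron (index ``y * width + x``); timestamps are floor-binned to steps
    of ``dt`` ms; multiple events of one pixel inside one step collapse to
    a single spike, counted in ``collisions``.
    """
    rows, cols = grid
    if (rows, cols) != (stream.height, stream.width):
        raise ConfigurationError(
            f"stimulus grid {rows}x{cols} does not match sensor "
            f"{stream.height}x{stream.width}"
        )
    dt_us = dt * 1000.0
    step = (stream.t / dt_us).astype(np.int64)
    neuron = stream.y.astype(np.int64) * cols + stream.x
    n_steps = int(np.ceil(stream.duration_us / dt_us))
    if step.size:
        n_steps = max(n_steps, int(step.max()) + 1)
    key = step * (rows * cols) + neuron
    uniq, counts = np.unique(key, return_counts=True)
    collisions = int((counts - 1).sum())
    u_step = uniq // (rows * cols)
    u_neuron = (uniq % (rows * cols)).astype(np.int64)
    order = np.argsort(u_step, kind="stable")
    u_step, u_neuron = u_step[order], u_neuron[order]
    indptr = np.searchsorted(u_step, np.arange(n_steps + 1))
    return StimulusSpikes(n_steps=n_steps, indptr=indptr, neuron=u_neuron,
                          n_neurons=rows * cols, collisions=collisions,
                          dt=dt)
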