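"""Time-stepped integration of the conductance-based LIF network.

Membrane dynamics per neuron:

    C dV/dt = −g_L (V − V_L) − g^E (V − V_E) − g^I (V − V_I)

with conductances from difference-of-exponentials kernels

    G(t) = (e^{−t/τ_d} − e^{−t/τ_r}) / (τ_d − τ_r),   ∫₀^∞ G dt = 1,

implemented exactly with two per-neuron exponential accumulators per
synapse type (a delivered spike adds its weight to both; the conductance
is their scaled difference).  The membrane equation is advanced with
exponential Euler (exact for the leak-only case, unconditionally stable,
and voltage stays inside [V_I, V_E] by construction).  A neuron crossing
threshold emits a spike at the step's end time, is reset to V_rt and
clamped there for the refractory period τ_ref while its synaptic
conductances keep evolving.  Spikes are delivered to their targets at the
next step (the kernel is zero at t = 0 anyway).

Each emitted spike is independently marked plasticity-visible with
probability 1 − p_noise of its population; invisible spikes propagate
normally but are hidden from the learning machinery.
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field

import numpy as np

from .network import EXCITATORY, ConfigurationError, Network
from .plasticity import PlasticityEngine

__all__ = ["kernel_value", "Simulator", "RunResult", "IntegrationError",
           "InputExhaustedError"]


class IntegrationError(RuntimeError):
    pass


class InputExhaustedError(ValueError):
    pass


def kernel_value(t, tau_r: float, tau_d: float):
    """Normalised difference-of-exponentials conductance kernel (1/ms).

    ``(exp(-t/tau_d) - exp(-t/tau_r)) / (tau_d - tau_r)`` for t >= 0; the
    denominator normalises the kernel to unit integral.
    """
    if tau_r <= 0 or tau_d <= 0:
        raise ConfigurationError("kernel time constants must be positive")
    if tau_d == tau_r:
        raise ConfigurationError(
            "degenerate kernel: tau_d must differ from tau_r"
        )
    if tau_d < tau_r:
        raise ConfigurationError("tau_d must exceed tau_r")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("kernel is causal: t must be >= 0")
    return (np.exp(-t / tau_d) - np.exp(-t / tau_r)) / (tau_d - tau_r)


class VoltageHistory:
    """Rolling per-neuron voltage history spanning one activity window.

    Stores the pre-reset membrane potential at each of the last
    ``size`` steps so window contributions can sample the driving force
    at the window's opening time.
    """

    def __init__(self, n: int, size: int, offsets: dict[str, int]) -> None:
        self.buf = np.empty((size, n))
        self.size = size
        self.offsets = offsets

    def write(self, step: int, V: np.ndarray) -> None:
        self.buf[step % self.size] = V

    def value(self, pop: str, i: int, step: int) -> float:
        return self.buf[step % self.size, self.offsets[pop] + i]


@dataclass
class RunResult:
    """Everything a simulation run produces."""

    duration: float
    pops: list[str]
    offsets: dict[str, int]
    spike_t: np.ndarray          # ms, end-of-step times, non-decreasing
    spike_idx: np.ndarray        # global simulated-neuron index
    spike_visible: np.ndarray    # learning-noise gate, decided at emission
    v_min: float
    v_max: float
    counters: dict[str, int] = field(default_factory=dict)
    current_t: np.ndarray | None = None
    current_exc: np.ndarray | None = None   # g^E (V - V_E), nA, per neuron
    current_inh: np.ndarray | None = None   # g^I (V - V_I), nA
    current_idx: np.ndarray | None = None
    v_snapshots: dict[float, np.ndarray] = field(default_factory=dict)
    rhat_log: dict[str, list] = field(default_factory=dict)

    def pop_of(self, idx: np.ndarray) -> np.ndarray:
        names = np.array(self.pops)
        bounds = np.array([self.offsets[p] for p in self.pops] +
                          [np.iinfo(np.int64).max])
        return names[np.searchsorted(bounds, idx, side="right") - 1]

    def spikes_for(self, pop: str, local: bool = True) -> tuple[np.ndarray,
                                                                np.ndarray]:
        """(times, indices) of one population's spikes."""
        off = self.offsets[pop]
        n_next = [self.offsets[p] for p in self.pops if self.offsets[p] > off]
        hi = min(n_next) if n_next else np.inf
        m = (self.spike_idx >= off) & (self.spike_idx < hi)
        idx = self.spike_idx[m] - (off if local else 0)
        return self.spike_t[m], idx

    def trains_for(self, pop: str, n: int) -> list[np.ndarray]:
        """Per-neuron sorted spike-time arrays for one population."""
        t, idx = self.spikes_for(pop)
        order = np.argsort(idx, kind="stable")
        t, idx = t[order], idx[order]
        starts = np.searchsorted(idx, np.arange(n + 1))
        return [t[starts[k]:starts[k + 1]] for k in range(n)]


class Simulator:
    """Steps a :class:`~plasticnet.network.Network` through time.

    Parameters
    ----------
    network:
        Topology + synapse groups (weights are trained in place when
        learning is enabled).
    seed:
        Master seed; independent named RNG streams are spawned for
        learning noise so toggling one component does not shift another's
        draws.
    learn:
        Enables the plasticity engine.
    engine_kwargs:
        Forwarded to :class:`~plasticnet.plasticity.PlasticityEngine`.
    """

    def __init__(
        self,
        network: Network,
        seed: int = 0,
        *,
        learn: bool = True,
        engine_kwargs: dict | None = None,
    ) -> None:
        self.net = network
        self.cfg = network.cfg
        cfg = self.cfg
        self.pops = network.sim_pops
        sizes = [network.topology.size(p) for p in self.pops]
        self.offsets = {p: int(o) for p, o in
                        zip(self.pops, np.concatenate(([0],
                                                       np.cumsum(sizes))))}
        self.n = int(sum(sizes))
        ss = np.random.SeedSequence(seed)
        kids = ss.spawn(3)
        self.rng_noise = np.random.default_rng(kids[0])
        self.rng_misc = np.random.default_rng(kids[1])
        # state
        self.V = np.full(self.n, cfg.V_L)
        self.refr_until = np.full(self.n, -np.inf)
        self.xr_E = np.zeros(self.n)
        self.xd_E = np.zeros(self.n)
        self.xr_I = np.zeros(self.n)
        self.xd_I = np.zeros(self.n)
        self.step_idx = 0
        self.v_min = cfg.V_L
        self.v_max = cfg.V_L
        # per-population p_noise vector over global indices
        self.p_noise = np.concatenate([
            np.full(network.topology.size(p),
                    network.topology.spec(p).p_noise)
            for p in self.pops
        ])
        self._pop_of_global = np.concatenate([
            np.full(network.topology.size(p), k, dtype=np.int32)
            for k, p in enumerate(self.pops)
        ])
        # decay factors
        self._d_rE = math.exp(-cfg.dt / cfg.tau_r_E)
        self._d_dE = math.exp(-cfg.dt / cfg.tau_d_E)
        self._d_rI = math.exp(-cfg.dt / cfg.tau_r_I)
        self._d_dI = math.exp(-cfg.dt / cfg.tau_d_I)
        self._inv_E = 1.0 / (cfg.tau_d_E - cfg.tau_r_E)
        self._inv_I = 1.0 / (cfg.tau_d_I - cfg.tau_r_I)
        # delivery tables: per group, posts as global indices
        self._deliver: dict[str, tuple] = {}
        for g in network.groups.values():
            post_global = g.post + self.offsets[g.post_pop]
            excit = g.pre_sign == EXCITATORY
            self._deliver[g.name] = (g, post_global, excit)
        self.v_hist = VoltageHistory(self.n, cfg.window_steps + 2,
                                     self.offsets)
        self.learn = learn
        if learn:
            self.engine = PlasticityEngine(network, **(engine_kwargs or {}))
            self.engine.v_hist = self.v_hist
        else:
            self.engine = None
        self._pending: list[tuple[str, int]] = []  # recurrent spikes to deliver
        self._stim_groups = [g for g in network.groups.values()
                             if g.pre_pop == "D"]
        self._out_names = {p: [g.name for g in network.outgoing(p)]
                           for p in self.pops}
        #: optional (StimulusSpikes-like, weight) pairs: uniform
        #: excitatory drive to every simulated neuron, outside plasticity
        self.extra_drives: list[tuple] = []

    # ------------------------------------------------------------------ #

    def _deliver_spikes(self, spikes: list[tuple[str, int]]) -> None:
        for gname, j in spikes:
            g, post_global, excit = self._deliver[gname]
            sl = slice(g.indptr[j], g.indptr[j + 1])
            tgt = post_global[sl]
            w = g.w[sl]
            if excit:
                self.xr_E[tgt] += w
                self.xd_E[tgt] += w
            else:
                self.xr_I[tgt] += w
                self.xd_I[tgt] += w

    def step(self, stim_spikes: np.ndarray | None = None):
        """Advance one time step; returns (global spike indices, visible).

        ``stim_spikes`` are indices of stimulus (D) neurons whose events
        fall in this step; they drive their targets this step and open
        Hebbian windows dated to the step's end time.
        """
        cfg = self.cfg
        t = self.step_idx * cfg.dt
        te = (self.step_idx + 1) * cfg.dt  # spikes land on the step grid
        # synaptic decay (exact exponential)
        self.xr_E *= self._d_rE
        self.xd_E *= self._d_dE
        self.xr_I *= self._d_rI
        self.xd_I *= self._d_dI
        # deliver recurrent spikes from the previous step + stimulus events
        if self._pending:
            self._deliver_spikes(self._pending)
            self._pending = []
        if stim_spikes is not None and len(stim_spikes):
            self._deliver_spikes(
                [(g.name, int(j)) for g in self._stim_groups
                 for j in stim_spikes]
            )
        for drv, w in self.extra_drives:
            k = len(drv.indices_at(self.step_idx))
            if k:
                self.xr_E += w * k
                self.xd_E += w * k
        g_E = (self.xd_E - self.xr_E) * self._inv_E
        g_I = (self.xd_I - self.xr_I) * self._inv_I
        # exponential-Euler membrane update for non-refractory neurons
        g_tot = cfg.g_L + g_E + g_I
        V_inf = (cfg.g_L * cfg.V_L + g_E * cfg.V_E + g_I * cfg.V_I) / g_tot
        decay = np.exp(-(cfg.dt / cfg.C) * g_tot)
        V = V_inf + (self.V - V_inf) * decay
        refr = self.refr_until > t
        V[refr] = cfg.V_rt
        if not np.all(np.isfinite(V)):
            bad = int(np.flatnonzero(~np.isfinite(V))[0])
            raise IntegrationError(
                f"non-finite membrane potential in neuron {bad} at t={te} ms"
            )
        self.V = V
        self._g_E, self._g_I = g_E, g_I  # exposed for current recording
        vmin = V.min()
        vmax = V.max()
        if vmin < self.v_min:
            self.v_min = float(vmin)
        if vmax > self.v_max:
            self.v_max = float(vmax)
        self.v_hist.write(self.step_idx, V)
        if self.engine is not None:
            for pop in self.pops:
                o = self.offsets[pop]
                self.engine.accumulate(
                    pop, V[o:o + self.net.topology.size(pop)]
                )
        # threshold crossing
        can = (V >= cfg.V_th) & ~refr
        spiking = np.flatnonzero(can)
        visible = np.empty(0, dtype=bool)
        if spiking.size:
            self.V[spiking] = cfg.V_rt
            self.refr_until[spiking] = te + cfg.tau_ref
            visible = (self.rng_noise.random(spiking.size)
                       >= self.p_noise[spiking])
            for gidx in spiking:
                pop = self.pops[self._pop_of_global[gidx]]
                loc = int(gidx) - self.offsets[pop]
                for gname in self._out_names[pop]:
                    self._pending.append((gname, loc))
        if self.engine is not None:
            # postsynaptic rules first, then open new windows, so a spike
            # never lands in a window opened in its own step
            for k, gidx in enumerate(spiking):
                pop = self.pops[self._pop_of_global[gidx]]
                loc = int(gidx) - self.offsets[pop]
                if visible[k]:
                    self.engine.on_post_spike(pop, loc, te, self.step_idx)
                else:
                    self.engine.on_invisible_post_spike(pop, loc, te)
            for k, gidx in enumerate(spiking):
                if visible[k]:
                    pop = self.pops[self._pop_of_global[gidx]]
                    loc = int(gidx) - self.offsets[pop]
                    self.engine.on_pre_spike(pop, loc, te, self.step_idx)
            if stim_spikes is not None and len(stim_spikes):
                p_noise_D = self.net.topology.spec("D").p_noise
                if p_noise_D > 0:
                    vis_D = self.rng_noise.random(len(stim_spikes)) >= p_noise_D
                else:
                    vis_D = np.ones(len(stim_spikes), dtype=bool)
                for j, v in zip(stim_spikes, vis_D):
                    if v:
                        self.engine.on_pre_spike("D", int(j), te,
                                                 self.step_idx)
            self.engine.close_due_windows(te, self.step_idx)
        self.step_idx += 1
        return spiking, visible

    # ------------------------------------------------------------------ #

    def run(
        self,
        duration: float,
        stimulus=None,
        *,
        record_currents: tuple | None = None,
        v_snapshot_times: tuple[float, ...] = (),
        record_rhat: tuple[str, ...] = (),
    ) -> RunResult:
        """Run for ``duration`` ms from the current state.

        ``stimulus`` is any object with ``n_steps`` and
        ``indices_at(step) -> array of D indices`` (see
        :class:`~plasticnet.stimulus.StimulusSpikes`); it must cover the
        run.  ``record_currents = (idx, t_start, t_stop, every)`` records
        the excitatory and inhibitory input currents of the global
        indices ``idx`` every ``every`` steps inside [t_start, t_stop).
        Deterministic given (network, seed, stimulus).
        """
        cfg = self.cfg
        n_steps = int(round(duration / cfg.dt))
        start_step = self.step_idx
        if stimulus is not None and stimulus.n_steps < start_step + n_steps:
            raise InputExhaustedError(
                f"stimulus covers {stimulus.n_steps} steps; "
                f"{start_step + n_steps} required"
            )
        if record_rhat and self.engine is not None:
            for name in record_rhat:
                self.engine.rhat_log.setdefault(name, [])
        spk_t: list[np.ndarray] = []
        spk_i: list[np.ndarray] = []
        spk_v: list[np.ndarray] = []
        cur_t: list[float] = []
        cur_e: list[np.ndarray] = []
        cur_i: list[np.ndarray] = []
        if record_currents is not None:
            rc_idx = np.asarray(record_currents[0], dtype=np.int64)
            rc_lo, rc_hi, rc_every = (record_currents[1], record_currents[2],
                                      int(record_currents[3]))
        snap_steps = {int(round(tm / cfg.dt)): tm for tm in v_snapshot_times}
        snaps: dict[float, np.ndarray] = {}
        for k in range(n_steps):
            s = self.step_idx
            stim = stimulus.indices_at(s) if stimulus is not None else None
            spiking, visible = self.step(stim)
            te = (s + 1) * cfg.dt
            if spiking.size:
                spk_t.append(np.full(spiking.size, te))
                spk_i.append(spiking.astype(np.int64))
                spk_v.append(visible)
            if record_currents is not None and rc_lo <= te < rc_hi \
                    and s % rc_every == 0:
                cur_t.append(te)
                cur_e.append(self._g_E[rc_idx] * (self.V[rc_idx] - cfg.V_E))
                cur_i.append(self._g_I[rc_idx] * (self.V[rc_idx] - cfg.V_I))
            if s in snap_steps:
                snaps[snap_steps[s]] = self.V.copy()
        counters = {"steps": n_steps, "spikes": int(sum(a.size for a in spk_i))}
        if self.engine is not None:
            counters.update(
                windows_opened=self.engine.windows_opened,
                windows_closed=self.engine.windows_closed,
                nonhebb_clamps=self.engine.clamp_count,
            )
        return RunResult(
            duration=n_steps * cfg.dt,
            pops=list(self.pops),
            offsets=dict(self.offsets),
            spike_t=(np.concatenate(spk_t) if spk_t else np.empty(0)),
            spike_idx=(np.concatenate(spk_i) if spk_i
                       else np.empty(0, dtype=np.int64)),
            spike_visible=(np.concatenate(spk_v) if spk_v
                           else np.empty(0, dtype=bool)),
            v_min=self.v_min,
            v_max=self.v_max,
            counters=counters,
            current_t=np.asarray(cur_t) if cur_t else None,
            current_exc=np.asarray(cur_e) if cur_e else None,
            current_inh=np.asarray(cur_i) if cur_i else None,
            current_idx=(rc_idx if record_currents is not None else None),
            v_snapshots=snaps,
            rhat_log=(dict(self.engine.rhat_log) if self.engine else {}),
        )

    # ------------------------------------------------------------------ #
    # checkpointing

    def checkpoint(self) -> bytes:
        """Serialise the full simulator state (bit-exact round trip)."""
        eng = self.engine
        state = {
            "step_idx": self.step_idx,
            "V": self.V.copy(),
            "refr_until": self.refr_until.copy(),
            "x": [a.copy() for a in (self.xr_E, self.xd_E,
                                     self.xr_I, self.xd_I)],
            "v_minmax": (self.v_min, self.v_max),
            "rng_noise": self.rng_noise.bit_generator.state,
            "rng_misc": self.rng_misc.bit_generator.state,
            "pending": list(self._pending),
            "v_hist": self.v_hist.buf.copy(),
            "weights": {g.name: g.w.copy()
                        for g in self.net.groups.values()},
        }
        if eng is not None:
            state["engine"] = {
                "acc_E": {p: a.copy() for p, a in eng.acc_E.items()},
                "acc_I": {p: a.copy() for p, a in eng.acc_I.items()},
                "prev_vis": {p: a.copy() for p, a in eng.prev_vis.items()},
                "clamp_count": eng.clamp_count,
                "windows": {
                    name: [(w.pre, w.t_open, w.step, list(w.pos), list(w.u))
                           for w in fifo]
                    for name, fifo in eng._fifo.items()
                },
            }
        return pickle.dumps(state)

    def restore(self, blob: bytes) -> None:
        from .plasticity import HebbianWindow

        state = pickle.loads(blob)
        self.step_idx = state["step_idx"]
        self.V = state["V"].copy()
        self.refr_until = state["refr_until"].copy()
        self.xr_E, self.xd_E, self.xr_I, self.xd_I = \
            (a.copy() for a in state["x"])
        self.v_min, self.v_max = state["v_minmax"]
        self.rng_noise.bit_generator.state = state["rng_noise"]
        self.rng_misc.bit_generator.state = state["rng_misc"]
        self._pending = list(state["pending"])
        self.v_hist.buf = state["v_hist"].copy()
        for g in self.net.groups.values():
            g.w[:] = state["weights"][g.name]
        if self.engine is not None and "engine" in state:
            eng = self.engine
            es = state["engine"]
            for p in eng.acc_E:
                eng.acc_E[p][:] = es["acc_E"][p]
                eng.acc_I[p][:] = es["acc_I"][p]
                eng.prev_vis[p][:] = es["prev_vis"][p]
            eng.clamp_count = es["clamp_count"]
            from collections import deque
            for name, rows in es["windows"].items():
                fifo = deque()
                by_pre: dict[int, list] = {}
                for pre, t_open, stp, pos, u in rows:
                    w = HebbianWindow(pre, t_open, stp)
                    w.pos = list(pos)
                    w.u = list(u)
                    fifo.append(w)
                    by_pre.setdefault(pre, []).append(w)
                eng._fifo[name] = fifo
                eng._open[name] = by_pre
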