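"""Decoded presynaptic rate, Hebbian and non-Hebbian plasticity.

The learning scheme treats a recurrent spiking network as an autoencoder:
each presynaptic neuron j should be decodable from the activity of its
postsynaptic neurons.  The decoded instantaneous presynaptic firing rate is

    r̂_j(t) = γ Σ_i  w_ij (V_i(t) − V_rev) e^{−(t_i − t)/τ} / C ,

summing, for each postsynaptic neuron i, the contribution of i's *first*
spike t_i in the window (t, t + τ_A]; the driving force is sampled at t and
the exponential reflects the leaky decay of the presynaptic spike's imprint
on the postsynaptic membrane.  Contributions use the unsigned driving force
(V_E − V_i for excitatory synapses, V_i − V_I for inhibitory), so r̂ ≥ 0.

Two weight updates follow:

* Hebbian (per presynaptic spike, applied when its window closes at
  t_j + τ_A): Δw_ij = ε w_ij u_i / r̂_j, where u_i is i's contribution term.
  Each non-empty window adds exactly ε/γ of total weight across its
  targets — credit assignment proportional to contribution.
* non-Hebbian (per postsynaptic spike at t_i): Δw_ij = −ε w_ij a_i / C for
  every input synapse, where a_i = ∫_{t_k}^{t_i} (V_i − V_rev) e^{−(t_i−t')/τ} dt'
  is an exponentially-weighted integral of the driving force since the
  previous postsynaptic spike t_k.  The relative decrement is identical
  across all inputs of one population pair (heterosynaptic uniformity).

Spikes can be hidden from learning with per-population probability
``p_noise``; a hidden spike propagates normally in the dynamics but opens
no window, is never a first spike, triggers no non-Hebbian update and (by
default) does not reset the accumulator.
"""

from __future__ import annotations

import logging
import math
from collections import deque

import numpy as np

from .network import EXCITATORY, ConfigurationError, Network, SynapseGroup

logger = logging.getLogger(__name__)

__all__ = [
    "HebbianWindow",
    "PlasticityEngine",
    "decode_rate",
    "configure_gamma",
    "implied_fractions",
    "decode_population_rate",
]


class HebbianWindow:
    """Open bookkeeping record of one visible presynaptic spike.

    Collects, per postsynaptic neuron, the contribution of that neuron's
    first visible spike inside (t_open, t_open + τ_A].  ``pos`` holds the
    weight-array slots of contributing synapses and ``u`` the matching
    contribution terms (driving force at t_open × exponential decay / C).
    """

    __slots__ = ("pre", "t_open", "step", "pos", "u")

    def __init__(self, pre: int, t_open: float, step: int) -> None:
        self.pre = pre
        self.t_open = t_open
        self.step = step
        self.pos: list[int] = []
        self.u: list[float] = []


def decode_rate(window: HebbianWindow, weights: np.ndarray,
                gamma: float) -> float:
    """r̂ for a closed window: γ Σ w·u (0 for an empty window)."""
    if gamma <= 0:
        raise ConfigurationError("gamma must be positive")
    if not window.pos:
        return 0.0
    w = weights[np.asarray(window.pos)]
    return float(gamma * (w * np.asarray(window.u)).sum())


class PlasticityEngine:
    """Applies the plasticity rules during a simulation.

    The engine owns, per simulated population, the non-Hebbian
    accumulators (one per synapse type) and the time of each neuron's
    previous plasticity-visible spike; per synapse group it owns the open
    Hebbian windows.  The driving force for a window contribution is read
    from the simulator's rolling voltage history at the window's opening
    step.

    Parameters
    ----------
    network:
        The network whose synapse groups are trained in place.
    clamp_fraction:
        Maximum relative decrement a single non-Hebbian event may apply
        (the multiplicative rule could otherwise drive a weight negative);
        clipped events are counted in ``clamp_count``.
    record_rhat:
        Synapse-group names (e.g. ``"DE"``) whose per-window decoded rate
        is logged as (t_open, pre_index, r̂) triples.
    record_events:
        If true, every weight change is logged as
        (t, kind, group, pre, post, delta_w) for replay oracles.
    reset_on_invisible:
        Config switch: whether a learning-invisible postsynaptic spike
        still resets the accumulator (default False: invisible spikes are
        invisible to all plasticity machinery).
    """

    def __init__(
        self,
        network: Network,
        *,
        clamp_fraction: float = 0.9,
        record_rhat: tuple[str, ...] = (),
        record_events: bool = False,
        reset_on_invisible: bool = False,
    ) -> None:
        self.net = network
        self.cfg = network.cfg
        self.clamp_fraction = float(clamp_fraction)
        self.reset_on_invisible = reset_on_invisible
        self.clamp_count = 0
        self.windows_opened = 0
        self.windows_closed = 0
        self.record_events = record_events
        self.events: list[tuple] = []
        self.rhat_log: dict[str, list[tuple[float, int, float]]] = {
            name: [] for name in record_rhat
        }
        self.v_hist = None  # set by the simulator
        # per simulated population state
        self.acc_E: dict[str, np.ndarray] = {}
        self.acc_I: dict[str, np.ndarray] = {}
        self.prev_vis: dict[str, np.ndarray] = {}
        for pop in network.sim_pops:
            n = network.topology.size(pop)
            self.acc_E[pop] = np.zeros(n)
            self.acc_I[pop] = np.zeros(n)
            self.prev_vis[pop] = np.full(n, -np.inf)
        # per-group window bookkeeping
        self._fifo: dict[str, deque[HebbianWindow]] = {}
        self._open: dict[str, dict[int, list[HebbianWindow]]] = {}
        self._in_nb: dict[str, dict[int, list[tuple[int, int]]]] = {}
        for g in network.groups.values():
            self._fifo[g.name] = deque()
            self._open[g.name] = {}
            self._in_nb[g.name] = {}
        self._incoming = {p: network.incoming(p) for p in network.sim_pops}
        self._outgoing = {
            p.name: network.outgoing(p.name)
            for p in network.topology.populations
        }
        tau = self.cfg.tau_m
        self._exp_dt = math.exp(-self.cfg.dt / tau)
        self._acc_gain = tau * (1.0 - self._exp_dt)
        # decay lookup by step offset, e^{-k dt / tau} for k in [0, tau_A/dt]
        self._exp_table = np.exp(
            -np.arange(self.cfg.window_steps + 2) * self.cfg.dt / tau
        ).tolist()

    # ------------------------------------------------------------------ #
    # per-step operations

    def accumulate(self, pop: str, V: np.ndarray) -> None:
        """Advance the non-Hebbian accumulators one step (exact update).

        Solves da/dt = drive − a/τ with the driving force held constant
        over the step: a ← a e^{−Δt/τ} + drive·τ(1 − e^{−Δt/τ}).
        """
        cfg = self.cfg
        drive_E = np.maximum(cfg.V_E - V, 0.0)
        drive_I = np.maximum(V - cfg.V_I, 0.0)
        aE = self.acc_E[pop]
        aI = self.acc_I[pop]
        aE *= self._exp_dt
        aE += drive_E * self._acc_gain
        aI *= self._exp_dt
        aI += drive_I * self._acc_gain

    def close_due_windows(self, t: float, step: int | None = None) -> None:
        """Close every window whose τ_A has elapsed and apply the Hebbian
        credit.  With ``step`` given the comparison is done in integer
        steps (spike times sit on the step grid, so this is exact and
        immune to float accumulation)."""
        if step is not None:
            ws = self.cfg.window_steps
            for name, fifo in self._fifo.items():
                while fifo and step - fifo[0].step >= ws:
                    win = fifo.popleft()
                    self._open[name][win.pre].pop(0)
                    self._close_one(self.net.groups_by_name[name], win)
            return
        tau_A = self.cfg.tau_A
        for name, fifo in self._fifo.items():
            while fifo and fifo[0].t_open + tau_A <= t:
                win = fifo.popleft()
                self._open[name][win.pre].pop(0)
                self._close_one(self.net.groups_by_name[name], win)

    # ------------------------------------------------------------------ #
    # per-spike operations

    def on_pre_spike(self, pop: str, j: int, t: float, step: int) -> None:
        """A visible presynaptic spike opens one window per target pair."""
        for g in self._outgoing[pop]:
            win = HebbianWindow(j, t, step)
            self._fifo[g.name].append(win)
            self._open[g.name].setdefault(j, []).append(win)
            self.windows_opened += 1

    def on_post_spike(self, pop: str, i: int, t: float,
                      step: int | None = None) -> None:
        """A visible postsynaptic spike: non-Hebbian depression of all
        inputs, first-spike contributions to open windows, accumulator
        reset.

        ``step`` is the integration step of the spike; when given, the
        exponential decay is taken from a per-step lookup table (exact,
        since spikes land on the step grid).
        """
        cfg = self.cfg
        prev = self.prev_vis[pop][i]
        inv_C = 1.0 / cfg.C
        tau = cfg.tau_m
        vh = self.v_hist
        use_table = step is not None and vh is not None
        if use_table:
            flat = vh.buf.reshape(-1)
            nbuf = vh.buf.shape[1]
            base = vh.offsets[pop] + i
            size = vh.size
            table = self._exp_table
        for g in self._incoming[pop]:
            excit = g.pre_sign == EXCITATORY
            a = (self.acc_E[pop][i] if excit else self.acc_I[pop][i])
            if a > 0.0 and g.epsilon > 0.0:
                frac = g.epsilon * a * inv_C
                if frac > self.clamp_fraction:
                    frac = self.clamp_fraction
                    self.clamp_count += 1
                seg = slice(g.pindptr[i], g.pindptr[i + 1])
                sl = g.pos[seg]
                if self.record_events:
                    old = g.w[sl].copy()
                g.w[sl] *= 1.0 - frac
                if self.record_events:
                    for j_, d_ in zip(g.pre[seg], g.w[sl] - old):
                        self.events.append(
                            (t, "nH", g.name, int(j_), i, float(d_))
                        )
            open_by_pre = self._open[g.name]
            if open_by_pre:
                rev = g.reversal
                get = open_by_pre.get
                if use_table:
                    for j, pos in self._neighbours(g, i):
                        wl = get(j)
                        if not wl:
                            continue
                        for win in wl:
                            if prev <= win.t_open:
                                v = flat[(win.step % size) * nbuf + base]
                                drive = (rev - v) if excit else (v - rev)
                                if drive > 0.0:
                                    win.pos.append(pos)
                                    win.u.append(
                                        drive * inv_C * table[step - win.step]
                                    )
                else:
                    for j, pos in self._neighbours(g, i):
                        wl = get(j)
                        if not wl:
                            continue
                        for win in wl:
                            if prev <= win.t_open:
                                v = self.v_hist.value(pop, i, win.step)
                                drive = (rev - v) if excit else (v - rev)
                                if drive > 0.0:
                                    u = (drive * inv_C
                                         * math.exp(-(t - win.t_open) / tau))
                                    win.pos.append(pos)
                                    win.u.append(u)
        self.acc_E[pop][i] = 0.0
        self.acc_I[pop][i] = 0.0
        self.prev_vis[pop][i] = t

    def on_invisible_post_spike(self, pop: str, i: int, t: float) -> None:
        """Optionally reset accumulators for a learning-invisible spike."""
        if self.reset_on_invisible:
            self.acc_E[pop][i] = 0.0
            self.acc_I[pop][i] = 0.0

    # ------------------------------------------------------------------ #
    # internals

    def _neighbours(self, g: SynapseGroup, i: int) -> list[tuple[int, int]]:
        cache = self._in_nb[g.name]
        nb = cache.get(i)
        if nb is None:
            sl = slice(g.pindptr[i], g.pindptr[i + 1])
            nb = list(zip(g.pre[sl].tolist(), g.pos[sl].tolist()))
            cache[i] = nb
        return nb

    def _close_one(self, g: SynapseGroup, win: HebbianWindow) -> None:
        self.windows_closed += 1
        log = self.rhat_log.get(g.name)
        if not win.pos:
            if log is not None:
                log.append((win.t_open, win.pre, 0.0))
            return
        pos = np.asarray(win.pos, dtype=np.int64)
        u = np.asarray(win.u)
        wv = g.w[pos]
        contrib = wv * u
        total = contrib.sum()
        if total <= 0.0:
            raise RuntimeError(
                f"non-empty window with zero decoded rate in {g.name} "
                f"(pre={win.pre}, t={win.t_open}); internal error"
            )
        rhat = g.gamma * total
        delta = g.epsilon * contrib / rhat
        g.w[pos] += delta
        if log is not None:
            log.append((win.t_open, win.pre, float(rhat)))
        if self.record_events:
            t_close = win.t_open + self.cfg.tau_A
            for p_, d_ in zip(pos, delta):
                self.events.append(
                    (t_close, "H", g.name, win.pre, int(g.post[p_]), float(d_))
                )

    def flush(self, t: float) -> None:
        """Force-close every open window (end of run)."""
        for name, fifo in self._fifo.items():
            g = self.net.groups_by_name[name]
            while fifo:
                win = fifo.popleft()
                self._open[name][win.pre].pop(0)
                self._close_one(g, win)


# ---------------------------------------------------------------------- #
# gamma configuration (stability / excitation-inhibition balance)


def configure_gamma(
    rates: dict[str, float],
    shares: dict[str, float],
    fractions: dict[str, float],
    V_s: float,
    post_pops: tuple[str, ...] = ("E", "I"),
    external_fraction: float = 0.0,
) -> dict[tuple[str, str], float]:
    """Choose r̂ scaling factors γ^{αβ} from the stability condition.

    Stability requires that, over a period containing s_α spikes from each
    source population α, the summed membrane-potential contribution to a
    target population β equals the voltage needed to produce its spikes:

        V_s s_β = Σ_{α excit} s_α ⟨r̂^{αβ}⟩/γ^{αβ} − Σ_{α inhib} s_α ⟨r̂^{αβ}⟩/γ^{αβ}

    Each source α is assigned a fraction f_α of the net per-spike voltage
    V_s (with the feasibility constraint f_D + f_E − f_I = 1), giving

        γ^{αβ} = s_α ⟨r^α⟩ / (f_α V_s s_β).

    Sources with f_α = 0 contribute nothing and get no γ.

    Parameters
    ----------
    rates:
        Expected mean firing rate ⟨r^α⟩ per source population (ms⁻¹); at
        the learned fixed point ⟨r̂^{αβ}⟩ ≈ ⟨r^α⟩.
    shares:
        Expected spike-count shares s_α (any common scale) for every
        population appearing as source or target.
    fractions:
        f_α per source population.
    V_s:
        Reset-to-threshold voltage (mV).
    """
    if V_s <= 0:
        raise ConfigurationError("V_s must be positive")
    sgn = {"D": 1.0, "E": 1.0, "I": -1.0}
    net = sum(sgn.get(a, 1.0) * f for a, f in fractions.items())
    net += external_fraction  # drive supplied outside the modelled sources
    if abs(net - 1.0) > 1e-9:
        raise ConfigurationError(
            f"infeasible balance fractions: f_D + f_E - f_I = {net}, not 1"
        )
    for a, f in fractions.items():
        if f < 0:
            raise ConfigurationError(f"fraction f_{a} must be >= 0")
    gammas: dict[tuple[str, str], float] = {}
    for beta in post_pops:
        if beta not in shares:
            raise ConfigurationError(f"missing spike share for {beta!r}")
        for alpha, f in fractions.items():
            if f == 0.0:
                continue
            if rates.get(alpha, 0.0) <= 0:
                raise ConfigurationError(
                    f"expected rate for {alpha!r} must be positive"
                )
            gammas[(alpha, beta)] = (
                shares[alpha] * rates[alpha] / (f * V_s * shares[beta])
            )
    return gammas


def implied_fractions(
    gammas: dict[tuple[str, str], float],
    rates: dict[str, float],
    shares: dict[str, float],
    V_s: float,
) -> dict[tuple[str, str], float]:
    """Invert the stability condition: the voltage fraction each source
    supplies per target spike under given γ values."""
    out = {}
    for (alpha, beta), gamma in gammas.items():
        out[(alpha, beta)] = (
            shares[alpha] * rates[alpha] / (gamma * V_s * shares[beta])
        )
    return out


# ---------------------------------------------------------------------- #
# offline decoding (same first-spike contribution rule as learning)


def decode_population_rate(
    group: SynapseGroup,
    post_spikes: list[np.ndarray],
    V_at_t: np.ndarray,
    t: float,
    *,
    tau_m: float,
    tau_A: float,
    C: float,
) -> np.ndarray:
    """r̂^{αβ}_j(t) for every presynaptic neuron j of one synapse group.

    ``post_spikes`` holds each postsynaptic neuron's sorted spike times;
    ``V_at_t`` its membrane potentials sampled at the evaluation time t.
    The same first-spike-in-(t, t+τ_A] rule and contribution term as the
    learning path are applied; r̂ can be evaluated at any t, independent of
    presynaptic activity.
    """
    excit = group.pre_sign == EXCITATORY
    rev = group.reversal
    rhat = np.zeros(group.n_pre)
    for i in range(group.n_post):
        times = post_spikes[i]
        if times.size == 0:
            continue
        k = np.searchsorted(times, t, side="right")
        if k >= times.size:
            continue
        t_i = times[k]
        if t_i > t + tau_A:
            continue
        drive = (rev - V_at_t[i]) if excit else (V_at_t[i] - rev)
        if drive <= 0.0:
            continue
        u = drive * math.exp(-(t_i - t) / tau_m) / C
        sl = slice(group.pindptr[i], group.pindptr[i + 1])
        rhat[group.pre[sl]] += group.w[group.pos[sl]] * u
    return group.gamma * rhat
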