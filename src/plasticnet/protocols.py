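"""Closed-form plasticity-protocol predictions and an event-driven check.

For classical spike-pair and spike-triplet stimulation protocols (pairs of
presynaptic/postsynaptic spikes with delay Δt repeated with period T, n
times), the combined Hebbian + non-Hebbian rules admit closed-form
predictions of the total relative weight change, assuming the membrane
potential V and the decoded presynaptic rate r̂ are clamped constant.
With the lumped scale k = ε n |V − V_rev| / C (ms⁻¹):

    pre-before-post pairs:   Δw/w = k (e^{−Δt/τ}/r̂ − τ(1 − e^{−T/τ}))
    post-before-pre pairs:   Δw/w = k (e^{−(T−Δt)/τ}/r̂ − τ(1 − e^{−T/τ}))
    post-pre-post triplets:  Δw/w = k (e^{−Δt₂/τ}/r̂ − τ(2 − e^{−(Δt₁+Δt₂)/τ}))
    pre-post-pre triplets:   Δw/w = k (e^{−Δt₁/τ}/r̂ − τ)

The first (Hebbian) term is potentiating, the second (non-Hebbian,
integrated between consecutive postsynaptic spikes) depressive.  Results
are reported for an excitatory synapse with positive = LTP; the sign
prefix distinguishing synapse types is folded into k > 0.

``simulate_protocol`` applies the two rules event by event to explicit
spike trains at clamped V and r̂ — an independent route to the same
quantities that the closed forms must match in the small-ε regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ProtocolSpec",
    "ProtocolResult",
    "ProtocolError",
    "predict",
    "predict_pair_pre_post",
    "predict_pair_post_pre",
    "predict_triplet",
    "frequency_curve",
    "crossover_frequency",
    "simulate_protocol",
    "simulate_pair",
    "simulate_triplet",
    "PRESETS",
    "TRIPLET_DELAYS",
]

PAIR_PRE_POST = "pair_pre_post"
PAIR_POST_PRE = "pair_post_pre"
TRIPLET_POST_PRE_POST = "triplet_post_pre_post"
TRIPLET_PRE_POST_PRE = "triplet_pre_post_pre"

#: (Δt1, Δt2) grid of the standard triplet stimulation protocol (ms)
TRIPLET_DELAYS = [(5.0, 5.0), (5.0, 10.0), (5.0, 15.0),
                  (10.0, 5.0), (10.0, 10.0), (10.0, 15.0),
                  (15.0, 5.0), (15.0, 10.0), (15.0, 15.0)]


class ProtocolError(ValueError):
    pass


@dataclass(frozen=True)
class ProtocolSpec:
    """A spike-timing stimulation experiment.

    ``k`` is the lumped scale ε·n·|V − V_rev|/C in ms⁻¹; ``rhat`` the
    clamped decoded presynaptic rate in ms⁻¹; ``T`` the repetition
    period in ms; ``n`` the repetition count (already folded into k for
    the closed forms).
    """

    kind: str
    tau: float
    rhat: float
    k: float
    T: float = math.inf
    dt: float | None = None
    dt1: float | None = None
    dt2: float | None = None
    n: int = 60

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.rhat <= 0 or self.k <= 0:
            raise ProtocolError("tau, rhat and k must be positive")
        if self.kind in (PAIR_PRE_POST, PAIR_POST_PRE):
            if self.dt is None or not (0 < self.dt < self.T):
                raise ProtocolError("pair protocols need 0 < dt < T")
        elif self.kind in (TRIPLET_POST_PRE_POST, TRIPLET_PRE_POST_PRE):
            if self.dt1 is None or self.dt2 is None:
                raise ProtocolError("triplet protocols need dt1 and dt2")
            if self.dt1 <= 0 or self.dt2 <= 0 or \
                    self.dt1 + self.dt2 >= self.T:
                raise ProtocolError(
                    "triplet protocols need dt1, dt2 > 0 and dt1+dt2 < T"
                )
        else:
            raise ProtocolError(f"unknown protocol kind {self.kind!r}")


@dataclass(frozen=True)
class ProtocolResult:
    """Predicted relative weight change and its decomposition."""

    hebbian: float      # >= 0
    nonhebbian: float   # <= 0

    @property
    def total(self) -> float:
        return self.hebbian + self.nonhebbian


def predict_pair_pre_post(spec: ProtocolSpec) -> ProtocolResult:
    if spec.kind != PAIR_PRE_POST:
        raise ProtocolError(f"wrong kind {spec.kind!r}")
    tau = spec.tau
    heb = spec.k * math.exp(-spec.dt / tau) / spec.rhat
    dep = -spec.k * tau * (1.0 - math.exp(-spec.T / tau))
    return ProtocolResult(heb, dep)


def predict_pair_post_pre(spec: ProtocolSpec) -> ProtocolResult:
    if spec.kind != PAIR_POST_PRE:
        raise ProtocolError(f"wrong kind {spec.kind!r}")
    tau = spec.tau
    heb = spec.k * math.exp(-(spec.T - spec.dt) / tau) / spec.rhat
    dep = -spec.k * tau * (1.0 - math.exp(-spec.T / tau))
    return ProtocolResult(heb, dep)


def predict_triplet(spec: ProtocolSpec) -> ProtocolResult:
    tau = spec.tau
    if spec.kind == TRIPLET_POST_PRE_POST:
        heb = spec.k * math.exp(-spec.dt2 / tau) / spec.rhat
        dep = -spec.k * tau * (
            2.0 - math.exp(-(spec.dt1 + spec.dt2) / tau)
        )
    elif spec.kind == TRIPLET_PRE_POST_PRE:
        heb = spec.k * math.exp(-spec.dt1 / tau) / spec.rhat
        dep = -spec.k * tau
    else:
        raise ProtocolError(f"wrong kind {spec.kind!r}")
    return ProtocolResult(heb, dep)


_PREDICTORS = {
    PAIR_PRE_POST: predict_pair_pre_post,
    PAIR_POST_PRE: predict_pair_post_pre,
    TRIPLET_POST_PRE_POST: predict_triplet,
    TRIPLET_PRE_POST_PRE: predict_triplet,
}


def predict(spec: ProtocolSpec) -> ProtocolResult:
    return _PREDICTORS[spec.kind](spec)


def frequency_curve(
    dt: float,
    frequencies_hz,
    tau: float,
    rhat: float,
    k: float,
    ordering: str = PAIR_PRE_POST,
) -> list[ProtocolResult]:
    """Pair predictions with T = 1/f across a grid of pair frequencies."""
    out = []
    for f in np.atleast_1d(frequencies_hz):
        T = 1000.0 / float(f)  # Hz -> ms period
        if not dt < T:
            raise ProtocolError(
                f"frequency {f} Hz incompatible with dt={dt} ms"
            )
        spec = ProtocolSpec(kind=ordering, tau=tau, rhat=rhat, k=k,
                            T=T, dt=dt)
        out.append(predict(spec))
    return out


def crossover_frequency(
    dt: float, tau: float, rhat: float,
    f_lo: float = 1e-3, f_hi: float = 100.0,
    ordering: str = PAIR_PRE_POST,
) -> float | None:
    """Pair frequency (Hz) where LTD turns into LTP, or None.

    When r̂τ < e^{−Δt/τ} the Hebbian term dominates at every frequency —
    only LTP occurs and there is no transition.
    """
    def total_at(f_hz: float) -> float:
        T = 1000.0 / f_hz
        spec = ProtocolSpec(kind=ordering, tau=tau, rhat=rhat, k=1.0,
                            T=T, dt=dt)
        return predict(spec).total

    # the protocol needs dt < T, so the search cannot reach 1/dt
    f_hi = min(f_hi, 0.99 * 1000.0 / dt)
    lo, hi = total_at(f_lo), total_at(f_hi)
    if lo > 0 and hi > 0:
        return None
    if lo * hi > 0:
        return None
    return float(brentq(total_at, f_lo, f_hi, xtol=1e-9))


# ---------------------------------------------------------------------- #
# event-driven clamped-voltage simulator


def simulate_protocol(
    pre_times,
    post_times,
    *,
    tau: float,
    rhat: float,
    q: float,
    w0: float = 1.0,
    window: float | None = None,
):
    """Apply the plasticity rules event by event at clamped V and r̂.

    ``q`` = ε |V − V_rev| / C (ms⁻¹) is the per-event scale.  Hebbian:
    each presynaptic spike t_j pairs with the first postsynaptic spike
    t_i in (t_j, t_j + window] and multiplies the weight by
    1 + q e^{−(t_i−t_j)/τ}/r̂ when the window closes.  Non-Hebbian: each
    postsynaptic spike t_i multiplies by 1 − q τ(1 − e^{−(t_i−t_k)/τ}),
    the exponential accumulator integrated from the previous
    postsynaptic spike (from the train start before the first).
    Simultaneous pre and post spikes are ordered pre-first.

    Returns (times, weights): the weight value after every plasticity
    event, starting from ``w0``.
    """
    if window is None:
        window = 10.0 * tau
    pre_times = np.sort(np.asarray(pre_times, dtype=float))
    post_times = np.sort(np.asarray(post_times, dtype=float))
    # (time, priority, payload); pre before post on ties
    events: list[tuple[float, int, float]] = []
    events += [(t, 0, t) for t in pre_times]
    events += [(t, 1, t) for t in post_times]
    events.sort()
    # pair each pre with its first following post (pre-first tie-break)
    closes: list[tuple[float, float]] = []  # (close time, exp factor arg)
    for tj in pre_times:
        k = np.searchsorted(post_times, tj, side="left")
        if k < post_times.size:
            ti = post_times[k]
            if ti - tj <= window:
                closes.append((tj + window, ti - tj))
    all_events: list[tuple[float, int, float]] = []
    all_events += [(t, 1, float(t)) for t in post_times]      # non-Hebb
    all_events += [(tc, 2, float(dlt)) for tc, dlt in closes]  # Hebb applies
    all_events.sort()
    w = float(w0)
    t_prev_post = 0.0  # accumulator integrates from the train start
    ts: list[float] = []
    ws: list[float] = []
    for t, kind, payload in all_events:
        if kind == 1:
            isi = t - t_prev_post
            w *= 1.0 - q * tau * (1.0 - math.exp(-isi / tau))
            t_prev_post = t
        else:
            w *= 1.0 + q * math.exp(-payload / tau) / rhat
        ts.append(t)
        ws.append(w)
    return np.asarray(ts), np.asarray(ws)


def _train_for(spec: ProtocolSpec, reps: int) -> tuple[np.ndarray,
                                                       np.ndarray]:
    base = np.arange(reps) * spec.T
    if spec.kind == PAIR_PRE_POST:
        return base, base + spec.dt
    if spec.kind == PAIR_POST_PRE:
        return base + spec.dt, base
    if spec.kind == TRIPLET_POST_PRE_POST:
        pre = base + spec.dt1
        post = np.sort(np.concatenate((base, base + spec.dt1 + spec.dt2)))
        return pre, post
    if spec.kind == TRIPLET_PRE_POST_PRE:
        pre = np.sort(np.concatenate((base, base + spec.dt1 + spec.dt2)))
        post = base + spec.dt1
        return pre, post
    raise ProtocolError(spec.kind)


def simulate_total(spec: ProtocolSpec, *, q_total: float | None = None,
                   window: float | None = None) -> float:
    """Steady-state total relative change over n repetitions by event-driven
    simulation, normalised to the closed forms' lumped scale.

    ``q_total`` is the summed per-event scale n·q (defaults to ``spec.k``);
    the first repetitions are discarded (the closed forms assume steady
    state) by measuring the weight ratio between matching phase points.
    """
    if q_total is None:
        q_total = spec.k
    if window is None:
        window = 10.0 * spec.tau
    # lead-in repetitions so Hebbian window closes have reached steady
    # state before the measured stretch begins
    lead = int(math.ceil(window / spec.T)) + 2
    reps = spec.n + lead + 1
    q = q_total / spec.n
    pre, post = _train_for(spec, reps)
    ts, ws = simulate_protocol(pre, post, tau=spec.tau, rhat=spec.rhat,
                               q=q, window=window)
    # weight just before the start of each repetition
    marks = np.arange(reps) * spec.T
    w_at = np.empty(reps)
    for r, m in enumerate(marks):
        k = np.searchsorted(ts, m, side="left")
        w_at[r] = ws[k - 1] if k > 0 else 1.0
    return float(w_at[lead + spec.n] / w_at[lead] - 1.0)


def simulate_pair(spec: ProtocolSpec, **kw) -> float:
    if spec.kind not in (PAIR_PRE_POST, PAIR_POST_PRE):
        raise ProtocolError("pair protocol expected")
    return simulate_total(spec, **kw)


def simulate_triplet(spec: ProtocolSpec, **kw) -> float:
    if spec.kind not in (TRIPLET_POST_PRE_POST, TRIPLET_PRE_POST_PRE):
        raise ProtocolError("triplet protocol expected")
    return simulate_total(spec, **kw)


# ---------------------------------------------------------------------- #
# named parameter presets for the published comparison curves

PRESETS: dict[str, ProtocolSpec] = {
    # STDP pair-frequency experiments (visual cortex), Δt = 10 ms
    "fig4a_solid_prepost": ProtocolSpec(
        kind=PAIR_PRE_POST, tau=40.0, rhat=0.69 / 40.0, k=16.4,
        dt=10.0, T=100.0),
    "fig4a_solid_postpre": ProtocolSpec(
        kind=PAIR_POST_PRE, tau=40.0, rhat=0.56 / 40.0, k=16.4,
        dt=10.0, T=100.0),
    "fig4a_dashed_prepost": ProtocolSpec(
        kind=PAIR_PRE_POST, tau=57.8, rhat=0.88 / 57.8, k=14.6,
        dt=10.0, T=100.0),
    "fig4a_dashed_postpre": ProtocolSpec(
        kind=PAIR_POST_PRE, tau=20.0, rhat=0.25 / 20.0, k=21.0,
        dt=10.0, T=100.0),
    # induced-response stimulation-frequency experiment (CA1), Δt = 15 ms
    "fig4b_low": ProtocolSpec(
        kind=PAIR_PRE_POST, tau=20.0, rhat=0.49 / 20.0, k=4389.0,
        dt=15.0, T=100.0),
    "fig4b_mid": ProtocolSpec(
        kind=PAIR_PRE_POST, tau=20.0, rhat=0.54 / 20.0, k=4389.0,
        dt=15.0, T=100.0),
    "fig4b_high": ProtocolSpec(
        kind=PAIR_PRE_POST, tau=20.0, rhat=0.6 / 20.0, k=4389.0,
        dt=15.0, T=100.0),
    # spike-triplet experiments at 1 Hz
    "fig5_post_pre_post": ProtocolSpec(
        kind=TRIPLET_POST_PRE_POST, tau=50.0, rhat=0.05 / 50.0, k=0.41,
        dt1=10.0, dt2=10.0, T=1000.0),
    "fig5_pre_post_pre": ProtocolSpec(
        kind=TRIPLET_PRE_POST_PRE, tau=50.0, rhat=0.37 / 50.0, k=0.41,
        dt1=10.0, dt2=10.0, T=1000.0),
    # classical STDP shape, 60 pairs at 10 Hz
    "fig3_stdp": ProtocolSpec(
        kind=PAIR_PRE_POST, tau=20.0, rhat=0.425 / 20.0, k=1.0,
        dt=10.0, T=100.0),
}
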