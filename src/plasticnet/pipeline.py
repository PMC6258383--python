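"""End-to-end experiment orchestration.

Glue between the stimulus generator, network construction, simulation and
analysis: the desk-scale self-organisation experiment (learn on a
synthetic event-camera scene, then evaluate spiking statistics, E/I
balance and stimulus decoding before vs after learning) and the
feedforward rate-recovery experiment (Poisson presynaptic neurons whose
true rates the decoded rate r̂ must converge to).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import analysis
from .config import NetworkConfig, default_config
from .dynamics import RunResult, Simulator
from .network import (EXCITATORY, Network, PopulationSpec, SimConfig,
                      build_topology)
from .plasticity import configure_gamma
from .stimulus import SceneSpec, StimulusSpikes, events_to_spikes, \
    generate_events

logger = logging.getLogger(__name__)

__all__ = [
    "scene_for_scale",
    "stimulus_for",
    "SelfOrganisationResult",
    "self_organisation_experiment",
    "rate_recovery_experiment",
]


def scene_for_scale(cfg: NetworkConfig, duration_s: float,
                    seed: int) -> SceneSpec:
    """A juggling-like scene matched to the config's stimulus grid."""
    d = cfg.population("D")
    return SceneSpec(width=d.cols, height=d.rows, duration_s=duration_s,
                     seed=seed)


def stimulus_for(cfg: NetworkConfig, scene: SceneSpec) -> StimulusSpikes:
    d = cfg.population("D")
    stream = generate_events(scene)
    return events_to_spikes(stream, cfg.sim.dt, (d.rows, d.cols))


@dataclass
class SelfOrganisationResult:
    """Metrics of the learn-then-evaluate experiment."""

    rate_early_hz: float
    rate_late_hz: float
    cv_isi_late: float
    balance_pre: float          # median peak E/I current correlation
    balance_post: float
    balance_lag_post_ms: float  # median peak lag, + = inhibition trails
    decode_corr_pre: float      # mean decoded-frame correlation
    decode_corr_post: float
    learn_result: RunResult = field(repr=False, default=None)
    weights_initial: dict = field(repr=False, default=None)
    weights_final: dict = field(repr=False, default=None)
    network: Network = field(repr=False, default=None)


def _eval_run(
    cfg: NetworkConfig,
    net: Network,
    stim: StimulusSpikes,
    *,
    eval_s: float,
    seed: int,
    decode_times: tuple[float, ...],
    current_idx: np.ndarray,
) -> RunResult:
    sim = Simulator(net, seed=seed, learn=False)
    return sim.run(
        eval_s * 1000.0,
        stim,
        record_currents=(current_idx, 0.0, eval_s * 1000.0, 1),
        v_snapshot_times=decode_times,
    )


def self_organisation_experiment(
    scale: str = "desk",
    learn_s: float = 200.0,
    eval_s: float = 10.0,
    seed: int = 1,
    cfg: NetworkConfig | None = None,
) -> SelfOrganisationResult:
    """Learn on a synthetic scene, then compare before/after learning.

    The network starts from the published initial condition — very
    strong stimulus synapses, very weak recurrence — so the initial
    regime has high, stimulus-locked firing.  Learning should lower the
    excitatory rate, raise spiking irregularity above Poisson
    (CV_ISI > 1), tighten the excitation-inhibition correlation and
    improve decoding of the stimulus from the excitatory population.

    Evaluation runs (plasticity frozen) use the same stimulus segment
    and seed for the initial and the learned weights, so every
    before/after contrast is paired.
    """
    cfg = cfg or default_config(scale)
    scene = scene_for_scale(cfg, max(learn_s, eval_s), seed + 1)
    stim = stimulus_for(cfg, scene)
    net = cfg.build()
    w0 = {g.name: g.w.copy() for g in net.groups.values()}
    d = cfg.population("D")
    tau_m = cfg.sim.tau_m
    decode_times = tuple(np.arange(1000.0, eval_s * 1000.0, 250.0))
    n_e = net.topology.size("E")
    rng = np.random.default_rng(seed + 2)
    current_idx = np.sort(rng.choice(n_e, size=min(8, n_e), replace=False))

    def eval_metrics(run: RunResult) -> tuple[float, float, float]:
        bal = analysis.balance_metrics(run.current_t,
                                       run.current_exc, run.current_inh)
        trains = run.trains_for("E", n_e)
        decoded_t, frames = analysis.decode_stimulus(
            net.group("D", "E"), trains, run.v_snapshots, decode_times,
            (d.rows, d.cols), tau_m=tau_m, tau_A=cfg.sim.tau_A,
            C=cfg.sim.C)
        target = analysis.smeared_stimulus(stim.trains(), decode_times,
                                           (d.rows, d.cols), tau_m)
        corr = analysis.frame_correlations(frames, target)
        return (float(bal["peak_corr"].median()),
                float(bal["lag_ms"].median()),
                float(np.nanmean(corr)))

    # --- evaluation with the initial weights
    run_pre = _eval_run(cfg, net, stim, eval_s=eval_s, seed=seed + 10,
                        decode_times=decode_times, current_idx=current_idx)
    bal_pre, _, corr_pre = eval_metrics(run_pre)
    # --- learning
    sim = Simulator(net, seed=seed, learn=True)
    learn_run = sim.run(learn_s * 1000.0, stim)
    wF = {g.name: g.w.copy() for g in net.groups.values()}
    # --- evaluation with the learned weights (same stimulus, same seed)
    run_post = _eval_run(cfg, net, stim, eval_s=eval_s, seed=seed + 10,
                         decode_times=decode_times, current_idx=current_idx)
    bal_post, lag_post, corr_post = eval_metrics(run_post)
    # --- spiking statistics from the learning run
    t_e, idx_e = learn_run.spikes_for("E")
    early = t_e < 0.1 * learn_s * 1000.0
    late = t_e >= 0.9 * learn_s * 1000.0
    rate_early = early.sum() / n_e / (0.1 * learn_s)
    rate_late = late.sum() / n_e / (0.1 * learn_s)
    late_from = 0.5 * learn_s * 1000.0
    m = t_e >= late_from
    trains_late = _split_trains(t_e[m], idx_e[m], n_e)
    stats_late = analysis.spike_stats(trains_late,
                                      learn_s * 1000.0 - late_from)
    return SelfOrganisationResult(
        rate_early_hz=float(rate_early),
        rate_late_hz=float(rate_late),
        cv_isi_late=stats_late.mean_cv,
        balance_pre=bal_pre,
        balance_post=bal_post,
        balance_lag_post_ms=lag_post,
        decode_corr_pre=corr_pre,
        decode_corr_post=corr_post,
        learn_result=learn_run,
        weights_initial=w0,
        weights_final=wF,
        network=net,
    )


def _split_trains(t: np.ndarray, idx: np.ndarray,
                  n: int) -> list[np.ndarray]:
    order = np.argsort(idx, kind="stable")
    t, idx = t[order], idx[order]
    starts = np.searchsorted(idx, np.arange(n + 1))
    return [t[starts[k]:starts[k + 1]] for k in range(n)]


# ---------------------------------------------------------------------- #
# feedforward rate recovery


def _attach_background(sim: Simulator, spikes: StimulusSpikes,
                       weight: float) -> None:
    """Uniform, non-plastic excitatory background drive for a simulator."""
    sim.extra_drives.append((spikes, float(weight)))


def poisson_stimulus(rates_hz: np.ndarray, duration_ms: float, dt: float,
                     seed: int) -> StimulusSpikes:
    """Independent Poisson spike trains binned to simulation steps."""
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration_ms / dt))
    all_steps = []
    all_neuron = []
    for j, r in enumerate(rates_hz):
        lam = r * 1e-3  # spikes per ms
        n_exp = rng.poisson(lam * duration_ms)
        times = np.sort(rng.uniform(0, duration_ms, n_exp))
        steps = np.unique((times / dt).astype(np.int64))
        steps = steps[steps < n_steps]
        all_steps.append(steps)
        all_neuron.append(np.full(steps.size, j, dtype=np.int64))
    steps = np.concatenate(all_steps)
    neuron = np.concatenate(all_neuron)
    order = np.argsort(steps, kind="stable")
    steps, neuron = steps[order], neuron[order]
    indptr = np.searchsorted(steps, np.arange(n_steps + 1))
    return StimulusSpikes(n_steps=n_steps, indptr=indptr, neuron=neuron,
                          n_neurons=len(rates_hz), dt=dt)


def rate_recovery_experiment(
    duration_s: float = 300.0,
    seed: int = 1,
    n_pre: int = 20,
    n_post: int = 50,
    rate_lo_hz: float = 2.0,
    rate_hi_hz: float = 20.0,
    target_post_rate_hz: float = 8.0,
    epsilon: float = 2e-6,
    w_init: float = 3e-2,
    p_noise_post: float = 0.75,
    background_n: int = 0,
    background_rate_hz: float = 10.0,
    background_w: float = 0.0,
    stimulus_fraction: float = 1.0,
    average_from_s: float | None = None,
) -> dict:
    """Feedforward toy: does the decoded rate learn the true rates?

    Poisson presynaptic neurons at fixed rates drive LIF targets
    through plastic synapses; γ comes from the stability condition with
    the stimulus as the (default) sole source, the initial weights are
    strong enough that targets spike from the outset (the Hebbian rule
    cannot bootstrap a silent population), and the published excitatory
    learning noise (p_noise = 0.75) regularises the decoder.  After
    learning, the time-averaged decoded rate r̂_j — the decode path
    evaluated at regular times over the second half of the run — should
    approximate each presynaptic neuron's true rate: the fixed point
    r̂ = r of the combined plasticity rules.

    The average of r̂_j sampled at j's own spike times is returned as a
    diagnostic: it systematically exceeds the marginal rate, because
    the learned decode is the posterior rate given the subsequent
    postsynaptic window, and conditioning on an actual spike selects
    windows that reflect it (see the methods note).

    An optional non-plastic Poisson background drive is available for
    exploring asynchronous-target regimes (off by default).

    Returns per-neuron true rates and time-averaged decoded rates (Hz).
    """
    rates = np.linspace(rate_lo_hz, rate_hi_hz, n_pre)
    sim_cfg = SimConfig(seed=seed)
    # lattices tiling the same plane, radius covering everything
    plane = 10.0
    pops = [
        PopulationSpec("D", 4, 5, plane / 5, EXCITATORY, 0.0, 0.0),
        PopulationSpec("E", 5, 10, plane / 10, EXCITATORY, 0.0,
                       p_noise_post),
    ]
    topo = build_topology(pops, radius=1000.0)
    s_D = rates.sum()
    s_E = n_post * target_post_rate_hz
    rhat_mean_ms = float((rates ** 2).sum() / rates.sum()) * 1e-3
    gamma = configure_gamma(
        {"D": rhat_mean_ms}, {"D": s_D, "E": s_E},
        {"D": stimulus_fraction}, sim_cfg.V_s, post_pops=("E",),
        external_fraction=1.0 - stimulus_fraction)[("D", "E")]
    net = Network(topo, sim_cfg, {
        ("D", "E"): {"gamma": gamma, "epsilon": epsilon, "w_init": w_init},
    })
    stim = poisson_stimulus(rates, duration_s * 1000.0, sim_cfg.dt,
                            seed + 1)
    sim = Simulator(net, seed=seed, learn=True)
    if background_n > 0 and background_w > 0:
        bg = poisson_stimulus(
            np.full(background_n, background_rate_hz),
            duration_s * 1000.0, sim_cfg.dt, seed + 2)
        _attach_background(sim, bg, background_w)
    if average_from_s is None:
        average_from_s = duration_s / 2.0
    decode_times = tuple(
        np.arange(average_from_s * 1000.0 + 500.0,
                  duration_s * 1000.0 - sim_cfg.tau_A, 500.0))
    run = sim.run(duration_s * 1000.0, stim, record_rhat=("DE",),
                  v_snapshot_times=decode_times)
    # time-averaged decoded rate: the decode path evaluated at regular
    # times (r̂ can be computed at any t, independent of presynaptic
    # activity), using the learning-visible postsynaptic spikes
    from .plasticity import decode_population_rate

    off = run.offsets["E"]
    m_e = run.spike_idx >= off
    t_vis = run.spike_t[m_e][run.spike_visible[m_e]]
    i_vis = run.spike_idx[m_e][run.spike_visible[m_e]] - off
    vis_trains = [np.sort(t_vis[i_vis == j]) for j in range(n_post)]
    g = net.group("D", "E")
    acc = np.zeros(n_pre)
    for t in decode_times:
        acc += decode_population_rate(
            g, vis_trains, run.v_snapshots[float(t)], float(t),
            tau_m=sim_cfg.tau_m, tau_A=sim_cfg.tau_A, C=sim_cfg.C)
    rhat_uncond_hz = acc / len(decode_times) * 1000.0
    # diagnostic: average of r̂ at the presynaptic spike times (carries
    # the posterior-conditioning excess; see methods)
    log = np.array(run.rhat_log["DE"], dtype=float)  # (t, j, rhat)
    m = log[:, 0] >= average_from_s * 1000.0
    rhat_spike_hz = np.full(n_pre, np.nan)
    for j in range(n_pre):
        sel = m & (log[:, 1] == j)
        if sel.any():
            rhat_spike_hz[j] = log[sel, 2].mean() * 1000.0
    return {
        "true_rates_hz": rates,
        "rhat_hz": rhat_uncond_hz,
        "rhat_spike_hz": rhat_spike_hz,
        "gamma": gamma,
        "run": run,
        "network": net,
    }
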