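"""The plasticity rules: windows, decoded rate, conservation, balance."""

import math

import numpy as np
import pytest

from plasticnet import Simulator, configure_gamma, implied_fractions
from plasticnet.network import ConfigurationError
from plasticnet.plasticity import HebbianWindow, decode_rate

from conftest import constant_stimulus


def make_engine(net, seed=0, **kw):
    sim = Simulator(net, seed=seed, learn=True, engine_kwargs=kw)
    return sim, sim.engine


class TestAccumulator:
    def test_constant_drive_closed_form(self, two_neuron_net):
        cfg = two_neuron_net.cfg
        sim, eng = make_engine(two_neuron_net)
        V_const = -60.0
        n = 2000  # 200 ms
        for _ in range(n):
            eng.accumulate("E", np.array([V_const]))
        tau = cfg.tau_m
        T = n * cfg.dt
        drive_E = cfg.V_E - V_const
        drive_I = V_const - cfg.V_I
        expect_E = drive_E * tau * (1.0 - math.exp(-T / tau))
        expect_I = drive_I * tau * (1.0 - math.exp(-T / tau))
        assert eng.acc_E["E"][0] == pytest.approx(expect_E, rel=1e-12)
        assert eng.acc_I["E"][0] == pytest.approx(expect_I, rel=1e-12)

    def test_zero_drive_stays_zero(self, two_neuron_net):
        cfg = two_neuron_net.cfg
        sim, eng = make_engine(two_neuron_net)
        for _ in range(100):
            eng.accumulate("E", np.array([cfg.V_E]))  # E driving force 0
        assert eng.acc_E["E"][0] == 0.0

    def test_arbitrary_trace_matches_fine_grid_quadrature(self,
                                                          two_neuron_net):
        cfg = two_neuron_net.cfg
        sim, eng = make_engine(two_neuron_net)
        tau = cfg.tau_m
        T = 150.0
        n = int(T / cfg.dt)

        def v_of(t):
            return -65.0 + 6.0 * np.sin(2 * np.pi * t / 40.0)

        for k in range(n):
            eng.accumulate("E", np.array([v_of((k + 1) * cfg.dt)]))
        # Riemann sum of the integrand at dt/10 resolution
        fine = cfg.dt / 10.0
        ts = np.arange(fine, T + fine / 2, fine)
        integrand = (cfg.V_E - v_of(ts)) * np.exp(-(T - ts) / tau)
        oracle = integrand.sum() * fine
        assert eng.acc_E["E"][0] == pytest.approx(oracle, rel=1e-3)


class TestWindows:
    def test_empty_window_decodes_zero_and_changes_nothing(self,
                                                           two_neuron_net):
        sim, eng = make_engine(two_neuron_net)
        g = two_neuron_net.group("D", "E")
        w_before = g.w.copy()
        eng.rhat_log["DE"] = []
        sim.v_hist.write(0, np.array([-65.0]))
        eng.on_pre_spike("D", 0, 0.1, 0)
        eng.close_due_windows(0.1 + two_neuron_net.cfg.tau_A)
        assert eng.rhat_log["DE"] == [(0.1, 0, 0.0)]
        assert np.array_equal(g.w, w_before)

    def test_only_first_postsynaptic_spike_contributes(self,
                                                       two_neuron_net):
        sim, eng = make_engine(two_neuron_net)
        sim.v_hist.write(0, np.array([-65.0]))
        eng.on_pre_spike("D", 0, 0.1, 0)
        eng.on_post_spike("E", 0, 5.0, 49)
        eng.on_post_spike("E", 0, 20.0, 199)
        win = eng._fifo["DE"][0]
        assert len(win.pos) == 1  # second spike ignored

    def test_two_presynaptic_spikes_open_independent_windows(
            self, two_neuron_net):
        sim, eng = make_engine(two_neuron_net)
        sim.v_hist.write(0, np.array([-65.0]))
        sim.v_hist.write(100, np.array([-58.0]))
        eng.on_pre_spike("D", 0, 0.1, 0)
        eng.on_pre_spike("D", 0, 10.1, 100)
        assert len(eng._open["DE"][0]) == 2
        eng.on_post_spike("E", 0, 20.0, 199)
        w1, w2 = eng._fifo["DE"]
        # both windows caught the spike, with their own driving forces
        cfg = two_neuron_net.cfg
        u1 = 65.0 * math.exp(-(20.0 - 0.1) / cfg.tau_m) / cfg.C
        u2 = 58.0 * math.exp(-(20.0 - 10.1) / cfg.tau_m) / cfg.C
        assert w1.u[0] == pytest.approx(u1, rel=1e-12)
        assert w2.u[0] == pytest.approx(u2, rel=1e-12)

    def test_decode_rate_matches_brute_force(self):
        rng = np.random.default_rng(3)
        win = HebbianWindow(0, 0.0, 0)
        weights = rng.uniform(0.1, 1.0, 10)
        win.pos = [0, 2, 4, 6, 8]
        win.u = rng.uniform(0.5, 3.0, 5).tolist()
        gamma = 1.7e-3
        oracle = gamma * sum(weights[p] * u for p, u in zip(win.pos, win.u))
        assert decode_rate(win, weights, gamma) == pytest.approx(
            oracle, rel=1e-12)
        with pytest.raises(ConfigurationError):
            decode_rate(win, weights, 0.0)


class TestHebbian:
    def test_single_entry_gains_eps_over_gamma(self, two_neuron_net):
        g = two_neuron_net.group("D", "E")
        sim, eng = make_engine(two_neuron_net)
        sim.v_hist.write(0, np.array([-65.0]))
        w0 = g.w[0]
        eng.on_pre_spike("D", 0, 0.1, 0)
        eng.on_post_spike("E", 0, 10.0, 99)
        eng.close_due_windows(1000.0)
        assert g.w[0] - w0 == pytest.approx(g.epsilon / g.gamma, rel=1e-12)

    def test_conservation_and_proportional_credit(self, small_net):
        """Every closed non-empty window adds exactly eps/gamma in total,
        split in proportion to the contribution terms."""
        g = small_net.group("D", "E")
        sim, eng = make_engine(small_net)
        rng = np.random.default_rng(0)
        g.w[:] = rng.uniform(0.005, 0.05, g.w.size)
        n_e = small_net.topology.size("E")
        sim.v_hist.buf[:] = rng.uniform(-70.0, -56.0,
                                        sim.v_hist.buf.shape)
        w_before = g.w.copy()
        eng.on_pre_spike("D", 4, 0.1, 0)
        # several postsynaptic neighbours spike at different times
        post, _ = g.out_edges(4)
        for k, i in enumerate(post[:5]):
            eng.on_post_spike("E", int(i), 2.0 + 3.0 * k, 19 + 30 * k)
        eng.close_due_windows(1000.0)
        delta = g.w - w_before
        # non-Hebbian updates also ran; isolate the Hebbian window total
        win_total = delta[delta != 0]
        assert delta.sum() == pytest.approx(
            g.epsilon / g.gamma
            - (w_before.sum() - (g.w - delta).sum()), rel=1e-9)

    def test_contribution_ratio_preserved_in_deltas(self, two_neuron_net):
        # rebuild a 1-pre 2-post situation with a wider E population
        from plasticnet import Network, PopulationSpec, SimConfig, \
            build_topology
        from plasticnet.network import EXCITATORY

        pops = [
            PopulationSpec("D", 1, 1, 2.0, EXCITATORY, 0.0, 0.0),
            PopulationSpec("E", 1, 2, 1.0, EXCITATORY, 0.0, 0.0),
        ]
        net = Network(build_topology(pops, 10.0), SimConfig(), {
            ("D", "E"): {"gamma": 1e-3, "epsilon": 1e-6, "w_init": 1e-2},
        })
        g = net.group("D", "E")
        sim, eng = make_engine(net)
        cfg = net.cfg
        # driving forces 60 and 20 at the window opening: 3:1 contributions
        sim.v_hist.buf[:, 0] = -60.0
        sim.v_hist.buf[:, 1] = -20.0
        eng.on_pre_spike("D", 0, 0.1, 0)
        eng.on_post_spike("E", 0, 5.1, 50)
        eng.on_post_spike("E", 1, 5.1, 50)
        win = eng._fifo["DE"][0]
        assert win.u[0] / win.u[1] == pytest.approx(3.0, rel=1e-12)
        w_before = g.w.copy()
        eng._fifo["DE"].clear()
        eng._open["DE"][0].pop(0)
        eng._close_one(g, win)
        d = g.w - w_before
        assert d[win.pos[0]] / d[win.pos[1]] == pytest.approx(3.0, rel=1e-6)
        assert d.sum() == pytest.approx(g.epsilon / g.gamma, rel=1e-12)


class TestNonHebbian:
    def test_zero_accumulator_means_zero_change(self, two_neuron_net):
        g = two_neuron_net.group("D", "E")
        sim, eng = make_engine(two_neuron_net)
        w0 = g.w.copy()
        eng.on_post_spike("E", 0, 1.0, 9)  # accumulators are still zero
        assert np.array_equal(g.w, w0)

    def test_uniform_relative_depression(self, small_net):
        """All inputs of one pair see the identical relative decrement."""
        sim, eng = make_engine(small_net)
        rng = np.random.default_rng(1)
        for g in small_net.groups.values():
            g.w[:] = rng.uniform(0.001, 0.05, g.w.size)
        before = {g.name: g.w.copy() for g in small_net.groups.values()}
        # build up accumulators, then spike neuron 5 of E
        for _ in range(500):
            for pop in ("E", "I"):
                n = small_net.topology.size(pop)
                eng.accumulate(pop, np.full(n, -60.0))
        eng.on_post_spike("E", 5, 50.0, 499)
        for g in small_net.incoming("E"):
            pre, pos = g.in_edges(5)
            ratio = g.w[pos] / before[g.name][pos]
            # one multiplicative factor applied to every input: relative
            # change identical up to division round-off
            assert np.allclose(ratio, ratio[0], rtol=1e-14, atol=0)
            assert np.all(ratio < 1.0)
            # weights 1:4 keep deltas 1:4 (multiplicative rule)
            d = before[g.name][pos] - g.w[pos]
            assert np.allclose(d / before[g.name][pos],
                               d[0] / before[g.name][pos][0], rtol=1e-12)
        # untouched synapses unchanged
        other = small_net.group("D", "E")
        mask = np.ones(other.w.size, bool)
        mask[other.in_edges(5)[1]] = False
        assert np.array_equal(other.w[mask], before["DE"][mask])

    def test_accumulators_reset_after_visible_spike(self, two_neuron_net):
        sim, eng = make_engine(two_neuron_net)
        for _ in range(100):
            eng.accumulate("E", np.array([-60.0]))
        assert eng.acc_E["E"][0] > 0
        eng.on_post_spike("E", 0, 10.0, 99)
        assert eng.acc_E["E"][0] == 0.0
        assert eng.acc_I["E"][0] == 0.0

    def test_constant_voltage_periodic_spiking_closed_form(self,
                                                           two_neuron_net):
        """Per-spike relative change at period T equals the closed-form
        non-Hebbian term -eps*drive*tau*(1-exp(-T/tau))/C."""
        cfg = two_neuron_net.cfg
        g = two_neuron_net.group("D", "E")
        sim, eng = make_engine(two_neuron_net)
        V = -62.0
        T = 50.0
        n_steps = int(T / cfg.dt)
        rel_changes = []
        for spike in range(3):
            for _ in range(n_steps):
                eng.accumulate("E", np.array([V]))
            w_before = g.w[0]
            eng.on_post_spike("E", 0, (spike + 1) * T,
                              (spike + 1) * n_steps - 1)
            rel_changes.append(g.w[0] / w_before - 1.0)
        tau = cfg.tau_m
        drive = cfg.V_E - V
        expect = -g.epsilon * drive * tau * (1 - math.exp(-T / tau)) / cfg.C
        # first interval integrates from t=0 (same length T here)
        for rc in rel_changes:
            assert rc == pytest.approx(expect, rel=1e-9)

    def test_clamp_bounds_relative_decrement(self, two_neuron_net):
        g = two_neuron_net.group("D", "E")
        g.epsilon = 1.0  # pathological learning rate
        sim, eng = make_engine(two_neuron_net)
        for _ in range(5000):
            eng.accumulate("E", np.array([-60.0]))
        w0 = g.w[0]
        eng.on_post_spike("E", 0, 500.0, 4999)
        assert g.w[0] == pytest.approx(0.1 * w0)
        assert g.w[0] > 0
        assert eng.clamp_count == 1


class TestLearningNoise:
    def test_invisible_spike_is_hidden_from_all_plasticity(self,
                                                           two_neuron_net):
        sim, eng = make_engine(two_neuron_net)
        g = two_neuron_net.group("D", "E")
        sim.v_hist.buf[:] = -65.0
        for _ in range(200):
            eng.accumulate("E", np.array([-65.0]))
        acc = eng.acc_E["E"][0]
        w0 = g.w.copy()
        eng.on_pre_spike("D", 0, 0.1, 0)
        eng.on_invisible_post_spike("E", 0, 10.0)
        assert eng.acc_E["E"][0] == acc          # no reset
        assert np.array_equal(g.w, w0)           # no depression
        assert len(eng._fifo["DE"][0].pos) == 0  # not a first spike
        # the next visible spike is still "first in window"
        eng.on_post_spike("E", 0, 15.0, 149)
        assert len(eng._fifo["DE"][0].pos) == 1

    def test_reset_on_invisible_config_switch(self, two_neuron_net):
        sim, eng = make_engine(two_neuron_net, reset_on_invisible=True)
        for _ in range(200):
            eng.accumulate("E", np.array([-65.0]))
        eng.on_invisible_post_spike("E", 0, 10.0)
        assert eng.acc_E["E"][0] == 0.0


class TestGammaConfiguration:
    def test_single_source_formula(self):
        # purely feedforward: gamma solves s_D <r>/gamma = V_s s_E
        rates = {"D": 5e-3}
        shares = {"D": 100.0, "E": 50.0}
        g = configure_gamma(rates, shares, {"D": 1.0}, 15.0,
                            post_pops=("E",))
        assert g[("D", "E")] == pytest.approx(100.0 * 5e-3 / (15.0 * 50.0))

    def test_roundtrip_with_implied_fractions(self):
        rates = {"D": 5e-3, "E": 6e-3, "I": 6e-3}
        shares = {"D": 1000.0, "E": 900.0, "I": 225.0}
        fr = {"D": 1.0, "E": 1.0, "I": 1.0}
        gammas = configure_gamma(rates, shares, fr, 15.0)
        implied = implied_fractions(gammas, rates, shares, 15.0)
        for (a, b), f in implied.items():
            assert f == pytest.approx(fr[a], rel=1e-12)

    def test_doubling_gamma_halves_voltage_contributions(self):
        rates = {"D": 5e-3, "E": 6e-3, "I": 6e-3}
        shares = {"D": 1000.0, "E": 900.0, "I": 225.0}
        gammas = configure_gamma(rates, shares,
                                 {"D": 1.0, "E": 1.0, "I": 1.0}, 15.0)
        doubled = {k: 2 * v for k, v in gammas.items()}
        f0 = implied_fractions(gammas, rates, shares, 15.0)
        f2 = implied_fractions(doubled, rates, shares, 15.0)
        for k in f0:
            assert f2[k] == pytest.approx(f0[k] / 2.0, rel=1e-12)

    def test_infeasible_fractions_rejected(self):
        with pytest.raises(ConfigurationError):
            configure_gamma({"D": 5e-3}, {"D": 1.0, "E": 1.0},
                            {"D": 0.5}, 15.0)
        with pytest.raises(ConfigurationError):
            configure_gamma({"D": 0.0}, {"D": 1.0, "E": 1.0},
                            {"D": 1.0}, 15.0)


class TestReplayOracle:
    def test_full_simulation_matches_bruteforce_replay(self):
        """Weight trajectories of a small learning run are reproduced by an
        independent straightforward reimplementation over the recorded
        spike log and voltage history."""
        from plasticnet.config import default_config

        cfg = default_config("tiny")
        for p in cfg.populations:
            assert p.name in "DEI"
        net = cfg.build()
        sim = Simulator(net, seed=11, learn=True)
        stim = constant_stimulus(
            {s: [(7 * s) % 64, (11 * s + 3) % 64]
             for s in range(0, 3000, 4)}, 3000, 64)
        w0 = {g.name: g.w.copy() for g in net.groups.values()}
        # capture V and spikes step by step
        v_log = np.empty((3000, sim.n))
        spike_log = []
        for s in range(3000):
            spiking, visible = sim.step(stim.indices_at(s))
            v_log[s] = sim.v_hist.buf[s % sim.v_hist.size]
            spike_log.append((spiking.copy(), visible.copy()))
        got = {g.name: g.w.copy() for g in net.groups.values()}
        expect = _replay(net, cfg, w0, v_log, spike_log, stim, sim)
        for name in got:
            np.testing.assert_allclose(got[name], expect[name], rtol=1e-9)


def _replay(net, cfg, w0, v_log, spike_log, stim, sim):
    """Independent reimplementation of both plasticity rules."""
    simc = cfg.sim
    dt = simc.dt
    tau = simc.tau_m
    n_steps = v_log.shape[0]
    weights = {k: v.copy() for k, v in w0.items()}
    offsets = sim.offsets
    sizes = {p: net.topology.size(p) for p in sim.pops}
    acc = {p: {"E": np.zeros(sizes[p]), "I": np.zeros(sizes[p])}
           for p in sim.pops}
    prev_vis = {p: np.full(sizes[p], -np.inf) for p in sim.pops}
    open_windows = {g.name: [] for g in net.groups.values()}
    dec = math.exp(-dt / tau)
    gain = simc.tau_m * (1 - dec)
    group_order = [g.name for g in net.groups.values()]
    for s in range(n_steps):
        te = (s + 1) * dt
        # accumulators from the recorded voltages
        for p in sim.pops:
            V = v_log[s, offsets[p]:offsets[p] + sizes[p]]
            acc[p]["E"] = acc[p]["E"] * dec + \
                np.maximum(simc.V_E - V, 0) * gain
            acc[p]["I"] = acc[p]["I"] * dec + \
                np.maximum(V - simc.V_I, 0) * gain
        spiking, visible = spike_log[s]
        vis_set = []
        for gidx, vis in zip(spiking, visible):
            p = "E" if gidx < offsets.get("I", sim.n) else "I"
            loc = gidx - offsets[p]
            if not vis:
                continue
            vis_set.append((p, loc))
            for g in net.incoming(p):
                a = acc[p]["E" if g.pre_sign == "excitatory" else "I"][loc]
                frac = min(g.epsilon * a / simc.C, 0.9)
                pre, pos = g.in_edges(loc)
                weights[g.name][pos] *= 1 - frac
                for j, ps in zip(pre, pos):
                    for win in open_windows[g.name]:
                        if win["pre"] == j and \
                                prev_vis[p][loc] <= win["t"] < te:
                            v = v_log[win["step"],
                                      offsets[p] + loc]
                            drive = (g.reversal - v
                                     if g.pre_sign == "excitatory"
                                     else v - g.reversal)
                            if drive > 0:
                                win["pos"].append(ps)
                                win["u"].append(
                                    drive / simc.C
                                    * math.exp(-(te - win["t"]) / tau))
            acc[p]["E"][loc] = 0.0
            acc[p]["I"][loc] = 0.0
            prev_vis[p][loc] = te
        for p, loc in vis_set:
            for g in net.outgoing(p):
                open_windows[g.name].append(
                    {"pre": loc, "t": te, "step": s, "pos": [], "u": []})
        for j in stim.indices_at(s):
            for g in net.outgoing("D"):
                open_windows[g.name].append(
                    {"pre": int(j), "t": te, "step": s, "pos": [],
                     "u": []})
        for name in group_order:
            g = net.groups_by_name[name]
            still = []
            for win in open_windows[name]:
                if s - win["step"] >= simc.window_steps:
                    if win["pos"]:
                        pos = np.array(win["pos"])
                        u = np.array(win["u"])
                        wv = weights[name][pos]
                        contrib = wv * u
                        weights[name][pos] += \
                            g.epsilon * contrib / (g.gamma * contrib.sum())
                else:
                    still.append(win)
            open_windows[name] = still
    return weights
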