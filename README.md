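# plasticnet

Simulation and analysis of **function-derived synaptic plasticity** in
conductance-based spiking networks.

Most plasticity models are fitted to experiments (STDP curves, frequency
dependence, triplets) and then combined ad hoc. Here both the Hebbian and
the homeostatic (non-Hebbian) rule follow from a single objective: the
network acts as a *recurrent autoencoder*, in which each presynaptic
neuron *j* learns to make its own instantaneous firing rate decodable
from the activity of its postsynaptic neurons,

```
r̂_j(t) = γ Σ_i  (w_ij / C) (V_i(t) − V_rev) e^{−(t_i − t)/τ}
```

where *t_i* is postsynaptic neuron *i*'s **first** spike in the window
(t, t + τ_A], the driving force (V_i − V_rev) is sampled at *t*, τ is the
membrane time constant, and γ converts summed voltage contributions into
a rate. Learning drives r̂ toward the true presynaptic rate through two
complementary updates:

* **Hebbian (LTP), per presynaptic spike**:
  Δw_ij = ε w_ij (V_i − V_rev) e^{−(t_i−t_j)/τ} / (C r̂_j) — credit
  proportional to each postsynaptic neuron's contribution; every window
  adds exactly ε/γ of total weight across its targets.
* **non-Hebbian (LTD), per postsynaptic spike**:
  Δw_ij = −(ε w_ij / C) ∫_{t_k}^{t_i} (V_i − V_rev) e^{−(t_i−t')/τ} dt' —
  a multiplicative, heterosynaptic scaling of *all* inputs, integrated
  since the previous postsynaptic spike.

Their balance has a stable fixed point at r̂ = r. Under clamped membrane
potential the combination reproduces classical STDP, its pairing-frequency
dependence and its BCM-like sliding threshold, and spike-triplet results
in closed form; embedded in a spatial spiking circuit driven by an
event-camera stimulus it self-organises balanced excitation/inhibition,
irregular spiking, log-normal-like weights and receptive fields, while
the stimulus stays decodable from the population activity.

The package provides:

* `plasticnet.network` / `plasticnet.config` — spatial populations
  (stimulus D, excitatory E, inhibitory I on one plane), radius-based
  connectivity, the published parameter set and reduced-scale presets;
* `plasticnet.dynamics` — conductance-based leaky integrate-and-fire
  integration (difference-of-exponentials synapses, exact synaptic
  decay, exponential-Euler membrane update, refractoriness, checkpoints);
* `plasticnet.plasticity` — the decoded rate, both plasticity rules,
  learning-noise gating, and the γ stability/balance configurator;
* `plasticnet.protocols` — closed-form pair/triplet/frequency
  predictions plus an independent event-driven protocol simulator;
* `plasticnet.stimulus` — synthetic event-camera (DVS-style) streams
  with 1 µs timestamps and a 15 µs per-pixel dead time;
* `plasticnet.analysis` — CV/Fano spike statistics, E/I current
  cross-correlation, weight/receptive-field analysis, stimulus decoding;
* a `plasticnet` CLI: `simulate`, `protocol`, `generate-stimulus`,
  `analyze`, `decode`.

## Worked example

Closed-form STDP predictions at the classic 60-pairs-at-10-Hz protocol
(τ = 20 ms, r̂ = 0.425/τ):

```pycon
>>> from plasticnet.protocols import ProtocolSpec, predict
>>> spec = ProtocolSpec(kind="pair_pre_post", tau=20.0, rhat=0.425/20,
...                     k=1.0, dt=10.0, T=100.0)
>>> r = predict(spec)
>>> round(r.hebbian, 3), round(r.nonhebbian, 3), round(r.total, 3)
(28.54, -19.866, 8.674)
```

A positive combined change: potentiation for pre-before-post pairing at
10 ms delay. Shifting to post-before-pre (delay 10 ms) flips the sign:

```pycon
>>> spec = ProtocolSpec(kind="pair_post_pre", tau=20.0, rhat=0.425/20,
...                     k=1.0, dt=10.0, T=100.0)
>>> round(predict(spec).total, 3)
-19.336
```

A desk-scale network run from the shell:

```sh
$ plasticnet simulate --scale tiny --duration-s 1 --seed 1 --out run1
spikes: 966
wrote run1/run.h5 and run1/weights.h5
$ plasticnet analyze --spikes run1/run.h5 --report run1/report
{
  "E": {
    "mean_rate_hz": 7.78,
    "mean_cv_isi": 0.54,
    "min_isi_ms": 7.5
  },
  ...
}
```

Per population: the mean firing rate, the mean CV of the interspike
intervals (low here — one second of a tiny stimulus-locked network), and
the minimum ISI, which can never undercut the 5 ms refractory period.

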