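# Methods

## Model

**Neurons.** Excitatory (E) and inhibitory (I) populations are
conductance-based leaky integrate-and-fire neurons,

C dV/dt = −g_L(V−V_L) − g^E(V−V_E) − g^I(V−V_I),

with C = 1 nF, g_L = 50 nS, V_L = −70 mV, V_E = 0 mV, V_I = −80 mV,
threshold −55 mV, reset −70 mV, refractory period 5 ms. Synaptic
conductances follow normalised difference-of-exponentials kernels
(rise 0.5 ms; decay 2 ms excitatory, 7 ms inhibitory), implemented with
two exponential accumulators per synapse type so the kernel shape is
exact regardless of step size. A stimulus population (D) injects
externally defined spikes and receives none.

**Geometry.** All populations overlay one square plane of grid units
(300×300 at full scale). E sits on a unit lattice, I on a double-spaced
lattice, D on a lattice scaled to cover the plane (128×128 at full
scale). Every neuron connects bidirectionally to all neurons of any
population within a Euclidean radius (15 grid units at full scale;
boundary ties included), except that nothing projects onto D and
distance-zero self-connections are excluded (an autapse would make the
decoded-rate normalisation degenerate). No periodic boundaries: border
neurons simply have fewer neighbours.

**Plasticity.** See the README for the decoded rate r̂ and the two
rules. Implementation semantics that the equations do not fix:

* A presynaptic spike's window closes τ_A = 140 ms after it opens; the
  Hebbian update is applied at close time using the weights current at
  that moment. Driving forces are sampled at the window's opening from
  a rolling voltage history (pre-reset values).
* "First spike" bookkeeping is O(1): a postsynaptic spike at t_i is the
  first in window (t_j, t_j+τ_A] iff the neuron's previous
  learning-visible spike was at or before t_j. Overlapping windows from
  different presynaptic spikes are independent; one postsynaptic spike
  may be first in many windows.
* Contributions use the unsigned driving force (V_E − V_i for
  excitatory, V_i − V_I for inhibitory synapses), which is what the
  sign prefixes in the rules accomplish; r̂ is therefore non-negative.
* The non-Hebbian accumulator integrates dα/dt = drive − α/τ exactly
  per step (piecewise-constant drive); it starts at 0 at simulation
  start, standing in for the undefined "previous spike" before a
  neuron's first spike, and resets on each learning-visible spike.
* τ in all plasticity formulas is the resting membrane constant
  C/g_L = 20 ms, even though the effective time constant under
  conductance load is shorter.
* Learning noise: each spike is hidden from learning with probability
  p_noise (0 for D, 0.75 for E, 0.5 for I). A hidden spike propagates
  normally but opens no window, never counts as a first spike, triggers
  no depression and does not reset the accumulator (a config switch can
  re-enable the reset; nothing in the model fixes this choice).
* Because the depression is multiplicative, a pathological accumulator
  could zero a weight in one event; single-event relative decrements
  are clamped at 90% and counted. Weights therefore stay positive.

**γ configuration.** Stability requires that, per target spike, the
summed voltage contributions of all sources equal the reset-to-threshold
voltage V_s = 15 mV. `configure_gamma` assigns each source population a
fraction f of V_s (feasibility: f_D + f_E − f_I = 1) and solves
γ^{αβ} = s_α⟨r^α⟩/(f_α V_s s_β) with s the expected spike-count shares.
The full-scale parameter table is used verbatim at the `paper` scale;
one printed γ exponent is typographically ambiguous (γ^IE as 2.78×10⁻⁴
vs 10⁻³); the smaller reading is the default and the other is a plain
config override.

## Numerical scheme

The membrane equation is advanced with **exponential Euler** at
Δt = 0.1 ms: V ← V∞ + (V − V∞)e^{−Δt g_tot/C} with g_tot and V∞ the
instantaneous total conductance and its reversal-weighted equilibrium.
This is exact for the leak-only case (passive decay matches the closed
form to machine precision), unconditionally stable, and confines V to
[V_I, V_E] by construction. Spikes are detected at step ends, delivered
to targets one step later (the synaptic kernel is zero at t = 0, so no
charge is lost), and reset/refractory clamping holds V at the reset
potential while conductances keep evolving (conductances are
membrane-independent; nothing in the model couples them to the clamp).
Windows open and close on the integer step grid, so window lifetime
comparisons are exact integer arithmetic. One master seed fans out to
named RNG streams (learning noise, stimulus, auxiliaries), making runs
bit-reproducible and componentwise independent.

## Synthetic stimulus

The event-camera generator emulates a neuromorphic sensor: per pixel, an
event fires when the accumulated log-intensity change since that pixel's
last event crosses a contrast threshold, with 1 µs timestamps and a
15 µs per-pixel dead time. The default scene is juggling-like — a few
bright Gaussian discs moving ballistically under gravity, bouncing off
the frame — rendered on a 1 ms grid. The default contrast threshold
(0.3) puts the mean event rate near 5 Hz per pixel, the few-Hz-per-pixel
regime typical of such recordings. What the synthetic scene does *not*
reproduce: natural-scene texture, sensor noise events, refractory
violations, or the specific spatiotemporal statistics of any real
recording — so passing tests show the mechanisms work on moving-object
streams, not that real-data statistics are matched. Both polarities
drive the pixel's single stimulus neuron; timestamps are floor-binned to
simulation steps with at most one spike per neuron per step (collapsed
duplicates are counted).

## Scaled-down experiments

Full-scale learning (129 000 neurons, 3100 s) is a cluster-scale
computation; the packaged experiments run on one desk CPU:

* **Self-organisation** (`pipeline.self_organisation_experiment`):
  30×30 E, 15×15 I, 32×32 D on a 30-unit plane, radius 5, 200 s of
  learning, 10 s paired evaluations. Three preset adjustments map the
  full-scale study onto this budget, chosen from the model (not tuned
  to any test outcome): γ is re-derived from the stability condition
  with f_D = f_E = f_I = 1, assumed stimulus rate 5 Hz/pixel and target
  neural rates 6 Hz, because r̂ sums over radius-limited neighbourhoods
  whose size changes with scale; the initial stimulus weights are
  boosted ×3 so the run starts in the over-driven stimulus-locked
  regime the full-scale initialisation produces; and the learning rates
  are boosted ×8 so 200 s spans a cumulative weight change comparable
  to the full run's 3100 s.
* **Rate recovery** (`pipeline.rate_recovery_experiment`): 20 Poisson
  presynaptic neurons (2–20 Hz) fully connected to 50 LIF targets,
  300 s; γ from the single-source stability condition (target rate
  8 Hz), ε = 2×10⁻⁶ µS/mV, W_init = 3×10⁻² µS·ms — strong enough that
  targets spike from the outset (the Hebbian rule cannot bootstrap a
  silent population), learning noise at the published excitatory value
  (p_noise = 0.75). The check reads the time-averaged decoded rate per
  presynaptic neuron: the decode path evaluated at regular times over
  the last 150 s, with voltage snapshots taken at those times.

  Sampling r̂_j at neuron j's own spike times instead gives a
  systematically higher average (~×1.3 here). This is a property of
  the learned quantity, not an artifact: the decode converges to the
  posterior presynaptic rate given the subsequent postsynaptic window,
  and conditioning on an actual spike selects windows that reflect it;
  averaged over *all* times the posterior's mean is the marginal rate.
  In this tiny toy every target shares all 20 inputs, so windows carry
  a lot of information per spike and the conditioning excess is large;
  it shrinks as fan-in grows or learning noise thins the decoded
  activity. The experiment returns both readings.

## Protocol comparisons

The closed forms assume constant V and r̂ and report totals over n
repetitions without compounding. The event-driven protocol simulator
compounds multiplicatively, so the two are compared in the linearisation
regime: a lumped per-protocol scale small enough that the quadratic
compounding bias stays inside the comparison band, and 100× smaller
again where agreement tightens by two orders. The simulator discards
lead-in repetitions (one window length) so Hebbian closes have reached
periodic steady state; simultaneous pre and post spikes are ordered
pre-first. Agreement is measured against the magnitude sum of the
Hebbian and non-Hebbian components, which stays finite at the LTP/LTD
zero crossings of the combined curve.

## Known limitations

* The per-spike window machinery is pure Python over arrays; desk-scale
  learning runs take minutes of wall time per hundred simulated seconds.
* No synaptic or axonal delays; no exact within-step spike timing.
* The fixed-point property (r̂ → r) is verified in the feedforward toy
  and at the weight level; recurrent-network decoding accuracy is
  checked only as before/after improvement, not against any absolute
  standard.
* Checkpoints serialise the full simulator state (including open
  plasticity windows) via pickle; they are runtime artifacts, not an
  interchange format.
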