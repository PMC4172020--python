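# Model and methods

`replaynet` simulates a rat learning a context-dependent item–reward
rule with a three-layer spiking network, and reproduces the accompanying
electrophysiology-style analyses (selectivity indices, weight
binariness, functional-network identification).

## Task

The environment has two contexts (A, B), each with two places (1, 2);
each place holds one of two items (X, Y; one of each per trial, assigned
uniformly).  Digging is rewarded for X in context A and for Y in context
B, independent of place; at a non-rewarded item the correct response is
to move to the other place, which always switches both place and sensed
item but never context.  Context, starting place and item layout are
drawn uniformly at each trial, giving eight equiprobable starting
triplets (e.g. A1X).

## Network

Six sensory cells (one per context-place A1, A2, B1, B2 and one per
item X, Y), eight hippocampal cells (configurable, e.g. twelve for the
extension experiment) and two motor cells (dig, move).  Layers are
connected all-to-all by plastic excitatory weights `W_exc ∈ [0, 1]`;
cells within the hippocampal and motor layers carry fixed random
inhibitory weights with zero diagonal.  All weights are initialized
i.i.d. uniform on [0, 1].

Every cell is a leaky integrate-and-fire neuron,

    C dV/dt = −G_l (V − V_reset) + I + η,

integrated by explicit Euler with Δt = 0.5 ms; η is a Gaussian
increment of σ = 1 µV applied once per step.  A cell crossing
V_th = −50 mV is held at V_peak = 0 mV for one step, then reset to
V_reset = −70 mV.  With C = 5.5 nF, G_l = 10 nS and a 1.00 nA drive,
the inter-spike interval is 123.5 ms (8.10 Hz, theta band); the
closed-form charging time τ ln[(I/G_l)/(I/G_l − (V_th − V_reset))] =
122.7 ms serves as the integrator's test oracle.

### Winner-take-all routing

Activity flows between layers through a winner-take-all rule: the
downstream cell maximizing

    score(j) = Σ_i (V_i − V_reset) W_exc[i,j] − Σ_{i≠j} (V_i^post − V_reset) W_inh[i,j]

receives a constant current pulse (I_hippo = 0.98 nA, I_motor =
0.96 nA); all other cells of the layer receive none.  The winner is
re-evaluated on the steps the presynaptic layer spikes and held between
spikes; until the first presynaptic spike of a stimulus the winner
follows the subthreshold ramp, so all three layers charge concurrently.
Because the input currents decrease from sensory (1.00 nA) to motor
(0.96 nA), each theta cycle produces an ordered sensory → hippocampal →
motor spike succession ~2.5–3 ms apart.

Two deliberate consequences of this scheme:

* **Noise-driven winner exploration.**  The two driven sensory cells
  accumulate independent noise (≈22 µV spread at threshold against a
  72 µV Euler step), so they spike in the same step on most cycles but
  one step apart on a sizeable fraction.  On desynchronised cycles the
  spike-step score is dominated by a single cue rather than the joint
  stimulus, and a different hippocampal cell can win the cycle.  This
  is the model's only exploration mechanism; it is what lets runs
  escape unlucky weight configurations, and — because it keeps rare
  errors flowing even in well-trained networks — what keeps the
  depression-ablation control (below) at chance.
* **Membrane re-initialization on actions.**  When an executed action
  switches the stimulus, all membrane potentials are reset to V_reset.
  The membrane time constant (0.55 s) is close to the action cadence
  (~0.65 s), so without this step potentials left over from the
  previous stimulus dominate the early part of the next decision and
  systematically mis-attribute the winner; measured over ten seeds this
  carryover drops mean final accuracy from ~0.84 to ~0.66.

### Actions and adaptive thresholds

Motor spikes are counted per action; an action executes when its cell's
count reaches its threshold.  Both thresholds start at five spikes at
each trial start.  Each move lowers the digging threshold by one (floor
zero: after at most five moves the next motor spike digs) and resets
the moving threshold; each dig resets the digging threshold.  A dig
ends the trial; if no dig occurs within T_trial = 4 s the trial times
out unrewarded (and is not replayed).  With the concurrent-charge
routing, a one-action trial lasts ~0.65 s (five motor spikes at
~129 ms) and a two-action trial ~1.16 s.

## Plasticity during replay

Spike-timing dependent plasticity acts only in the replay phase.  For a
pre/post pair with timing Δ = t_post − t_pre:

    LTP (Δ > 0):  ΔW = (w_max − W) · A₊ e^{−Δ/τ₊} · dt_pair/τ_w
    LTD (Δ < 0):  ΔW = (w_min − W) · A₋ e^{+Δ/τ₋} · dt_pair/τ_w

with A₊ = +1.2, A₋ = −0.4, τ₊ = τ₋ = τ_w = 10 ms, and pairs further
apart than the 10 ms evaluation window ignored.  `dt_pair` is the
effective time a pairing acts on the weight — the model's learning
rate.  The default sets `dt_pair` equal to the 10 ms evaluation window
(= τ_w), i.e. one pairing contributes its full term once.  At the
replay timings this closes ~94% of a weight's remaining gap to w_max
per rewarded pairing while a depression event removes ~30% of the
weight: rewarded pathways consolidate within a couple of replays,
wrong associations are dismantled over several failures, and the task
is learned within roughly 100–130 trials.  The 3:1
potentiation/depression amplitude ratio is essential — the control
experiment with A₊ = 1.0, A₋ = −1.0 (equal amplitudes) destroys
structure as fast as it is built and stays at chance.

## Replay

After each completed trial the last `n_replay = 2` (stimulus,
hippocampal winner, action) steps are replayed with noise off and
plasticity on.  Rewarded trials replay forward: per segment, the two
sensory cells receive I_sensory, the recorded winner I_hippo, the
recorded motor cell I_motor, producing the sensory → hippocampal →
motor order with ~2.5–3 ms gaps — every adjacent pair inside the STDP
window, hence potentiation.  Non-rewarded trials replay backward:
segments last-to-first and the current magnitudes mirrored (motor
largest), inverting the spike order, hence depression.  Each planned
segment is played once per episode; a full replay lasts ≤ ~260 ms,
inside the T_replay = 400 ms budget and far shorter than the ≥ 0.65 s
behaviour it compresses.  Because the replayed cells are driven
directly and noiselessly, playback spike times are the deterministic
single-cell charging times; they are computed once per current by Euler
simulation and cached (an exact memoization, not an approximation).

## Analyses

Firing rates are taken from behaviour-phase hippocampal spikes between
stimulus onset and action execution, attributed to the triplet sensed
in that interval, and pooled within 30-trial blocks (1–30, 31–60,
61–90, 91–120).  The selectivity index over n events with rates λ_i and
preferred rate λ_pref = max λ_i is

    SI = (n − Σ λ_i/λ_pref) / (n − 1)  ∈ [0, 1].

Place SI uses the four context-places with item-averaged rates (n = 4);
item SI the X-set vs Y-set means (n = 2); context SI the A-set vs B-set
means (n = 2).  A hippocampal cell belongs to the functional network
when its largest weight onto a motor cell exceeds 1 − 10⁻⁶; the
end-of-run functional set is applied retrospectively to all blocks, and
silent cells are excluded per block.  Weight binariness is
B = 4(W − 0.5)², averaged over the sensory inputs of functional cells;
block values use the weight matrix at each block's end.  The grouping
table labels a cell by its near-saturated (> 0.9) sensory inputs, e.g.
`A1/2,X` when they span both places of context A plus item X.

## Default experiment and reported behaviour

A suite is `n_runs` independent runs of 130 trials; run k uses the
stream seeded `master_seed + k`, which drives weight initialization,
membrane noise, task draws and tie-breaks, making every run bit-for-bit
reproducible.  Learning curves are centred 30-trial sliding means with
the first and last 30 trials omitted.  With the defaults, the mean
final-window fraction of correct trials reaches ~0.85–0.90 across
20-run suites; place SI stays ≈0.7–0.75 across blocks while item and
context SI rise to ≳0.95, and binariness of the functional cells'
sensory weights rises from ≈0.45 to ≈0.65–0.7 — function and
connectivity emerge together.  Typically four cells end up functional
(one per context-item pair, places merged); with twelve hippocampal
cells and 200 trials, four to six do.

## Numerical and design notes

* Exact score ties in the winner-take-all argmax are resolved uniformly
  from the run's random stream; they are essentially confined to
  saturated-weight configurations.
* The SI is clamped to [0, 1] to absorb float round-off for exactly
  uniform rates; a silent cell's SI is undefined (NaN) and excluded.
* A non-finite membrane potential raises an integration error — the
  Euler step is too large for the current/voltage scale in use.
* The behaviour loop steps the three layers as a single fused potential
  vector; the arithmetic and random-draw order match per-layer stepping
  (the per-layer integrator remains the public, oracle-tested API).
* Problem sizes in the test-suite and in `scripts/acceptance.py` are 20
  seeded runs per stochastic quantity (the multi-run figures in the
  source study use up to 100); block statistics at 20 runs have SEMs of
  a few hundredths, comfortably inside the tolerances checked.

## What the model does not capture

No continuous space or locomotion, no odor/texture features, no
sharp-wave-ripple waveform (replay is an abstract ordered
reactivation), no refractory periods or conductance synapses, and no
significance testing of block differences (descriptive means ± SEM
only).  The simulated rat's behaviour phase is driven by a discrete
stimulus encoding; conclusions about real hippocampal data are limited
to the qualitative selectivity/binariness trajectories the source
experiments report.

## Typical timing caveat

Post-learning trials are a roughly even mix of one-action (~0.65 s) and
two-action (~1.16 s) sequences, so the median behaviour-phase duration
over a run's last 30 trials is ~0.65–1.16 s depending on the mix; the
across-run mean of these medians is ~0.8–0.9 s.
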