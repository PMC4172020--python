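# replaynet

A spiking-network model of how hippocampal neurons learn a
context-dependent item–reward rule, and of the accompanying
unit-recording analyses.

A model rat is in one of two contexts (A or B), each with two places;
each place holds one of two items (X or Y).  Digging is rewarded for
item X in context A and for item Y in context B, independent of place;
at the wrong item the correct response is to move to the other place.
A three-layer leaky integrate-and-fire network — six sensory cells
(context-places A1, A2, B1, B2 and items X, Y), eight hippocampal
cells, two motor cells (dig / move) — learns this rule with no external
teacher.  Credit assignment works through replay: after a rewarded
trial the last two (stimulus → hippocampal winner → action) steps are
reactivated in forward temporal order, so pre-synaptic spikes precede
post-synaptic spikes and spike-timing dependent plasticity (STDP)
potentiates the pathway; after a non-rewarded trial the sequence is
replayed backward and the same rule depresses it:

* membrane: `C dV/dt = −G_l (V − V_reset) + I + η`, Euler step 0.5 ms,
  spike at V_th with one-step peak and reset — constant drive yields
  8.1 Hz theta-band spiking;
* routing: a winner-take-all rule gives the downstream cell with the
  largest drive `Σ_i (V_i − V_reset) W_exc − Σ_{i≠j} (V_i − V_reset) W_inh`
  a fixed current pulse (1.00 / 0.98 / 0.96 nA from sensory to motor,
  so each theta cycle spikes in order);
* plasticity (replay only):
  `ΔW = (w_max − W)·A₊ e^{−Δ/τ₊}` for pre-before-post,
  `ΔW = (w_min − W)·A₋ e^{+Δ/τ₋}` for post-before-pre,
  with A₊/|A₋| = 3 — the asymmetry the learning provably needs
  (equal amplitudes stay at chance).

Analyses mirror the experimental literature: per-cell selectivity
indices `SI = (n − Σλᵢ/λ_pref)/(n − 1)` for place (n = 4,
item-averaged), item and context (n = 2, set means); weight binariness
`B = 4(W − 0.5)²`; and a "functional network" of hippocampal cells
whose motor weight saturates above 1 − 10⁻⁶.  During learning the
model maintains place selectivity while item and context selectivity
and weight binariness rise — the shift from place coding to conjunctive
item-context coding seen in rodent CA1 during this task.

Intended users: computational neuroscientists studying replay-based
credit assignment, and anyone needing a small, fully reproducible
spiking-network learning testbed.

## Worked example

```bash
replaynet run --seed 11 --runs 2 --trials 130 --out demo --no-rasters
```

prints

```
2 runs x 130 trials: mean final-window accuracy 1.000; outputs in demo/
```

meaning both seeded runs solved the task within 130 trials (fraction of
trials whose terminating dig was at a rewarded pot, over the final 30
trials).  `demo/learning_curve.csv` holds the across-run sliding-window
curve (here starting at 0.88 by trial 31 and rising to 1.0), and
`demo/weights_final.csv` the learned connectivity of the first run:

```
,Cell 1,Cell 2,Cell 3,Cell 4,Cell 5,Cell 6,Cell 7,Cell 8
A1,0.13,1.0,0.42,0.03,0.15,1.0,0.05,0.13
B1,0.67,0.51,0.82,1.0,0.69,0.2,1.0,0.48
A2,0.67,1.0,0.37,0.18,0.47,1.0,0.14,0.79
B2,0.35,0.42,0.24,1.0,0.61,0.13,1.0,0.28
X,0.06,1.0,0.43,0.15,0.47,0.95,1.0,0.22
Y,0.03,0.1,0.24,1.0,0.45,1.0,0.34,0.02
Dig,0.16,1.0,0.04,1.0,0.15,0.89,0.02,0.47
Move,0.69,0.48,0.03,0.59,0.22,1.0,1.0,0.13
Function,None,"A1/2,X",None,"B1/2,Y",None,None,"B1/2,X",None
```

Cell 2 has learned saturated weights from A1, A2 and X and projects to
"dig": it groups both places of context A with item X — a conjunctive
context-item cell independent of place.  Cell 4 is its context-B
counterpart (B1/2, Y → dig) and Cell 7 maps B1/2, X to "move".  This
run's functional network (`run_summary.json`) is cells {2, 4, 6, 7}
(1-based) — four of the eight hippocampal cells carry the behaviour,
the rest stay unstructured.

The depression-ablation control is one override away:

```bash
replaynet sweep --override A_plus=1.0 --override A_minus=-1.0 \
    --seed 11 --runs 2 --trials 130 --out demo_ablation --no-rasters
```

which stays near 50% — without the 3:1 potentiation/depression
asymmetry the replay rule builds structure no faster than it destroys
it.

Library use mirrors the CLI:

```python
from replaynet import ExperimentConfig, run_suite

suite = run_suite(ExperimentConfig(n_runs=20, n_trials=130, master_seed=0))
print(suite.curve.tail())        # sliding-window learning curve
print(suite.block_stats)         # SI and binariness per 30-trial block
```

See `docs/methods.md` for the full model description, parameter table
semantics and design decisions.

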