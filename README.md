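# cortcol

A spiking simulator of a primary-visual-cortex column and the perturbation
analysis built on top of it: put the column into a network state
(spontaneous, feedforward-driven, feedback-driven, or both), inject a small
DC current into one cell group at a time, and map how every other group's
firing rate responds.

The package is for computational neuroscientists who want to predict the
outcome of cell-type-specific stimulation experiments — which layer and
interneuron class to drive, and how the answer depends on the column's
state — without hand-building a laminar microcircuit each time.

## The model

Neurons are leaky integrate-and-fire units,

```
C_m dV/dt = -g_L (V - V_rest) + I_syn(t),
```

with a spike on reaching `V_th`, an instantaneous reset to `V_rest` and an
absolute refractory period `tau_ref`.  The synaptic current

```
I_syn = I_ext + I_bg,AMPA + I_AMPA + I_NMDA + I_GABA
```

combines conductance-based receptor channels, each `g . s . (V_rev - V)`
with a dimensionless gating variable `s` driven by presynaptic delta pulses
and decaying exponentially (`tau_AMPA` = 2 ms, `tau_GABA` = 5 ms; NMDA has
80 ms decay / 2 ms rise dynamics with saturation).  NMDA currents carry the
voltage-dependent magnesium block `1 / (1 + [Mg2+] e^{-0.062 V} / 3.57)`.
The excitatory reversal is 0 mV; the GABA-A reversal is each neuron's own
resting potential.  Background input is a private Poisson train per neuron
onto an AMPA channel; sensory-like feedforward (layer 4) and top-down
feedback (layers 5, 2/3, 6) drives are DC currents to 25% of pyramidal and
5% of PV cells of the targeted layers.

The column holds 17 groups — E, PV, SST and VIP cells in layers 2/3, 4, 5
and 6, plus layer-1 VIP (85% pyramidal per complete layer) — wired by
Bernoulli connectivity from a 17x17 probability matrix `P` with strengths
`S` (mV).  Each excitatory projection splits 0.8/0.2 between AMPA and NMDA
contacts.  Synapse weights follow `w = G ws / (N_send p)`, which keeps the
expected group-level input invariant under network size, and reported
probabilities are translated from their measurement disk (radius 75 um) to
the model column's disk (125 um) through the per-connection Gaussian
profile widths.

The perturbation pipeline measures, for each of the 16 perturbable groups,
the percent change of every group's mean rate over matched windows,
producing a 16x16 response matrix `R_XY`; matrices are thresholded at
±20% into marked increases/decreases, compared across states entrywise,
and summarized by marked-change counts and Frobenius distances.

The reference connectivity matrices (Allen Institute, "mv1-all-layers") are
an optional user-supplied input in a documented CSV layout; a seeded
synthetic column with the same structure (`cortcol.synthetic_bundle`) makes
the whole package runnable and testable offline.

## Worked example

```python
import cortcol as cc
from cortcol.perturbation import ExperimentPlan, perturbation_sweep
from cortcol.analysis import categorize, count_marked

bundle = cc.synthetic_bundle(seed=1)
network = cc.build_network(bundle, N_total=600, seed=1)
record = cc.run_simulation(network, cc.make_state_protocol("spontaneous"),
                           duration=2000.0, seed=1)
print(cc.mean_rates(record, (500.0, 2000.0)).round(2))

plan = ExperimentPlan(state="spontaneous", master_seed=1,
                      window_ms=400.0, settle_ms=400.0, state_onset_ms=300.0)
matrix = perturbation_sweep(plan, network)
n, pos = count_marked(categorize(matrix))
print(f"marked changes (|change| > 20%): {n}, positive fraction {pos:.2f}")
```

prints (excerpt)

```
VIP1     14.33
E23       1.39
...
E5        1.53
...
PV6      15.47
...
marked changes (|change| > 20%): 10, positive fraction 0.40
```

Pyramidal groups fire at 1-2 spikes/s and interneurons faster — the
inhibition-dominated, low-rate operating point the column is tuned to —
and a 30 pA perturbation sweep marks 10 of the 240 off-diagonal
group-to-group interactions as changed by more than 20%.  The same objects
expose the full matrices: `matrix.values` (percent changes),
`categorize(matrix)` (-1/0/+1) and, across states,
`compare_categorical`, `numeric_difference` and `pairwise_frobenius`.

The same workflow is available from the shell:

```
cortcol synth-bundle --seed 42 --out column/
cortcol run --bundle column/ --state ff --duration-ms 3000 --seed 1 --out spikes.csv
cortcol perturb-sweep --bundle column/ --state spontaneous --seed 1 --out-dir sweep/
cortcol condition-sweep --bundle column/ --family ff --min 0 --max 400 --n 14 \
    --seed 1 --out-dir conditions/
```

An example bundle lives in `examples/synthetic_column/` (generated, clearly
synthetic); see `docs/methods.md` for the file formats and every model
parameter.

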