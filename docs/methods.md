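# Methods

## Neuron and synapse model

Every cell is a leaky integrate-and-fire neuron with its own group-level
parameters: resting potential `V_rest` (mV), threshold `V_th` (mV),
capacitance `C_m` (pF), leak conductance `g_L` (nS) and refractory period
`tau_ref` (ms); the membrane time constant is `tau_m = C_m / g_L`.  On
threshold crossing the membrane resets instantaneously to `V_rest` and is
clamped there for `tau_ref`, during which inputs are discarded.

Synaptic currents are conductance-based.  With gating variables `s` per
receptor channel,

    I_syn = I_ext + g_AMPA (V_E - V) s_bg
          + g_AMPA (V_E - V) SUM_j w_j s_j^AMPA
          + g_NMDA (V_E - V) B(V) SUM_j w_j s_j^NMDA
          + g_GABA (V_I - V) SUM_j w_j s_j^GABA,

    B(V) = 1 / (1 + [Mg2+] exp(-0.062 V) / 3.57).

A note on sign conventions: the driving forces are written `(V_rev - V)` so
that AMPA/NMDA depolarize below their reversal and GABA-A inhibits above
its reversal.  Conventions in the literature differ (some texts write
`g (V - V_rev) s` inside a current that is then subtracted); the form used
here is the one under which excitatory input raises firing, which is the
behaviour the model is defined to have.

Parameter defaults: `V_E = 0` mV; `V_I` equals the **postsynaptic**
neuron's own `V_rest` (a reversal potential is a property of the
postsynaptic channel; the alternative reading — the presynaptic group's
resting potential — was considered and rejected on these grounds);
`[Mg2+] = 1` mM; all conductance conversion factors 1 nS.  Gating
kinetics: `tau_AMPA = 2` ms and `tau_GABA = 5` ms first-order channels
incremented by +1 per presynaptic spike; NMDA follows the saturating pair

    ds/dt = -s / tau_decay + alpha x (1 - s),     tau_decay = 80 ms
    dx/dt = -x / tau_rise  + spike deltas,        tau_rise  = 2 ms

with `alpha = 0.5 /ms`; the `(1 - s)` term keeps `s` in [0, 1].

Units are internally consistent throughout: mV, ms, pF, nS, pA
(1 nS · 1 mV = 1 pA; 1 pA · 1 ms / 1 pF = 1 mV).

## Column composition and connectivity

17 groups: `VIP1`, then E/PV/SST/VIP per layer 2/3, 4, 5, 6, always in this
layer-major canonical order.  Population sizes come from fractional shares
of `N_total` (default 5000) with exactly 85% pyramidal cells per complete
layer; integer counts use largest-remainder rounding (ties broken by
canonical order), with every declared group guaranteed one neuron.

Connectivity is pairwise Bernoulli from the 17x17 probability matrix P.
Excitatory projections are drawn twice, independently per channel: AMPA
contacts at `p · 0.8` and NMDA contacts at `p · 0.2` (the receptor split);
inhibitory projections once at `p` for GABA-A.  At most one synapse exists
per (pre, post, receptor) triple and autapses are excluded.  Every synapse
of a group pair carries the same weight

    w = G ws / (N_send p),

with global coupling `G = 5 /mV` and `ws` (mV) from the strength matrix S,
so the expected summed weight a neuron receives from any source group is
`N_send · p · w = G ws`, independent of network size.  S defines 288 of the
289 entries (the layer-1 self-projection is absent); the undefined entry is
stored as NaN and treated as zero.

Reported connection probabilities correspond to a Gaussian connectivity
profile `A exp(-r^2/sigma^2)` averaged over a disk of radius R0 = 75 um,
whereas the model column is a uniform disk of radius R = 125 um.  The
translation used is

    P_new = P_rep (R0^2/R^2) (1 - e^{-R^2/sigma^2}) / (1 - e^{-R0^2/sigma^2}),

i.e. the disk-R average of the same profile whose disk-R0 average equals
`P_rep`.  It satisfies both limits that pin the algebra down: flat profiles
(`sigma -> inf`) leave the probability unchanged, and narrow profiles
(`sigma -> 0`) shrink it by `(R0/R)^2 = 0.36`.  The formula is monotone
increasing in `sigma` and bounded by `[0.36 P_rep, P_rep]`.

Two structural variants are first-class: lognormal weights (each nonzero
weight replaced by an independent lognormal draw with arithmetic mean equal
to the original weight and SD equal to that mean, i.e.
`sigma_log^2 = ln 2`, `mu_log = ln(mean) - sigma_log^2/2`), and the
inhibitory-output lesion (all GABA rows removed; inhibitory neurons still
receive input and spike).

## Stimulation

Background: every neuron owns an independent homogeneous Poisson generator
at its group's rate `nu_bg`, feeding a dedicated AMPA channel with unit
increments (the generator-to-neuron weight is taken as 1; no other value is
specified anywhere, and the per-group rates are the tuning knob that sets
the operating point).

State drives and perturbations are DC currents through `I_ext`, justified
by the diffusion approximation for barrages of many small synaptic inputs;
no extra noise term is added.  Named states (default 150 pA, onset 700 ms):

| state | targets |
|---|---|
| `ff` | 25% of E4, 5% of PV4 |
| `fb_L5` | 25% of E5, 5% of PV5 |
| `fb_L23`, `fb_L6` | same fractions in the named layer |
| `fb_L23_L5`, `fb_L23_L5_L6` | union of the single-layer sets |
| `ff_fb` | FF at 500 ms, then FB to layer 5 at 1100 ms |

Perturbations (default +30 pA; negative values allowed, the scan range is
-40..+40 pA) are applied to **all** neurons of one group.  The published
description says current is injected "into each group" without naming a
fraction; the plain reading — the whole group — is adopted, with the
fraction exposed as a parameter for the subset interpretation.  Layer-1
VIP cells are not perturbable: the response matrices cover the 16 groups of
the complete layers.

## Numerical integration

Fixed step `dt = 0.1` ms, forward Euler on the membrane and on the
nonlinear NMDA gating equation.  The linear gating equations (AMPA,
background AMPA, GABA, NMDA rise variable) are advanced by their exact
exponential decay plus delta increments — plain Euler at `dt = 0.1` ms
would distort the 2 ms AMPA channel by a few percent, while the exact
update is free and keeps the single-spike impulse response on its closed
form to machine precision.

Spikes are detected at step end and delivered to targets on the next step
(a one-step latency; the model has no explicit axonal or synaptic delays).
Background events are binned per step: the Poisson count for each `dt` is
drawn and added at the step boundary, scaled by the expected decay from a
uniform within-step arrival time, `E[e^{-u/tau}] = (1 - e^{-dt/tau}) (tau/dt)`.
Without this factor the binning inflates both the mean and the variance of
the background drive by O(dt/tau), which measurably shifts rates in the
near-threshold regime; with it, halving `dt` moves the column's aggregate
rate by well under 5% (the residual is first-passage discretization).

Linear-algebra organization: because the first-order gating ODEs are linear
in the spike drive, the weighted sums over presynaptic AMPA/GABA channels
are collapsed into one accumulator per postsynaptic neuron, updated
event-wise.  The NMDA equation is nonlinear, but all synapses from one
presynaptic neuron share a spike train and hence one gating trajectory, so
NMDA is tracked per presynaptic neuron and the postsynaptic weighted sum is
a sparse matrix-vector product per step.  Both rearrangements are exact.

Initial conditions: `V(0) = V_rest`, all gating variables zero —
deterministic and state-free.  A run aborts with a diagnostic naming the
neuron and step if any |V| exceeds 500 mV.

Seeding: one master seed spawns named substreams (connectivity, background,
target selection, weight randomization), so whole pipelines are
bit-reproducible while any single randomness source can be varied in
isolation.  Each stimulus epoch carries its own target-selection key, so
adding an epoch (e.g. a perturbation) never disturbs the random streams of
the existing protocol — an amplitude-0 perturbation is verifiably
invisible, spike for spike.

## Perturbation analysis

A plan fixes the state, the windows and the master seed.  The perturbation
switches on `settle_ms` (default 1000 ms) after the state drive and stays
on through a measurement window of `window_ms` (default 3000 ms).  Baseline
rates come from the state-only simulation over the same absolute window
under the same seeds: since all streams are shared, any rate difference is
attributable to the perturbation alone, and a zero-amplitude perturbation
yields an exactly zero matrix (this is tested).  Entry (Y, X) of the
response matrix is `100 (rate_X^pert(Y) - rate_X^base) / rate_X^base`.

Zero-baseline entries are undefined — flagged, reported as NaN, treated as
category 0, and excluded from marked-change counts; they are never silently
zero.  The categorical view uses strictly-greater-than thresholds (an entry
exactly at ±20% is unmarked).  The state-comparison matrix colours each
entry white (categories equal), red (transitions 0→+1, -1→0, -1→+1) or
green (+1→-1, +1→0, 0→-1); numeric comparisons report `B - A` in
percentage points with a sign-flip mask (`A·B < 0`).  Frobenius distances
`||A - B||_F` are computed over entries defined in both matrices, and a
pairwise-distance table summarizes a set of state matrices.

Condition sweeps rerun the full 16-group sweep across state-drive
amplitudes; the default grid is 14 evenly spaced values over 0-400 pA (the
design dimension is stated as 14 conditions over that range; the exact grid
is not enumerated anywhere, so an even grid is used and is overridable).
The amplitude/threshold scan reuses one sweep's percent matrices across all
thresholds without re-simulation.

Matrices are computed per single seeded realization; a mean ± SD mode
across seeds can be had by rerunning with different master seeds.

## The synthetic column

`synthetic_bundle(seed)` generates a column with the structure of the real
data but synthetic content, so every operation is testable offline:

- 17 groups, exact 85/15 E/I split per complete layer, interneuron shares
  PV > SST > VIP; layer shares roughly L2/3 ≥ L4 ≈ L5 ≈ L6 >> L1.
- Connection probabilities in [0, 0.3] (a "dense" regime scales by 1.5),
  stronger within than across layers, arranged in canonical microcircuit
  motifs: a feedforward excitatory chain L4 → L2/3 → L5 → L6; deep-layer
  pyramidal cells (E5, E6) recruiting PV/SST interneurons in other layers
  (translaminar gain control); VIP → SST disinhibition, including from
  layer 1.  Strengths lie in [0.1, 2] mV and Gaussian widths in
  [50, 300] um (narrower within-layer).  All values carry ±15% seeded
  jitter.
- Class-level electrophysiology in physiological ranges (e.g. E cells:
  `V_rest ~ -70` mV, 20 mV to threshold, `tau_m ~ 20` ms; PV cells faster).
  Background rates are derived per group from an operating-point rule —
  the mean background current is a fixed fraction of rheobase (0.95 for E,
  1.05 for PV, 1.0 for SST/VIP), evaluated at the mid-point voltage — which
  places every group in a fluctuation-driven regime: pyramidal rates of
  1-2 spikes/s, interneurons faster, nonzero spiking in every group within
  seconds.

What the synthetic column does and does not show: passing tests on it
demonstrate the mechanics (construction, integration, seed discipline,
matrix bookkeeping) and the qualitative state signatures built into its
motif structure — feedforward drive raises excitatory rates in all layers,
feedback to layer 5 suppresses excitatory cells elsewhere, removing
inhibitory output raises every group's rate, and stronger state drives
leave fewer marked perturbation-induced changes.  They do **not**
reproduce quantitative features tied to the measured connectivity (e.g.
specific response-matrix entries or in-vivo-matched per-group rates); those
require supplying the reference matrices in the documented CSV layout.

## File formats

- `P.csv`, `S.csv`, `sigma.csv`: 17 labelled rows (presynaptic) x 17
  labelled columns (postsynaptic) in the canonical order `VIP1, E23, PV23,
  SST23, VIP23, E4, ..., VIP6`.  `S` may leave the `VIP1,VIP1` entry empty.
- `params.yaml`: `provenance`, a `global` block (`G`, `nmda_fraction`, `R`,
  `R0`, `Mg`, `dt`), `fractions` (17 population shares summing to 1) and
  `groups` (per group: `V_rest`, `V_th`, `C_m`, `g_L`, `tau_ref`,
  `nu_bg`).
- Spike output: CSV `neuron_id,group,time_ms`; optionally an HDF5 container
  with spikes, decimated voltage samples (default 1 ms) and the full config
  echo (seed, dt, protocol, network hash) sufficient to re-run
  bit-identically.
- Sweep output: labelled 16x16 CSV matrices (percent and categorical),
  counts and a provenance JSON.

## Problem sizes used in the shipped checks

The test suite and the worked example run the column at 600 neurons with
windows of 400-800 ms and the acceptance script uses a 500x500-neuron
connectivity block and a 400 ms kinetics horizon — sizes at which every
contract above is sharply testable on a desktop.  All sizes are parameters;
the default column is 5000 neurons with 3 s windows.

## Known limitations

Point neurons only (no dendritic compartments), no synaptic delays or
short-term plasticity, no conductance-based (spike-train) feedforward or
feedback afferents, no explicit thalamus, no spatial embedding beyond the
disk-average probability translation, and no orientation/tuning structure.
Rates in the near-threshold fluctuation-driven regime retain a small
first-passage discretization bias at fixed `dt`; halving `dt` shifts
aggregate rates by a few percent at most.
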