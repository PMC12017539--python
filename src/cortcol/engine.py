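"""Time-stepped simulation of the full column.

Forward integration at a fixed step (default dt = 0.1 ms).  Per step the
engine (1) draws each neuron's private background Poisson deliveries,
(2) propagates the previous step's spikes through the synapse table into
receptor-specific weighted gating sums (one-step delivery latency; the model
has no explicit axonal delays), (3) advances all gating variables,
(4) computes the total synaptic current including protocol DC terms, and
(5) advances the membranes, detecting, resetting and refracting spikes.

The linear gating equations (AMPA, background AMPA, GABA, NMDA rise) are
summed per postsynaptic neuron with their weights folded in — a valid
rearrangement because those ODEs are linear in the spike drive.  The
nonlinear NMDA gating variable is tracked per presynaptic neuron (all
synapses from one neuron see the same spike train, hence share one gating
trajectory) and weighted sums are formed by a sparse matrix-vector product.

Runs are bit-identical given (network, protocol, seed, dt).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import _seeds
from .model_core import SynapseKinetics
from .network_builder import Network
from .stimulation import StimulusProtocol

__all__ = ["SimulationRecord", "run_simulation"]


@dataclass
class SimulationRecord:
    """Spikes (and optionally sampled membrane potentials) of one run.

    ``spike_neurons`` / ``spike_times`` are parallel arrays; ``group_index``
    maps every neuron id to its position in ``group_names``.  The
    ``config_echo`` dict carries everything needed to re-run bit-identically
    (seed, dt, duration, protocol, network hash).
    """

    spike_neurons: np.ndarray
    spike_times: np.ndarray
    group_index: np.ndarray
    group_names: tuple[str, ...]
    group_counts: np.ndarray
    duration: float
    dt: float
    config_echo: dict = field(default_factory=dict)
    voltage_times: np.ndarray | None = None
    voltage: np.ndarray | None = None        # (n_samples, n_recorded)
    voltage_neurons: np.ndarray | None = None

    @property
    def n_neurons(self) -> int:
        return int(self.group_index.size)

    def spikes_dataframe(self) -> pd.DataFrame:
        names = np.asarray(self.group_names, dtype=object)
        return pd.DataFrame(
            {
                "neuron_id": self.spike_neurons,
                "group": names[self.group_index[self.spike_neurons]],
                "time_ms": self.spike_times,
            }
        )

    def neurons_of(self, group: str) -> np.ndarray:
        gi = self.group_names.index(group)
        return np.flatnonzero(self.group_index == gi)

    def spike_trains(self, group: str | None = None) -> dict[int, np.ndarray]:
        """Per-neuron sorted spike-time arrays (neurons with spikes only)."""
        if group is None:
            sel = slice(None)
            neurons = self.spike_neurons
            times = self.spike_times
        else:
            gi = self.group_names.index(group)
            mask = self.group_index[self.spike_neurons] == gi
            neurons = self.spike_neurons[mask]
            times = self.spike_times[mask]
        order = np.lexsort((times, neurons))
        neurons, times = neurons[order], times[order]
        out: dict[int, np.ndarray] = {}
        for nid, start, count in zip(
            *np.unique(neurons, return_index=True, return_counts=True)
        ):
            out[int(nid)] = times[start:start + count]
        return out


def _receptor_matrices(network: Network):
    """Sparse weight matrices per receptor.

    AMPA/GABA: shape (N, N) CSR with row = presynaptic neuron, so a spike's
    deliveries are one row.  NMDA: shape (N, N) CSR with row = postsynaptic
    neuron, for the per-step weighted sum over presynaptic gating variables.
    """
    n = network.n_neurons
    tbl = network.synapses
    mats = {}
    for rec in ("AMPA", "GABA"):
        rows = tbl[tbl["receptor"] == rec]
        mats[rec] = sp.csr_matrix(
            (rows["weight"].to_numpy(float),
             (rows["pre"].to_numpy(np.int64), rows["post"].to_numpy(np.int64))),
            shape=(n, n),
        )
    rows = tbl[tbl["receptor"] == "NMDA"]
    mats["NMDA"] = sp.csr_matrix(
        (rows["weight"].to_numpy(float),
         (rows["post"].to_numpy(np.int64), rows["pre"].to_numpy(np.int64))),
        shape=(n, n),
    )
    return mats


def _deliver(W: sp.csr_matrix, spikes: np.ndarray, out: np.ndarray) -> None:
    """Add the summed weighted rows of *W* for the spiking neurons to *out*."""
    if spikes.size == 0 or W.nnz == 0:
        return
    indptr, indices, data = W.indptr, W.indices, W.data
    cols = np.concatenate([indices[indptr[r]:indptr[r + 1]] for r in spikes])
    vals = np.concatenate([data[indptr[r]:indptr[r + 1]] for r in spikes])
    np.add.at(out, cols, vals)


def run_simulation(
    network: Network,
    protocol: StimulusProtocol,
    duration: float,
    dt: float = 0.1,
    seed: int = 0,
    record_voltage: bool = False,
    voltage_sample_ms: float = 1.0,
    voltage_neurons: np.ndarray | None = None,
) -> SimulationRecord:
    """Simulate the column for ``duration`` ms and return the record.

    All neurons start at their resting potential with all gating variables
    at zero.  Voltage recording, if requested, is decimated to
    ``voltage_sample_ms`` (default 1 ms) to bound memory; ``voltage_neurons``
    restricts recording to a subset of neuron ids.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < dt:
        raise ValueError("duration must be at least one time step")

    kin: SynapseKinetics = network.kinetics
    n = network.n_neurons
    n_steps = int(round(duration / dt))

    mats = _receptor_matrices(network)
    W_ampa, W_gaba, W_nmda = mats["AMPA"], mats["GABA"], mats["NMDA"]
    exc_mask = network.excitatory_mask

    rng_bg = _seeds.substream(seed, _seeds.BACKGROUND)
    lam = network.nu_bg * dt / 1000.0
    has_bg = np.any(lam > 0)
    # Background events arrive uniformly within a step (their times are not
    # resolved); crediting them with the expected decay E[e^{-u/tau}] over
    # u ~ U[0, dt] keeps the drive's mean and variance dt-independent.
    a = dt / kin.tau_AMPA
    bg_gain = -np.expm1(-a) / a

    # state
    V = network.V_rest.copy()
    refrac = np.zeros(n)
    s_bg = np.zeros(n)
    S_ampa = np.zeros(n)     # weighted postsynaptic AMPA sum
    S_gaba = np.zeros(n)
    s_nmda = np.zeros(n)     # per presynaptic excitatory neuron
    x_nmda = np.zeros(n)

    d_ampa = np.exp(-dt / kin.tau_AMPA)
    d_gaba = np.exp(-dt / kin.tau_GABA)
    d_rise = np.exp(-dt / kin.tau_NMDA_rise)

    epochs = protocol.resolve(network, seed)

    spk_neurons: list[np.ndarray] = []
    spk_times: list[np.ndarray] = []
    prev_spikes = np.array([], dtype=np.int64)

    if record_voltage:
        rec_ids = (np.arange(n) if voltage_neurons is None
                   else np.asarray(voltage_neurons, dtype=np.int64))
        sample_every = max(int(round(voltage_sample_ms / dt)), 1)
        v_times: list[float] = []
        v_samples: list[np.ndarray] = []

    for k in range(n_steps):
        t = k * dt

        # (1) + (2): this step's deliveries — background counts and the
        # previous step's spikes (one-step latency)
        exc_spk = prev_spikes[exc_mask[prev_spikes]]
        inh_spk = prev_spikes[~exc_mask[prev_spikes]]

        # (3) gating: nonlinear NMDA first (uses step-start x), then the
        # exact exponential decays plus delta increments
        s_nmda += dt * (-s_nmda / kin.tau_NMDA_decay
                        + kin.alpha * x_nmda * (1.0 - s_nmda))
        x_nmda *= d_rise
        if exc_spk.size:
            np.add.at(x_nmda, exc_spk, 1.0)
        S_ampa *= d_ampa
        _deliver(W_ampa, exc_spk, S_ampa)
        S_gaba *= d_gaba
        _deliver(W_gaba, inh_spk, S_gaba)
        s_bg *= d_ampa
        if has_bg:
            s_bg += bg_gain * rng_bg.poisson(lam)

        # (4) total synaptic current
        drive_E = kin.V_E - V
        I = kin.g_AMPA * drive_E * (s_bg + S_ampa)
        I += (kin.g_NMDA * drive_E
              / (1.0 + kin.Mg * np.exp(-0.062 * V) / 3.57)
              * (W_nmda @ s_nmda))
        I += kin.g_GABA * (network.V_rest - V) * S_gaba
        for ids, amp, t_on, t_off in epochs:
            if t_on <= t < t_off:
                I[ids] += amp

        # (5) membranes: Euler update, refractory clamp, spike detection
        in_ref = refrac > 0
        V = V + dt * (-network.g_L * (V - network.V_rest) + I) / network.C_m
        V[in_ref] = network.V_rest[in_ref]
        refrac[in_ref] -= dt
        spiking = np.flatnonzero(~in_ref & (V >= network.V_th))
        if spiking.size:
            V[spiking] = network.V_rest[spiking]
            refrac[spiking] = network.tau_ref[spiking]
            spk_neurons.append(spiking)
            spk_times.append(np.full(spiking.size, (k + 1) * dt))
        prev_spikes = spiking

        if not np.all(np.abs(V) <= 500.0):
            bad = int(np.argmax(np.abs(V)))
            raise RuntimeError(
                f"numerical divergence: |V| > 500 mV for neuron {bad} "
                f"(group {network.group_names[network.group_index[bad]]}) "
                f"at step {k} (t = {t:.1f} ms)"
            )

        if record_voltage and (k + 1) % sample_every == 0:
            v_times.append((k + 1) * dt)
            v_samples.append(V[rec_ids].copy())

    record = SimulationRecord(
        spike_neurons=(np.concatenate(spk_neurons) if spk_neurons
                       else np.array([], dtype=np.int64)),
        spike_times=(np.concatenate(spk_times) if spk_times
                     else np.array([], dtype=float)),
        group_index=network.group_index.copy(),
        group_names=network.group_names,
        group_counts=network.counts().to_numpy(),
        duration=duration,
        dt=dt,
        config_echo={
            "seed": int(seed),
            "dt": dt,
            "duration": duration,
            "protocol": protocol.to_dict(),
            "network_hash": network.network_hash(),
            "network_seed": int(network.seed),
            "n_neurons": n,
        },
    )
    if record_voltage:
        record.voltage_times = np.asarray(v_times)
        record.voltage = (np.vstack(v_samples) if v_samples
                          else np.empty((0, rec_ids.size)))
        record.voltage_neurons = rec_ids
    return record
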