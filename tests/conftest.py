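"""Shared fixtures: a seeded synthetic column, a realized network, and a
spontaneous-activity record reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cortcol import (
    CellTypeParams,
    SynapseKinetics,
    build_network,
    make_state_protocol,
    run_simulation,
    synthetic_bundle,
)
from cortcol.engine import SimulationRecord
from cortcol.network_builder import Network, PopulationSpec
from cortcol.perturbation import ExperimentPlan, perturbation_sweep

SEED = 1


@pytest.fixture(scope="session")
def bundle():
    return synthetic_bundle(SEED)


@pytest.fixture(scope="session")
def net600(bundle):
    """A 600-neuron realization of the synthetic column."""
    return build_network(bundle, N_total=600, seed=SEED)


@pytest.fixture(scope="session")
def spont_record(net600):
    """Two seconds of spontaneous activity of the 600-neuron column."""
    return run_simulation(
        net600, make_state_protocol("spontaneous"), duration=2000.0, seed=SEED
    )


@pytest.fixture(scope="session")
def fast_plan():
    """Short-window experiment plan sized for the 600-neuron test column."""
    return ExperimentPlan(
        state="spontaneous", master_seed=SEED,
        window_ms=400.0, settle_ms=400.0, state_onset_ms=300.0,
    )


@pytest.fixture(scope="session")
def spont_sweep(fast_plan, net600):
    """One full 16-population perturbation sweep in the spontaneous state."""
    return perturbation_sweep(fast_plan, net600)


def empty_synapse_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pre": np.array([], dtype=np.int64),
            "post": np.array([], dtype=np.int64),
            "receptor": pd.Series([], dtype=object),
            "weight": np.array([], dtype=float),
        }
    )


def isolated_network(
    params: CellTypeParams,
    n: int = 1,
    kinetics: SynapseKinetics | None = None,
) -> Network:
    """A network of n unconnected neurons of one group (no synapses)."""
    pop = PopulationSpec(params.group_id, n, params, 0)
    return Network(
        populations=[pop],
        synapses=empty_synapse_table(),
        kinetics=kinetics or SynapseKinetics(),
        spec=None,
        seed=0,
    )


def make_record(group_spikes: dict[str, list[np.ndarray]],
                duration: float = 1000.0) -> SimulationRecord:
    """Hand-built record: per group, a list of per-neuron spike-time arrays."""
    names = tuple(group_spikes)
    neurons, times, gidx = [], [], []
    nid = 0
    counts = []
    for gi, (g, trains) in enumerate(group_spikes.items()):
        counts.append(len(trains))
        for t in trains:
            t = np.asarray(t, dtype=float)
            neurons.append(np.full(t.size, nid, dtype=np.int64))
            times.append(t)
            gidx.append(gi)
            nid += 1
    return SimulationRecord(
        spike_neurons=(np.concatenate(neurons) if neurons
                       else np.array([], dtype=np.int64)),
        spike_times=(np.concatenate(times) if times
                     else np.array([], dtype=float)),
        group_index=np.asarray(gidx, dtype=np.int16),
        group_names=names,
        group_counts=np.asarray(counts),
        duration=duration,
        dt=0.1,
    )
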