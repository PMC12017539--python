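"""Background Poisson drive and DC-current stimulation protocols.

Network states are set by constant currents injected through the external
term of the synaptic current: the feedforward (FF, sensory-like) drive
targets 25% of layer-4 pyramidal cells and 5% of layer-4 PV cells; feedback
(FB, top-down) drives target the same fractions in layers 5, 2/3 and/or 6
(never layer 4); a combined state applies FF at 500 ms and FB at 1100 ms.
Perturbations add a small DC current (default 30 pA, negative values
allowed) to one whole population.

Constant currents stand in for barrages of distant synaptic input via the
diffusion approximation: many small, independent synaptic events sum to an
approximately constant drive, so no extra noise term is attached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _seeds
from .groups import GROUPS, PERTURBABLE_GROUPS
from .network_builder import Network, PopulationSpec

__all__ = [
    "STATE_NAMES",
    "BackgroundSpec",
    "Epoch",
    "StimulusProtocol",
    "select_fraction",
    "background_trains",
    "make_state_protocol",
    "add_perturbation",
]

#: Targets of each named state: list of (group, fraction) pairs.
_STATE_TARGETS: dict[str, list[tuple[str, float]]] = {
    "spontaneous": [],
    "ff": [("E4", 0.25), ("PV4", 0.05)],
    "fb_L5": [("E5", 0.25), ("PV5", 0.05)],
    "fb_L23": [("E23", 0.25), ("PV23", 0.05)],
    "fb_L23_L5": [("E23", 0.25), ("E5", 0.25), ("PV23", 0.05), ("PV5", 0.05)],
    "fb_L6": [("E6", 0.25), ("PV6", 0.05)],
    "fb_L23_L5_L6": [
        ("E23", 0.25), ("PV23", 0.05),
        ("E5", 0.25), ("PV5", 0.05),
        ("E6", 0.25), ("PV6", 0.05),
    ],
}

STATE_NAMES: tuple[str, ...] = tuple(_STATE_TARGETS) + ("ff_fb",)


@dataclass(frozen=True)
class BackgroundSpec:
    """Per-group background Poisson rates, spikes/s.  Every neuron owns an
    independent generator; neurons of one group share the rate only."""

    nu_bg: dict[str, float]

    def __post_init__(self) -> None:
        for g, r in self.nu_bg.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r} in background spec")
            if r < 0:
                raise ValueError(f"negative background rate for {g}")


@dataclass(frozen=True)
class Epoch:
    """One timed DC-current epoch applied to a seeded random subset of a
    population.  ``t_off = inf`` means "until the end of the simulation"."""

    target_group: str
    fraction: float
    amplitude: float        # pA; may be negative
    t_on: float             # ms
    t_off: float = math.inf
    substream_seed: int = 0

    def __post_init__(self) -> None:
        if self.target_group not in GROUPS:
            raise ValueError(f"unknown target group {self.target_group!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if not self.t_off > self.t_on:
            raise ValueError("t_off must exceed t_on")


@dataclass(frozen=True)
class StimulusProtocol:
    """A set of DC epochs; a neuron's external current at time t is the sum
    of all epochs covering it at t."""

    epochs: tuple[Epoch, ...] = ()
    name: str = "custom"

    def resolve(self, network: Network, master_seed: int):
        """Materialize epochs against a concrete network: returns a list of
        (neuron_ids, amplitude, t_on, t_off) tuples.  Target subsets are
        drawn from the target-selection substream of ``master_seed`` keyed
        by each epoch's own seed, so adding an epoch never disturbs the
        targets (or any other random stream) of existing ones.
        """
        resolved = []
        for ep in self.epochs:
            pop = network.population(ep.target_group)
            ids = select_fraction(
                pop, ep.fraction,
                _seeds.substream(master_seed, _seeds.TARGETS,
                                 ep.substream_seed),
            )
            resolved.append((ids, ep.amplitude, ep.t_on, ep.t_off))
        return resolved

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "epochs": [vars(ep).copy() for ep in self.epochs],
        }


def _epoch_seed(group: str, fraction: float) -> int:
    # stable per-(group, fraction) tag: same subset across protocols
    return _seeds.stream_key(f"{group}:{fraction:.6f}")


def select_fraction(
    pop: PopulationSpec,
    fraction: float,
    seed,
) -> np.ndarray:
    """Uniform sample without replacement of ``round(fraction * n)`` neuron
    ids from a population; reproducible under the given seed/generator."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    k = int(round(fraction * pop.n_neurons))
    ids = rng.choice(pop.n_neurons, size=k, replace=False)
    return np.sort(ids) + pop.start


def background_trains(
    spec: BackgroundSpec,
    network: Network,
    duration: float,
    seed: int,
) -> list[np.ndarray]:
    """Independent homogeneous Poisson spike trains, one per neuron, over
    ``[0, duration)`` ms.  These trains feed the background AMPA channel.

    The engine draws background deliveries per time step from the same
    substream family; this explicit-train form serves analyses and tests.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = _seeds.substream(seed, _seeds.BACKGROUND)
    trains = []
    for pop in network.populations:
        rate = spec.nu_bg.get(pop.group_id, pop.params.nu_bg)
        for _ in range(pop.n_neurons):
            n = rng.poisson(rate * duration / 1000.0)
            trains.append(np.sort(rng.uniform(0.0, duration, size=n)))
    return trains


def make_state_protocol(
    name: str,
    amplitude: float = 150.0,
    *,
    onset: float = 700.0,
    ff_onset: float = 500.0,
    fb_onset: float = 1100.0,
    t_off: float = math.inf,
) -> StimulusProtocol:
    """Protocol that puts the column into a named state.

    States: ``spontaneous`` (no drive), ``ff`` (layer 4), the feedback
    variants ``fb_L5``, ``fb_L23``, ``fb_L23_L5``, ``fb_L6``,
    ``fb_L23_L5_L6``, and ``ff_fb`` (FF at ``ff_onset``, FB to layer 5 at
    ``fb_onset``).  Default amplitude 150 pA; single-drive states switch on
    at ``onset`` (default 700 ms).
    """
    if amplitude < 0:
        raise ValueError("state-drive amplitude must be non-negative")
    if name == "ff_fb":
        epochs = [
            Epoch(g, f, amplitude, ff_onset, t_off, _epoch_seed(g, f))
            for g, f in _STATE_TARGETS["ff"]
        ] + [
            Epoch(g, f, amplitude, fb_onset, t_off, _epoch_seed(g, f))
            for g, f in _STATE_TARGETS["fb_L5"]
        ]
    elif name in _STATE_TARGETS:
        epochs = [
            Epoch(g, f, amplitude, onset, t_off, _epoch_seed(g, f))
            for g, f in _STATE_TARGETS[name]
        ]
    else:
        raise ValueError(
            f"unknown state {name!r}; expected one of {sorted(STATE_NAMES)}"
        )
    return StimulusProtocol(epochs=tuple(epochs), name=name)


def add_perturbation(
    base: StimulusProtocol,
    group: str,
    amplitude: float = 30.0,
    *,
    t_on: float = 0.0,
    t_off: float = math.inf,
    fraction: float = 1.0,
) -> StimulusProtocol:
    """Append one perturbation epoch delivering ``amplitude`` pA (negative
    allowed) to the named population, by default to all of its neurons.

    Layer-1 VIP cells are rejected: the perturbation-analysis matrices
    cover the 16 populations of the complete layers only.
    """
    if group not in PERTURBABLE_GROUPS:
        raise ValueError(
            f"{group!r} cannot be perturbed: response matrices cover the 16 "
            "populations of layers 2/3-6 (layer-1 VIP is excluded)"
        )
    ep = Epoch(group, fraction, amplitude, t_on, t_off,
               _epoch_seed(f"perturb:{group}", fraction))
    return StimulusProtocol(
        epochs=base.epochs + (ep,),
        name=f"{base.name}+perturb[{group}@{amplitude:g}pA]",
    )
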