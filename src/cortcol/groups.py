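"""Canonical cell-group labels for the cortical-column model.

The column holds 17 groups: four cell classes (E = pyramidal, PV, SST, VIP)
in each of the four complete layers (2/3, 4, 5, 6) plus a lone VIP group in
layer 1.  All matrix interfaces (connection probabilities, strengths,
Gaussian widths, response matrices) use this fixed, layer-major ordering.
"""

from __future__ import annotations

#: Canonical group order: layer-major (L1, L2/3, L4, L5, L6), within a
#: layer E, PV, SST, VIP.
GROUPS: tuple[str, ...] = (
    "VIP1",
    "E23", "PV23", "SST23", "VIP23",
    "E4", "PV4", "SST4", "VIP4",
    "E5", "PV5", "SST5", "VIP5",
    "E6", "PV6", "SST6", "VIP6",
)

#: The 16 groups that can be perturbed / observed in response matrices
#: (layer-1 VIP is excluded; the published matrices are 16 x 16).
PERTURBABLE_GROUPS: tuple[str, ...] = tuple(g for g in GROUPS if g != "VIP1")

#: Excitatory (pyramidal) groups; all spikes from these target AMPA/NMDA.
EXCITATORY_GROUPS: tuple[str, ...] = ("E23", "E4", "E5", "E6")

#: Inhibitory interneuron groups; their output is GABA-A only.
INHIBITORY_GROUPS: tuple[str, ...] = tuple(
    g for g in GROUPS if g not in EXCITATORY_GROUPS
)

#: Complete layers (holding all four cell classes).
COMPLETE_LAYERS: tuple[str, ...] = ("23", "4", "5", "6")


def is_excitatory(group: str) -> bool:
    return group in EXCITATORY_GROUPS


def layer_of(group: str) -> str:
    """Layer tag of a group label, e.g. ``'E23' -> '23'``, ``'VIP1' -> '1'``."""
    for prefix in ("E", "PV", "SST", "VIP"):
        if group.startswith(prefix):
            return group[len(prefix):]
    raise ValueError(f"unknown group label: {group!r}")


def cell_class_of(group: str) -> str:
    """Cell class of a group label, e.g. ``'SST5' -> 'SST'``."""
    for prefix in ("VIP", "SST", "PV", "E"):
        if group.startswith(prefix):
            return prefix
    raise ValueError(f"unknown group label: {group!r}")


def validate_labels(labels) -> None:
    """Check that *labels* is exactly the canonical 17-group set, in order."""
    labels = list(labels)
    if labels != list(GROUPS):
        missing = sorted(set(GROUPS) - set(labels))
        extra = sorted(set(labels) - set(GROUPS))
        raise ValueError(
            "group labels do not match the canonical 17-group order; "
            f"missing={missing}, unexpected={extra}, got={labels}"
        )
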