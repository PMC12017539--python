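"""File interfaces, configuration handling and the synthetic column generator.

A *column bundle* is everything needed to build the network: the 17x17
connection-probability matrix P, the strength matrix S (mV), the Gaussian
widths sigma (um) — all labelled CSV, rows = presynaptic group, columns =
postsynaptic group, in canonical order — plus a YAML parameter file with
one block per group (V_rest, V_th, C_m, g_L, tau_ref, nu_bg), the
population fractions and a global block (G, nmda_fraction, Mg, radii).

The reference matrices from the Allen Institute portal are an OPTIONAL
user-supplied input in exactly this layout; nothing is downloaded.
:func:`synthetic_bundle` generates a fully self-contained column with the
same structure — canonical microcircuit motifs, an 85/15 E/I split per
complete layer, and background rates placing each group in a
fluctuation-driven, low-rate regime — so every part of the package is
testable offline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import _seeds
from .groups import (
    COMPLETE_LAYERS,
    GROUPS,
    cell_class_of,
    layer_of,
    validate_labels,
)
from .model_core import CellTypeParams, SynapseKinetics
from .network_builder import ConnectivitySpec
from .stimulation import BackgroundSpec

__all__ = [
    "ColumnBundle",
    "read_bundle",
    "write_bundle",
    "synthetic_bundle",
    "write_spikes_csv",
    "write_matrix_csv",
    "write_record_h5",
]

_PARAM_KEYS = ("V_rest", "V_th", "C_m", "g_L", "tau_ref", "nu_bg")
_GLOBAL_DEFAULTS = {
    "G": 5.0, "nmda_fraction": 0.2, "R": 125.0, "R0": 75.0,
    "Mg": 1.0, "dt": 0.1,
}


@dataclass
class ColumnBundle:
    """Validated group-level description of one column."""

    P: pd.DataFrame
    S: pd.DataFrame
    sigma: pd.DataFrame
    params: dict[str, CellTypeParams]
    fractions: pd.Series
    globals: dict = field(default_factory=dict)
    provenance: str = "user-supplied"

    def __post_init__(self) -> None:
        for name, m in (("P", self.P), ("S", self.S), ("sigma", self.sigma)):
            try:
                validate_labels(m.index)
                validate_labels(m.columns)
            except ValueError as err:
                raise ValueError(f"{name} matrix: {err}") from None
        p = self.P.to_numpy(float)
        bad = np.argwhere(~np.isfinite(p) | (p < 0) | (p > 1))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"P[{self.P.index[i]}, {self.P.columns[j]}] = {p[i, j]} "
                "is not a probability in [0, 1]"
            )
        sig = self.sigma.to_numpy(float)
        bad = np.argwhere((p > 0) & ~(sig > 0))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"sigma[{self.sigma.index[i]}, {self.sigma.columns[j]}] must "
                "be positive where P > 0"
            )
        missing = [g for g in GROUPS if g not in self.params]
        if missing:
            raise ValueError(f"cell parameters missing for groups {missing}")
        self.fractions = pd.Series(self.fractions, dtype=float).reindex(
            list(GROUPS)
        )
        if self.fractions.isna().any():
            missing = list(self.fractions.index[self.fractions.isna()])
            raise ValueError(f"population fractions missing for {missing}")
        g = dict(_GLOBAL_DEFAULTS)
        g.update(self.globals)
        self.globals = g

    def connectivity_spec(self) -> ConnectivitySpec:
        return ConnectivitySpec(
            P=self.P, S=self.S, sigma=self.sigma,
            G=float(self.globals["G"]),
            nmda_fraction=float(self.globals["nmda_fraction"]),
            R=float(self.globals["R"]), R0=float(self.globals["R0"]),
        )

    def kinetics(self) -> SynapseKinetics:
        return SynapseKinetics(Mg=float(self.globals["Mg"]))

    def background_spec(self) -> BackgroundSpec:
        return BackgroundSpec(
            {g: p.nu_bg for g, p in self.params.items()}
        )


def _read_matrix(path: Path, name: str) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    non_numeric = df.map(
        lambda v: not (pd.isna(v) or isinstance(v, (int, float, np.number)))
    )
    if non_numeric.to_numpy().any():
        i, j = np.argwhere(non_numeric.to_numpy())[0]
        raise ValueError(
            f"{name}[{df.index[i]}, {df.columns[j]}] is not numeric: "
            f"{df.iat[i, j]!r}"
        )
    return df.astype(float)


def read_bundle(directory) -> ColumnBundle:
    """Read and validate a bundle from ``P.csv``, ``S.csv``, ``sigma.csv``
    and ``params.yaml`` in *directory*."""
    d = Path(directory)
    for f in ("P.csv", "S.csv", "sigma.csv", "params.yaml"):
        if not (d / f).exists():
            raise FileNotFoundError(f"bundle file missing: {d / f}")
    P = _read_matrix(d / "P.csv", "P")
    S = _read_matrix(d / "S.csv", "S")
    sigma = _read_matrix(d / "sigma.csv", "sigma")
    cfg = yaml.safe_load((d / "params.yaml").read_text())
    params = {}
    for g, block in cfg.get("groups", {}).items():
        missing = [k for k in _PARAM_KEYS if k not in block]
        if missing:
            raise ValueError(f"group {g}: missing parameters {missing}")
        params[g] = CellTypeParams(group_id=g,
                                   **{k: float(block[k]) for k in _PARAM_KEYS})
    return ColumnBundle(
        P=P, S=S, sigma=sigma, params=params,
        fractions=pd.Series(cfg.get("fractions", {}), dtype=float),
        globals=cfg.get("global", {}),
        provenance=str(cfg.get("provenance", "user-supplied")),
    )


def write_bundle(bundle: ColumnBundle, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    bundle.P.to_csv(d / "P.csv")
    bundle.S.to_csv(d / "S.csv")
    bundle.sigma.to_csv(d / "sigma.csv")
    cfg = {
        "provenance": bundle.provenance,
        "global": {k: float(v) for k, v in bundle.globals.items()},
        "fractions": {g: float(v) for g, v in bundle.fractions.items()},
        "groups": {
            g: {k: float(getattr(p, k)) for k in _PARAM_KEYS}
            for g, p in bundle.params.items()
        },
    }
    (d / "params.yaml").write_text(
        yaml.safe_dump(cfg, sort_keys=False, default_flow_style=False)
    )


# ---------------------------------------------------------------------------
# synthetic column
# ---------------------------------------------------------------------------

#: Layer shares of the total population (layer 1 holds only VIP cells).
_LAYER_SHARE = {"1": 0.016, "23": 0.29, "4": 0.24, "5": 0.23, "6": 0.224}
#: Cell-class split inside a complete layer (E is 85% by construction).
_CLASS_SHARE = {"E": 0.85, "PV": 0.07, "SST": 0.05, "VIP": 0.03}

#: Within-layer connection-probability motif (pre class -> post class),
#: before the uniform-disk correction.
_P_LOCAL = {
    ("E", "E"): 0.12, ("E", "PV"): 0.30, ("E", "SST"): 0.20,
    ("E", "VIP"): 0.15,
    ("PV", "E"): 0.35, ("PV", "PV"): 0.25, ("PV", "SST"): 0.05,
    ("PV", "VIP"): 0.10,
    ("SST", "E"): 0.25, ("SST", "PV"): 0.20, ("SST", "SST"): 0.05,
    ("SST", "VIP"): 0.25,
    ("VIP", "E"): 0.05, ("VIP", "PV"): 0.08, ("VIP", "SST"): 0.30,
    ("VIP", "VIP"): 0.05,
}

#: Within-layer strength motif (mV).
_S_LOCAL = {
    ("E", "E"): 0.5, ("E", "PV"): 0.8, ("E", "SST"): 0.5, ("E", "VIP"): 0.4,
    ("PV", "E"): 1.5, ("PV", "PV"): 1.0, ("PV", "SST"): 0.4,
    ("PV", "VIP"): 0.5,
    ("SST", "E"): 1.2, ("SST", "PV"): 0.8, ("SST", "SST"): 0.3,
    ("SST", "VIP"): 0.8,
    ("VIP", "E"): 0.3, ("VIP", "PV"): 0.4, ("VIP", "SST"): 1.0,
    ("VIP", "VIP"): 0.3,
}

#: Cross-layer motifs (pre group, post group) -> (p, ws).  Excitation climbs
#: the canonical feedforward chain L4 -> L2/3 -> L5 -> L6; layer-5 and
#: layer-6 pyramidal cells recruit inhibition in other layers (translaminar
#: gain control), and layer-1 VIP cells disinhibit via SST targets.
_CROSS = {
    ("E4", "E23"): (0.15, 0.8), ("E23", "E5"): (0.15, 0.8),
    ("E5", "E6"): (0.02, 0.2), ("E4", "E5"): (0.08, 0.5),
    ("E23", "E6"): (0.09, 0.6), ("E4", "E6"): (0.08, 0.5),
    ("E5", "PV23"): (0.12, 1.0), ("E5", "SST23"): (0.10, 0.8),
    ("E5", "PV4"): (0.15, 1.2), ("E5", "SST4"): (0.10, 0.8),
    ("E5", "PV6"): (0.12, 1.0), ("E5", "SST6"): (0.10, 0.8),
    ("E5", "E23"): (0.02, 0.2), ("E5", "E4"): (0.01, 0.15),
    ("E6", "PV23"): (0.06, 0.5), ("E6", "PV4"): (0.06, 0.5),
    ("E6", "PV5"): (0.06, 0.5), ("E6", "E4"): (0.03, 0.3),
    ("E23", "PV5"): (0.05, 0.4), ("E23", "PV6"): (0.04, 0.3),
    ("VIP1", "SST23"): (0.15, 0.8), ("VIP1", "SST4"): (0.10, 0.6),
    ("VIP1", "SST5"): (0.10, 0.6), ("VIP1", "SST6"): (0.08, 0.5),
    ("E23", "VIP1"): (0.08, 0.4), ("E4", "VIP1"): (0.04, 0.3),
    ("E5", "VIP1"): (0.06, 0.4), ("SST23", "VIP1"): (0.10, 0.6),
}

#: Class-level electrophysiology templates (mV, pF, nS, ms) and the
#: background operating point c = mean background current / rheobase.
_CELL_TEMPLATES = {
    "E":   dict(V_rest=-70.0, V_th=-50.0, C_m=200.0, g_L=10.0, tau_ref=2.0,
                c_bg=0.95),
    "PV":  dict(V_rest=-72.0, V_th=-52.0, C_m=100.0, g_L=10.0, tau_ref=1.0,
                c_bg=1.05),
    "SST": dict(V_rest=-65.0, V_th=-47.0, C_m=120.0, g_L=8.0, tau_ref=1.5,
                c_bg=1.0),
    "VIP": dict(V_rest=-68.0, V_th=-50.0, C_m=90.0, g_L=7.0, tau_ref=1.5,
                c_bg=1.0),
}


def synthetic_bundle(seed: int, regime: str = "sparse") -> ColumnBundle:
    """Seeded synthetic column with the structure of the reference data.

    17 named groups with an exact 85/15 E/I split per complete layer;
    probabilities in [0, 0.3] ("dense" scales them by 1.5), stronger within
    than across layers and arranged in canonical microcircuit motifs
    (feedforward excitatory chain, translaminar inhibition recruited by
    deep-layer pyramidal cells, VIP->SST disinhibition); strengths in
    [0.1, 2] mV; Gaussian widths in [50, 300] um; per-group LIF parameters
    in physiological ranges; background rates set so that every group fires
    at a low, fluctuation-driven rate.  Fully reproducible under ``seed``.
    """
    if regime not in ("sparse", "dense"):
        raise ValueError("regime must be 'sparse' or 'dense'")
    rng = _seeds.substream(seed, "synthetic")
    scale = 1.5 if regime == "dense" else 1.0

    idx = list(GROUPS)
    P = pd.DataFrame(0.0, index=idx, columns=idx)
    S = pd.DataFrame(np.nan, index=idx, columns=idx)
    sigma = pd.DataFrame(0.0, index=idx, columns=idx)

    def jitter():
        return rng.uniform(0.85, 1.15)

    for pre in GROUPS:
        for post in GROUPS:
            lp, lq = layer_of(pre), layer_of(post)
            cp, cq = cell_class_of(pre), cell_class_of(post)
            if (pre, post) in _CROSS:
                p0, w0 = _CROSS[(pre, post)]
            elif lp == lq and lp != "1":
                p0, w0 = _P_LOCAL[(cp, cq)], _S_LOCAL[(cp, cq)]
            elif pre == "VIP1" and post == "VIP1":
                p0, w0 = 0.0, np.nan   # the one undefined strength entry
            elif cp == "E" and cq == "E":
                p0, w0 = 0.01, 0.15    # weak residual excitatory scaffold
            else:
                p0, w0 = 0.0, 0.1
            p = min(p0 * scale * jitter(), 1.0) if p0 > 0 else 0.0
            P.loc[pre, post] = p
            if not (pre == "VIP1" and post == "VIP1"):
                S.loc[pre, post] = (np.clip(w0 * jitter(), 0.1, 2.0)
                                    if np.isfinite(w0) else np.nan)
            # narrower profiles within a layer, broader across
            lo, hi = (50.0, 150.0) if lp == lq else (120.0, 300.0)
            sigma.loc[pre, post] = rng.uniform(lo, hi)

    fractions = {}
    for g in GROUPS:
        if g == "VIP1":
            fractions[g] = _LAYER_SHARE["1"]
        else:
            fractions[g] = (_LAYER_SHARE[layer_of(g)]
                            * _CLASS_SHARE[cell_class_of(g)])

    kin = SynapseKinetics()
    params = {}
    for g in GROUPS:
        t = _CELL_TEMPLATES[cell_class_of(g)]
        V_rest = t["V_rest"] + rng.uniform(-1.0, 1.0)
        V_th = t["V_th"] + rng.uniform(-1.0, 1.0)
        C_m = t["C_m"] * rng.uniform(0.9, 1.1)
        g_L = t["g_L"] * rng.uniform(0.9, 1.1)
        # mean background current c_bg * rheobase at the mid-point voltage:
        # nu [spk/s] such that g_AMPA * nu * tau_AMPA * |V_mid| matches it
        V_mid = 0.5 * (V_rest + V_th)
        rheobase = g_L * (V_th - V_rest)
        nu = (t["c_bg"] * rheobase * 1000.0
              / (kin.g_AMPA * kin.tau_AMPA * abs(V_mid)))
        params[g] = CellTypeParams(
            group_id=g, V_rest=V_rest, V_th=V_th, C_m=C_m, g_L=g_L,
            tau_ref=t["tau_ref"], nu_bg=nu,
        )

    return ColumnBundle(
        P=P, S=S, sigma=sigma, params=params,
        fractions=pd.Series(fractions), globals=dict(_GLOBAL_DEFAULTS),
        provenance="synthetic",
    )


# ---------------------------------------------------------------------------
# output writers
# ---------------------------------------------------------------------------

def write_spikes_csv(record, path) -> None:
    """Spike output: CSV with header ``neuron_id,group,time_ms``."""
    record.spikes_dataframe().to_csv(path, index=False)


def write_matrix_csv(matrix: pd.DataFrame, path) -> None:
    """Labelled matrix CSV (full precision round-trips)."""
    matrix.to_csv(path)


def write_record_h5(record, path) -> None:
    """HDF5 container holding spikes, voltage samples and the config echo."""
    with h5py.File(path, "w") as f:
        f.create_dataset("spikes/neuron_id", data=record.spike_neurons)
        f.create_dataset("spikes/time_ms", data=record.spike_times)
        f.create_dataset("group_index", data=record.group_index)
        f.attrs["group_names"] = list(record.group_names)
        f.attrs["duration_ms"] = record.duration
        f.attrs["dt_ms"] = record.dt
        f.attrs["config_echo"] = json.dumps(record.config_echo)
        if record.voltage is not None:
            f.create_dataset("voltage/time_ms", data=record.voltage_times)
            f.create_dataset("voltage/V_mV", data=record.voltage)
            f.create_dataset("voltage/neuron_id", data=record.voltage_neurons)
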