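"""Construction of the 17-group cortical column.

Takes group-level connectivity data — a 17x17 connection-probability matrix
P, a synaptic-strength matrix S (mV) and per-connection Gaussian widths
sigma (um) — plus per-group cell parameters, and realizes a concrete
network: integer population sizes, Bernoulli neuron-to-neuron synapses with
an AMPA/NMDA receptor split for excitatory projections, and dimensionless
synapse weights

    w = G . ws / (N_send . p)

which keep the expected summed input from any source group (N_send . p . w
= G . ws) invariant under changes of the total network size.

Because the reported probabilities correspond to a Gaussian connectivity
profile measured over a disk of radius R0 = 75 um while the model column
represents a uniform disk of radius R = 125 um, probabilities are first
translated to uniform-disk values (:func:`correct_probability`).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _seeds
from .groups import (
    EXCITATORY_GROUPS,
    GROUPS,
    is_excitatory,
    layer_of,
    validate_labels,
)
from .model_core import CellTypeParams, SynapseKinetics

__all__ = [
    "PopulationSpec",
    "ConnectivitySpec",
    "SYNAPSE_COLUMNS",
    "build_populations",
    "correct_probability",
    "correct_probability_matrix",
    "compute_weight",
    "realize_connectivity",
    "lognormalize_weights",
    "lesion_inhibitory_output",
    "Network",
    "build_network",
]

#: Column schema of a realized synapse table (one row per synapse).
SYNAPSE_COLUMNS = ("pre", "post", "receptor", "weight")


@dataclass(frozen=True)
class PopulationSpec:
    """One realized population: label, size, parameters and the half-open
    global neuron-id range ``[start, start + n_neurons)``."""

    group_id: str
    n_neurons: int
    params: CellTypeParams
    start: int = 0

    @property
    def ids(self) -> np.ndarray:
        return np.arange(self.start, self.start + self.n_neurons)


@dataclass(frozen=True)
class ConnectivitySpec:
    """Group-level connectivity: P (probabilities), S (strengths, mV),
    sigma (Gaussian widths, um), the global coupling G (mV^-1), the NMDA
    share of excitatory contacts, and the disk radii used for the
    probability translation.

    Matrices are 17x17 labelled DataFrames, rows = presynaptic group,
    columns = postsynaptic group.  Undefined strengths (the reference S
    matrix carries 288 of 289 entries) are stored as NaN and treated as 0.
    """

    P: pd.DataFrame
    S: pd.DataFrame
    sigma: pd.DataFrame
    G: float = 5.0
    nmda_fraction: float = 0.2
    R: float = 125.0
    R0: float = 75.0

    def __post_init__(self) -> None:
        for name, m in (("P", self.P), ("S", self.S), ("sigma", self.sigma)):
            validate_labels(m.index)
            validate_labels(m.columns)
        p = self.P.to_numpy(dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            i, j = np.argwhere((p < 0) | (p > 1))[0]
            raise ValueError(
                f"connection probability out of [0, 1] for "
                f"{self.P.index[i]} -> {self.P.columns[j]}: {p[i, j]}"
            )
        if self.G <= 0:
            raise ValueError("global coupling G must be positive")
        if not 0.0 <= self.nmda_fraction <= 1.0:
            raise ValueError("nmda_fraction must lie in [0, 1]")
        if self.R <= 0 or self.R0 <= 0:
            raise ValueError("disk radii must be positive")

    @property
    def n_defined_strengths(self) -> int:
        """Number of non-NaN entries of S (288 in the reference data)."""
        return int(self.S.notna().to_numpy().sum())


def build_populations(
    fractions,
    N_total: int,
    params_table: dict[str, CellTypeParams],
) -> list[PopulationSpec]:
    """Integer population sizes for all 17 groups.

    ``fractions`` maps group label -> fraction of ``N_total`` (must sum to
    1).  Counts are assigned by the largest-remainder method (ties broken by
    canonical group order) so they sum exactly to ``N_total``; every group
    with a positive fraction is guaranteed at least one neuron.
    """
    fractions = pd.Series(fractions, dtype=float).reindex(list(GROUPS))
    if fractions.isna().any():
        missing = list(fractions.index[fractions.isna()])
        raise ValueError(f"missing population fractions for groups {missing}")
    total = float(fractions.sum())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"population fractions sum to {total}, expected 1")
    if N_total < len(GROUPS):
        raise ValueError("N_total must be at least 17 (one neuron per group)")

    exact = fractions.to_numpy() * N_total
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    short = N_total - int(counts.sum())
    # stable sort keeps canonical order among equal remainders
    for idx in np.argsort(-remainder, kind="stable")[:short]:
        counts[idx] += 1
    # every declared group non-empty: borrow from the largest group
    declared = fractions.to_numpy() > 0
    while np.any(declared & (counts == 0)):
        counts[int(np.argmax(counts))] -= 1
        counts[int(np.flatnonzero(declared & (counts == 0))[0])] += 1

    pops, start = [], 0
    for g, n in zip(GROUPS, counts):
        if g not in params_table:
            raise ValueError(f"no cell parameters supplied for group {g}")
        pops.append(PopulationSpec(g, int(n), params_table[g], start))
        start += int(n)
    return pops


def correct_probability(p_rep, sigma, R: float = 125.0, R0: float = 75.0):
    """Translate a reported connection probability to a uniform-disk value.

    The reported probability ``p_rep`` is the disk-average over radius R0 of
    a Gaussian connectivity profile ``A exp(-r^2 / sigma^2)``.  The returned
    value is the average of the same profile over the model column's disk of
    radius R:

        P_new = p_rep (R0^2 / R^2) (1 - e^{-R^2/sigma^2})
                                 / (1 - e^{-R0^2/sigma^2})

    For R > R0 this shrinks the probability, down to the factor (R0/R)^2 for
    narrow profiles and back to p_rep for flat (sigma -> inf) ones.  The
    result is clamped to [0, 1].
    """
    if R <= 0 or R0 <= 0:
        raise ValueError("disk radii must be positive")
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    p_rep = np.asarray(p_rep, dtype=float)
    num = -np.expm1(-(R / sigma) ** 2)
    den = -np.expm1(-(R0 / sigma) ** 2)
    out = np.clip(p_rep * (R0 / R) ** 2 * num / den, 0.0, 1.0)
    return out if out.ndim else float(out)


def correct_probability_matrix(spec: ConnectivitySpec) -> pd.DataFrame:
    """Apply :func:`correct_probability` entrywise using the per-connection
    Gaussian widths; entries without a defined width pass through unchanged."""
    P = spec.P.to_numpy(dtype=float)
    sig = spec.sigma.to_numpy(dtype=float)
    ok = np.isfinite(sig) & (sig > 0)
    out = P.copy()
    out[ok] = correct_probability(P[ok], sig[ok], spec.R, spec.R0)
    return pd.DataFrame(out, index=spec.P.index, columns=spec.P.columns)


def compute_weight(G: float, ws: float, N_send: int, p: float) -> float:
    """Dimensionless synapse weight w = G ws / (N_send p).

    Shared by all realized synapses of one group pair; the 1/(N_send p)
    normalization makes the expected group-level input size-invariant.
    """
    if N_send < 1:
        raise ValueError("N_send must be at least 1")
    if p <= 0:
        if ws != 0:
            raise ValueError(
                "connection declared (ws != 0) but impossible (p = 0)"
            )
        return 0.0
    return G * ws / (N_send * p)


def realize_connectivity(
    pops: list[PopulationSpec],
    spec: ConnectivitySpec,
    seed: int,
) -> pd.DataFrame:
    """Draw the neuron-to-neuron synapse table.

    Probabilities in ``spec.P`` are taken as already corrected to
    uniform-disk values.  For every ordered group pair each neuron pair is
    an independent Bernoulli trial; excitatory projections are drawn
    separately for AMPA contacts (probability ``p * (1 - nmda_fraction)``)
    and NMDA contacts (``p * nmda_fraction``); inhibitory projections are
    drawn once for GABA (probability ``p``).  Autapses are excluded.  All
    synapses of a pair carry the weight from :func:`compute_weight` (based
    on the undivided pair probability ``p``).
    """
    by_name = {p.group_id: p for p in pops}
    for g in spec.P.index:
        if g not in by_name:
            raise ValueError(f"group {g} in P has no realized population")
    rng = _seeds.substream(seed, _seeds.CONNECTIVITY)

    pre_rows: list[np.ndarray] = []
    post_rows: list[np.ndarray] = []
    rec_rows: list[np.ndarray] = []
    w_rows: list[np.ndarray] = []

    def _draw(pre_pop, post_pop, prob, receptor, weight):
        block = rng.random((pre_pop.n_neurons, post_pop.n_neurons)) < prob
        if pre_pop.group_id == post_pop.group_id:
            np.fill_diagonal(block, False)
        i, j = np.nonzero(block)
        if i.size:
            pre_rows.append(i + pre_pop.start)
            post_rows.append(j + post_pop.start)
            rec_rows.append(np.full(i.size, receptor, dtype=object))
            w_rows.append(np.full(i.size, weight, dtype=float))

    for pre_name in GROUPS:
        pre_pop = by_name[pre_name]
        exc = is_excitatory(pre_name)
        for post_name in GROUPS:
            p = float(spec.P.loc[pre_name, post_name])
            ws = spec.S.loc[pre_name, post_name]
            ws = 0.0 if pd.isna(ws) else float(ws)
            if p <= 0:
                continue
            post_pop = by_name[post_name]
            if pre_pop.n_neurons == 0 or post_pop.n_neurons == 0:
                continue
            w = compute_weight(spec.G, ws, pre_pop.n_neurons, p)
            if exc:
                f = spec.nmda_fraction
                # independent draws per receptor channel of the same pair
                _draw(pre_pop, post_pop, p * (1.0 - f), "AMPA", w)
                _draw(pre_pop, post_pop, p * f, "NMDA", w)
            else:
                _draw(pre_pop, post_pop, p, "GABA", w)

    if not pre_rows:
        return pd.DataFrame(
            {
                "pre": np.array([], dtype=np.int64),
                "post": np.array([], dtype=np.int64),
                "receptor": pd.Series([], dtype=object),
                "weight": np.array([], dtype=float),
            }
        )
    return pd.DataFrame(
        {
            "pre": np.concatenate(pre_rows),
            "post": np.concatenate(post_rows),
            "receptor": np.concatenate(rec_rows),
            "weight": np.concatenate(w_rows),
        }
    )


def lognormalize_weights(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Replace each nonzero weight by an independent lognormal draw whose
    arithmetic mean equals the original weight and whose arithmetic SD
    equals that mean (so SD/mean = 1; lognormal parameters
    sigma_log^2 = ln 2, mu_log = ln(mean) - sigma_log^2 / 2).

    Zero weights stay zero; receptor assignment and topology are unchanged.
    """
    w = table["weight"].to_numpy(dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    rng = _seeds.substream(seed, _seeds.WEIGHTS)
    out = table.copy()
    nz = w > 0
    sigma2 = np.log(2.0)
    mu = np.log(w[nz]) - sigma2 / 2.0
    draws = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2))
    new_w = w.copy()
    new_w[nz] = draws
    out["weight"] = new_w
    return out


def lesion_inhibitory_output(table: pd.DataFrame) -> pd.DataFrame:
    """Remove all GABA synapses (block inhibitory output) while leaving the
    inhibitory neurons in place, still receiving input and able to spike."""
    return table[table["receptor"] != "GABA"].reset_index(drop=True)


@dataclass
class Network:
    """A fully realized column: populations, per-neuron parameter arrays,
    the synapse table, and the kinetics shared by all synapses."""

    populations: list[PopulationSpec]
    synapses: pd.DataFrame
    kinetics: SynapseKinetics
    spec: ConnectivitySpec
    seed: int

    group_index: np.ndarray = field(init=False)
    V_rest: np.ndarray = field(init=False)
    V_th: np.ndarray = field(init=False)
    C_m: np.ndarray = field(init=False)
    g_L: np.ndarray = field(init=False)
    tau_ref: np.ndarray = field(init=False)
    nu_bg: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n = self.n_neurons
        self.group_index = np.empty(n, dtype=np.int16)
        arrays = {k: np.empty(n) for k in
                  ("V_rest", "V_th", "C_m", "g_L", "tau_ref", "nu_bg")}
        for gi, pop in enumerate(self.populations):
            sl = slice(pop.start, pop.start + pop.n_neurons)
            self.group_index[sl] = gi
            for k in arrays:
                arrays[k][sl] = getattr(pop.params, k)
        for k, v in arrays.items():
            setattr(self, k, v)

    @property
    def n_neurons(self) -> int:
        return sum(p.n_neurons for p in self.populations)

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(p.group_id for p in self.populations)

    def population(self, group_id: str) -> PopulationSpec:
        for p in self.populations:
            if p.group_id == group_id:
                return p
        raise KeyError(group_id)

    def counts(self) -> pd.Series:
        return pd.Series(
            {p.group_id: p.n_neurons for p in self.populations}, name="n"
        )

    @property
    def excitatory_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_neurons, dtype=bool)
        for p in self.populations:
            if is_excitatory(p.group_id):
                mask[p.start:p.start + p.n_neurons] = True
        return mask

    def network_hash(self) -> str:
        """Digest of sizes, parameters and the synapse table; two networks
        with equal hashes produce identical simulations under equal seeds."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.group_index).tobytes())
        for k in ("V_rest", "V_th", "C_m", "g_L", "tau_ref", "nu_bg"):
            h.update(np.ascontiguousarray(getattr(self, k)).tobytes())
        for col in SYNAPSE_COLUMNS:
            h.update(np.ascontiguousarray(
                self.synapses[col].to_numpy(dtype="U8" if col == "receptor"
                                            else None)).tobytes())
        return h.hexdigest()[:16]


def build_network(
    bundle,
    N_total: int = 5000,
    seed: int = 0,
    kinetics: SynapseKinetics | None = None,
    correct_probabilities: bool = True,
    lognormal_weights: bool = False,
    lesion_inhibition: bool = False,
) -> Network:
    """Build a :class:`Network` from a column bundle (see
    :func:`cortcol.io.read_bundle` / :func:`cortcol.io.synthetic_bundle`).

    ``correct_probabilities`` applies the disk translation of
    :func:`correct_probability` (on by default, matching data reported at
    the reference radius); ``lognormal_weights`` switches on the
    broad-weight variant and ``lesion_inhibition`` removes all GABA output.
    """
    kin = kinetics if kinetics is not None else bundle.kinetics()
    spec = bundle.connectivity_spec()
    if correct_probabilities:
        spec = ConnectivitySpec(
            P=correct_probability_matrix(spec), S=spec.S, sigma=spec.sigma,
            G=spec.G, nmda_fraction=spec.nmda_fraction, R=spec.R, R0=spec.R0,
        )
    pops = build_populations(bundle.fractions, N_total, bundle.params)
    table = realize_connectivity(pops, spec, seed)
    if lognormal_weights:
        table = lognormalize_weights(table, seed)
    if lesion_inhibition:
        table = lesion_inhibitory_output(table)
    return Network(
        populations=pops, synapses=table, kinetics=kin, spec=spec, seed=seed
    )
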