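"""Statistics computed from spikes and membrane-potential traces.

Covers population mean rates over fixed windows, sliding-window rate
traces, inter-spike-interval irregularity (CV), the Golomb-Rinzel
voltage-based synchrony measure, Welch power spectra, and the
perturbation-analysis bookkeeping: 16x16 percent-change response matrices
R_XY (perturbed group Y on rows, observed group X on columns), their
categorical (-1/0/+1, threshold 20%) and comparison views, marked-change
counts, and Frobenius distances between matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .groups import PERTURBABLE_GROUPS
from .engine import SimulationRecord

__all__ = [
    "ResponseMatrix",
    "mean_rates",
    "rate_trace",
    "isi_cv",
    "synchrony_chi",
    "power_spectrum",
    "response_matrix",
    "categorize",
    "compare_categorical",
    "numeric_difference",
    "count_marked",
    "frobenius_distance",
    "pairwise_frobenius",
]


@dataclass
class ResponseMatrix:
    """Percent-change response matrix plus provenance.

    ``values[Y, X]`` is the percent change of population X's mean rate when
    population Y is perturbed.  Entries with zero baseline are undefined:
    they are NaN in ``values`` and flagged in ``undefined`` (never silently
    zero).  The diagonal is excluded from categorical counts.
    """

    values: pd.DataFrame
    baseline: pd.Series
    perturbed: pd.DataFrame          # rows = perturbed group, cols = observed
    threshold: float = 20.0
    undefined: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if self.undefined is None:
            self.undefined = self.values.isna()

    @property
    def labels(self) -> list[str]:
        return list(self.values.index)

    def diagonal_mask(self) -> pd.DataFrame:
        eye = np.eye(len(self.values), dtype=bool)
        return pd.DataFrame(eye, index=self.values.index,
                            columns=self.values.columns)


def mean_rates(
    record: SimulationRecord,
    window: tuple[float, float],
) -> pd.Series:
    """Per-group mean firing rate (spikes/s) over ``window = (t0, t1)`` ms:
    total group spikes in the window / (n_neurons * window length)."""
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("empty measurement window")
    in_win = (record.spike_times >= t0) & (record.spike_times < t1)
    gi = record.group_index[record.spike_neurons[in_win]]
    counts = np.bincount(gi, minlength=len(record.group_names))
    rates = counts / (record.group_counts * (t1 - t0) / 1000.0)
    return pd.Series(rates, index=list(record.group_names), name="rate_hz")


def rate_trace(
    record: SimulationRecord,
    group: str,
    window_ms: float = 100.0,
    step_ms: float = 1.0,
) -> pd.Series:
    """Sliding-window population rate (spikes/s) for one group.

    The window is centred on each time point, so a step input produces a
    rise that begins half a window before its onset.
    """
    if window_ms < step_ms:
        raise ValueError("window must be at least one step wide")
    gi = record.group_names.index(group)
    n = int(record.group_counts[gi])
    times = record.spike_times[
        record.group_index[record.spike_neurons] == gi
    ]
    edges = np.arange(0.0, record.duration + step_ms, step_ms)
    counts, _ = np.histogram(times, bins=edges)
    k = max(int(round(window_ms / step_ms)), 1)
    kernel = np.ones(k)
    smoothed = np.convolve(counts, kernel, mode="same")
    rate = smoothed / (n * k * step_ms / 1000.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.Series(rate, index=centers, name=f"rate_{group}")


def isi_cv(
    record: SimulationRecord,
    group: str,
    min_spikes: int = 3,
) -> tuple[pd.Series, float]:
    """Coefficient of variation of inter-spike intervals, per neuron.

    Neurons with fewer than ``min_spikes`` spikes are excluded (a CV needs
    at least two intervals).  Returns the per-neuron CVs and their mean
    (NaN when no neuron qualifies).
    """
    trains = record.spike_trains(group)
    cvs = {}
    for nid, t in trains.items():
        if t.size < min_spikes:
            continue
        isi = np.diff(t)
        m = isi.mean()
        cvs[nid] = isi.std() / m if m > 0 else np.nan
    out = pd.Series(cvs, dtype=float, name="cv_isi")
    return out, (float(out.mean()) if len(out) else float("nan"))


def synchrony_chi(voltage: np.ndarray) -> float:
    """Population synchrony from membrane-potential traces (Golomb-Rinzel).

    chi^2 = Var_t( mean_i V_i(t) ) / mean_i( Var_t V_i(t) ); returns chi in
    [0, 1]: 1 for identical traces, -> 0 for independent fluctuations.
    NaN is returned when the traces carry no temporal variance.
    """
    V = np.asarray(voltage, dtype=float)
    if V.ndim != 2 or V.shape[1] < 2:
        raise ValueError("need at least two equal-length voltage traces")
    per_neuron_var = V.var(axis=0).mean()
    if per_neuron_var == 0:
        return float("nan")
    return float(np.sqrt(V.mean(axis=1).var() / per_neuron_var))


def power_spectrum(
    trace,
    step_ms: float = 1.0,
    segment_ms: float = 1000.0,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch periodogram of a uniformly sampled rate trace (mean removed,
    Hann window, 50%-overlapping segments of ``segment_ms``)."""
    x = np.asarray(trace, dtype=float)
    nperseg = int(round(segment_ms / step_ms))
    if x.size < nperseg:
        raise ValueError("trace shorter than one spectral segment")
    fs = 1000.0 / step_ms
    f, p = signal.welch(
        x - x.mean(), fs=fs, window="hann", nperseg=nperseg,
        noverlap=int(nperseg * overlap), detrend=False,
    )
    return f, p


def response_matrix(
    baseline: pd.Series,
    perturbed: dict[str, pd.Series],
    threshold: float = 20.0,
    labels: tuple[str, ...] = PERTURBABLE_GROUPS,
) -> ResponseMatrix:
    """Assemble R_XY from a shared baseline and one per-group perturbed run.

    Entry (Y, X) = 100 (rate_X^pert(Y) - rate_X^base) / rate_X^base.
    Zero-baseline entries are NaN and flagged undefined.
    """
    labels = list(labels)
    base = baseline.reindex(labels).astype(float)
    pert = pd.DataFrame(
        {y: perturbed[y].reindex(labels).astype(float) for y in labels}
    ).T  # rows = perturbed group Y, columns = observed group X
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = 100.0 * (pert - base) / base
    vals[pert.notna() & (base == 0.0)] = np.nan
    return ResponseMatrix(
        values=vals, baseline=base, perturbed=pert, threshold=threshold
    )


def categorize(
    matrix: ResponseMatrix | pd.DataFrame,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Threshold a percent-change matrix into {-1, 0, +1}.

    +1 for changes strictly above +threshold, -1 strictly below -threshold,
    0 otherwise; undefined (NaN) entries map to 0 (they remain flagged on
    the response matrix itself).
    """
    if isinstance(matrix, ResponseMatrix):
        vals = matrix.values
        thr = matrix.threshold if threshold is None else threshold
    else:
        vals = matrix
        thr = 20.0 if threshold is None else threshold
    if thr <= 0:
        raise ValueError("threshold must be positive")
    v = vals.to_numpy(dtype=float)
    cat = np.zeros(v.shape, dtype=int)
    cat[v > thr] = 1
    cat[v < -thr] = -1
    return pd.DataFrame(cat, index=vals.index, columns=vals.columns)


#: Entrywise transition colours for comparison matrices, keyed (A, B).
_TRANSITIONS = {
    (0, 1): "red", (-1, 0): "red", (-1, 1): "red",
    (1, -1): "green", (1, 0): "green", (0, -1): "green",
    (0, 0): "white", (1, 1): "white", (-1, -1): "white",
}


def compare_categorical(A: pd.DataFrame, B: pd.DataFrame) -> pd.DataFrame:
    """Categorical comparison A -> B: white where the categories agree, red
    for transitions toward increase (0->+1, -1->0, -1->+1), green for
    transitions toward decrease (+1->-1, +1->0, 0->-1)."""
    if A.shape != B.shape:
        raise ValueError("categorical matrices must share a shape")
    a = A.to_numpy(dtype=int)
    b = B.to_numpy(dtype=int)
    out = np.empty(a.shape, dtype=object)
    for (ca, cb), colour in _TRANSITIONS.items():
        out[(a == ca) & (b == cb)] = colour
    return pd.DataFrame(out, index=A.index, columns=A.columns)


def numeric_difference(
    A: pd.DataFrame, B: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Entrywise B - A in percentage points, plus a boolean mask marking
    entries whose sign flipped between the two matrices."""
    if A.shape != B.shape:
        raise ValueError("matrices must share a shape")
    diff = B - A
    flips = (A * B) < 0
    return diff, flips


def count_marked(
    cat: pd.DataFrame,
    exclude_diagonal: bool = True,
) -> tuple[int, float]:
    """Number of marked (nonzero) entries of a categorical matrix and the
    fraction of them that are positive.  The diagonal (self-perturbation)
    never enters the count.  The fraction is NaN when nothing is marked."""
    c = cat.to_numpy(dtype=int).copy()
    if exclude_diagonal:
        np.fill_diagonal(c, 0)
    n_pos = int((c == 1).sum())
    n_neg = int((c == -1).sum())
    total = n_pos + n_neg
    return total, (n_pos / total if total else float("nan"))


def frobenius_distance(A, B) -> float:
    """|| A - B ||_F over the entries defined (finite) in both matrices."""
    a = np.asarray(A, dtype=float)
    b = np.asarray(B, dtype=float)
    if a.shape != b.shape:
        raise ValueError("matrices must share a shape")
    ok = np.isfinite(a) & np.isfinite(b)
    d = a[ok] - b[ok]
    return float(np.sqrt(np.sum(d * d)))


def pairwise_frobenius(matrices: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Symmetric table of Frobenius distances between named matrices."""
    names = list(matrices)
    out = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = frobenius_distance(matrices[a], matrices[b])
            out.loc[a, b] = out.loc[b, a] = d
    return out
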