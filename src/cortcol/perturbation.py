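"""End-to-end perturbation analysis.

The protocol mirrors the published experiment design: put the column into a
state (spontaneous, feedforward, one of the feedback configurations, or
combined FF+FB), let it settle, measure baseline rates over a fixed window,
then — in one separate simulation per target group, all sharing the same
random streams so that differences are attributable to the perturbation
alone — inject a small DC current into each of the 16 perturbable
populations and measure rates over an equally long post window.  The
resulting 16x16 percent-change response matrix feeds the categorical,
comparison and Frobenius-distance views, and the amplitude/threshold sweeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .analysis import (
    ResponseMatrix,
    categorize,
    count_marked,
    mean_rates,
    response_matrix,
)
from .engine import SimulationRecord, run_simulation
from .groups import PERTURBABLE_GROUPS
from .network_builder import Network
from .stimulation import (
    StimulusProtocol,
    add_perturbation,
    make_state_protocol,
)

__all__ = [
    "ExperimentPlan",
    "DEFAULT_CONDITION_AMPLITUDES",
    "DEFAULT_SCAN_AMPLITUDES",
    "DEFAULT_SCAN_THRESHOLDS",
    "run_state",
    "perturbation_sweep",
    "condition_sweep",
    "amplitude_threshold_scan",
]

#: 14 state-drive amplitudes spanning 0-400 pA (the published sweeps state
#: the range and the count; the exact grid is not enumerated).
DEFAULT_CONDITION_AMPLITUDES: tuple[float, ...] = tuple(
    np.linspace(0.0, 400.0, 14)
)
#: Perturbation amplitudes of the amplitude/threshold scan, pA.
DEFAULT_SCAN_AMPLITUDES: tuple[float, ...] = (
    -40.0, -30.0, -20.0, -10.0, 10.0, 20.0, 30.0, 40.0
)
#: Marked-change thresholds of the scan, %.
DEFAULT_SCAN_THRESHOLDS: tuple[float, ...] = (
    5.0, 10.0, 20.0, 30.0, 40.0, 50.0, 70.0, 80.0, 90.0, 100.0, 150.0, 200.0
)


@dataclass(frozen=True)
class ExperimentPlan:
    """One perturbation experiment: state, drives, windows, seed.

    The baseline and post-perturbation windows have equal length
    ``window_ms`` (default 3000 ms).  The perturbation switches on
    ``settle_ms`` after the state drive and stays on through the
    measurement window.  Baseline rates are taken from the state-only run
    over the same absolute window under the same seeds, so that any
    difference is attributable to the perturbation alone — a
    zero-amplitude perturbation reproduces the baseline exactly.
    """

    state: str = "spontaneous"
    state_amplitude: float = 150.0
    ff_amplitude: float | None = None   # combined-state override
    fb_amplitude: float | None = None
    perturb_amplitude: float = 30.0
    perturb_fraction: float = 1.0
    threshold: float = 20.0
    master_seed: int = 0
    window_ms: float = 3000.0
    settle_ms: float = 1000.0
    state_onset_ms: float = 700.0
    dt: float = 0.1
    n_realizations: int = 1

    def __post_init__(self) -> None:
        for name in ("state_amplitude", "perturb_amplitude", "window_ms",
                     "settle_ms", "state_onset_ms", "dt"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.window_ms <= 0 or self.dt <= 0:
            raise ValueError("window_ms and dt must be positive")

    def protocol(self) -> StimulusProtocol:
        if self.state == "ff_fb":
            ff = (self.state_amplitude if self.ff_amplitude is None
                  else self.ff_amplitude)
            fb = (self.state_amplitude if self.fb_amplitude is None
                  else self.fb_amplitude)
            p_ff = make_state_protocol("ff", ff, onset=500.0)
            p_fb = make_state_protocol("fb_L5", fb, onset=1100.0)
            return StimulusProtocol(
                epochs=p_ff.epochs + p_fb.epochs, name="ff_fb"
            )
        return make_state_protocol(
            self.state, self.state_amplitude, onset=self.state_onset_ms
        )

    def schedule(self) -> dict[str, float]:
        """Key times of one member simulation, ms."""
        proto = self.protocol()
        last_onset = max((ep.t_on for ep in proto.epochs), default=0.0)
        perturb_on = last_onset + self.settle_ms
        return {
            "perturb_on": perturb_on,
            "window_start": perturb_on,
            "window_end": perturb_on + self.window_ms,
            "end": perturb_on + self.window_ms,
        }


def run_state(
    plan: ExperimentPlan, network: Network
) -> tuple[pd.Series, SimulationRecord]:
    """Simulate the state drive alone and measure baseline rates over the
    settled measurement window (the same absolute window the perturbed
    runs are scored on, under the same seeds)."""
    sched = plan.schedule()
    record = run_simulation(
        network, plan.protocol(), duration=sched["end"],
        dt=plan.dt, seed=plan.master_seed,
    )
    baseline = mean_rates(
        record, (sched["window_start"], sched["window_end"])
    )
    return baseline, record


def perturbation_sweep(
    plan: ExperimentPlan,
    network: Network,
    perturb_amplitude: float | None = None,
) -> ResponseMatrix:
    """One full 16-population perturbation sweep.

    Runs the state alone for the shared baseline, then one simulation per
    perturbed group under identical seeds, and assembles the response
    matrix against the shared baseline.
    """
    amp = (plan.perturb_amplitude if perturb_amplitude is None
           else perturb_amplitude)
    sched = plan.schedule()
    baseline, _ = run_state(plan, network)
    state_proto = plan.protocol()
    perturbed: dict[str, pd.Series] = {}
    for group in PERTURBABLE_GROUPS:
        proto = add_perturbation(
            state_proto, group, amp,
            t_on=sched["perturb_on"], fraction=plan.perturb_fraction,
        )
        try:
            record = run_simulation(
                network, proto, duration=sched["end"],
                dt=plan.dt, seed=plan.master_seed,
            )
        except RuntimeError as err:
            raise RuntimeError(
                f"perturbation sweep aborted at group {group} "
                f"(state {plan.state!r}, amplitude {amp} pA): {err}"
            ) from err
        perturbed[group] = mean_rates(
            record, (sched["window_start"], sched["window_end"])
        )
    return response_matrix(baseline, perturbed, threshold=plan.threshold)


def condition_sweep(
    family: str,
    amplitudes,
    plan: ExperimentPlan,
    network: Network,
) -> pd.DataFrame:
    """Marked-change counts as a function of state-drive strength.

    ``family`` selects what varies: ``"ff"`` / ``"fb"`` vary a lone
    feedforward / feedback (layer 5) drive; ``"ff_fixed_fb_varying"`` holds
    FF at the plan's amplitude and varies FB; ``"fb_fixed_ff_varying"`` the
    converse.  Returns one row per amplitude with the number of marked
    changes and the positive fraction among them.
    """
    amplitudes = list(amplitudes)
    if not amplitudes:
        raise ValueError("amplitude list must be non-empty")
    rows = []
    for a in amplitudes:
        if family == "ff":
            p = replace(plan, state="ff", state_amplitude=float(a))
        elif family == "fb":
            p = replace(plan, state="fb_L5", state_amplitude=float(a))
        elif family == "ff_fixed_fb_varying":
            p = replace(plan, state="ff_fb",
                        ff_amplitude=plan.state_amplitude,
                        fb_amplitude=float(a))
        elif family == "fb_fixed_ff_varying":
            p = replace(plan, state="ff_fb",
                        ff_amplitude=float(a),
                        fb_amplitude=plan.state_amplitude)
        else:
            raise ValueError(
                "family must be one of 'ff', 'fb', 'ff_fixed_fb_varying', "
                "'fb_fixed_ff_varying'"
            )
        matrix = perturbation_sweep(p, network)
        n, pos = count_marked(categorize(matrix))
        rows.append({"amplitude_pa": float(a), "n_marked": n,
                     "positive_fraction": pos})
    return pd.DataFrame(rows)


def amplitude_threshold_scan(
    plan: ExperimentPlan,
    network: Network,
    amplitudes=DEFAULT_SCAN_AMPLITUDES,
    thresholds=DEFAULT_SCAN_THRESHOLDS,
) -> pd.DataFrame:
    """Count of super-threshold changes per (perturbation amplitude,
    threshold) pair; one sweep per amplitude, thresholds applied to the
    stored percent-change matrices without re-simulation."""
    thresholds = list(thresholds)
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    out = pd.DataFrame(
        0, index=pd.Index(thresholds, name="threshold_pct"),
        columns=pd.Index([float(a) for a in amplitudes], name="amplitude_pa"),
    )
    for a in amplitudes:
        matrix = perturbation_sweep(plan, network, perturb_amplitude=float(a))
        for t in thresholds:
            n, _ = count_marked(categorize(matrix, threshold=float(t)))
            out.loc[t, float(a)] = n
    return out
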