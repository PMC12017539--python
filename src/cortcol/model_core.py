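"""Single-neuron membrane dynamics and receptor gating kinetics.

Leaky integrate-and-fire membrane with conductance-based synapses:

    C_m dV/dt = -g_L (V - V_rest) + I_syn(t)

The total synaptic current is the sum of an external DC term, background
AMPA drive, and recurrent AMPA, NMDA and GABA-A currents.  Each current is
``g . s . (V_rev - V)`` with a dimensionless gating variable ``s`` driven by
presynaptic spikes (delta pulses) and decaying exponentially.  NMDA currents
additionally carry the voltage-dependent magnesium-block factor

    B(V) = 1 / (1 + [Mg2+] exp(-0.062 V) / 3.57)

All functions here are pure state updates and accept scalars or NumPy
arrays; the time-stepped network loop lives in :mod:`cortcol.engine`.

Units: mV, ms, pF, nS, pA (1 nS . 1 mV = 1 pA; 1 pA . 1 ms / 1 pF = 1 mV).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CellTypeParams",
    "SynapseKinetics",
    "NeuronState",
    "membrane_step",
    "nmda_voltage_factor",
    "gating_step_first_order",
    "gating_step_nmda",
    "total_synaptic_current",
]


@dataclass(frozen=True)
class CellTypeParams:
    """Electrophysiology of one cell group plus its background drive.

    Parameters
    ----------
    group_id : str
        Population label (layer x cell class), e.g. ``"PV4"``.
    V_rest : float
        Resting potential, mV.  Also the reset value after a spike and the
        GABA-A reversal potential of this neuron.
    V_th : float
        Firing threshold, mV; must exceed ``V_rest``.
    C_m : float
        Membrane capacitance, pF.
    g_L : float
        Leak conductance, nS.  The membrane time constant is ``C_m / g_L``.
    tau_ref : float
        Absolute refractory period, ms.
    nu_bg : float
        Rate of the private background Poisson generator, spikes/s.
    """

    group_id: str
    V_rest: float
    V_th: float
    C_m: float
    g_L: float
    tau_ref: float
    nu_bg: float = 0.0

    def __post_init__(self) -> None:
        if not self.V_th > self.V_rest:
            raise ValueError(
                f"{self.group_id}: V_th ({self.V_th}) must exceed "
                f"V_rest ({self.V_rest})"
            )
        if self.C_m <= 0 or self.g_L <= 0:
            raise ValueError(f"{self.group_id}: C_m and g_L must be positive")
        if self.tau_ref < 0 or self.nu_bg < 0:
            raise ValueError(
                f"{self.group_id}: tau_ref and nu_bg must be non-negative"
            )

    @property
    def tau_m(self) -> float:
        """Membrane time constant C_m / g_L, ms."""
        return self.C_m / self.g_L


@dataclass(frozen=True)
class SynapseKinetics:
    """Receptor time constants, magnesium concentration and conversion factors.

    Defaults: tau_AMPA = 2 ms, tau_GABA = 5 ms, NMDA decay/rise = 80/2 ms,
    alpha = 0.5 /ms, [Mg2+] = 1 mM, all conductance conversion factors 1 nS,
    excitatory reversal V_E = 0 mV.  The inhibitory reversal is not stored
    here: it equals each postsynaptic neuron's own V_rest.
    """

    tau_AMPA: float = 2.0
    tau_NMDA_decay: float = 80.0
    tau_NMDA_rise: float = 2.0
    alpha: float = 0.5          # 1/ms, drive of the NMDA gating variable
    tau_GABA: float = 5.0
    Mg: float = 1.0             # mM
    g_AMPA: float = 1.0         # nS per unit gating
    g_NMDA: float = 1.0
    g_GABA: float = 1.0
    V_E: float = 0.0            # mV

    def __post_init__(self) -> None:
        for name in ("tau_AMPA", "tau_NMDA_decay", "tau_NMDA_rise", "tau_GABA"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.Mg < 0:
            raise ValueError("Mg must be non-negative")
        if min(self.g_AMPA, self.g_NMDA, self.g_GABA) < 0:
            raise ValueError("conductance conversion factors must be >= 0")


@dataclass
class NeuronState:
    """Dynamic state of one neuron: membrane, refractoriness and the summed
    (weight-carrying) presynaptic gating accumulators per receptor channel."""

    V: float
    refractory_remaining: float = 0.0
    s_AMPA_bg: float = 0.0
    s_AMPA: float = 0.0
    s_GABA: float = 0.0
    s_NMDA: float = 0.0
    x_NMDA: float = 0.0


def nmda_voltage_factor(V, kin: SynapseKinetics):
    """Magnesium-block factor of the NMDA current, in (0, 1].

    Equals 1 identically when ``kin.Mg == 0`` and is strictly increasing in
    V otherwise (depolarization relieves the block).
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("non-finite membrane potential")
    out = 1.0 / (1.0 + kin.Mg * np.exp(-0.062 * V) / 3.57)
    return out if out.ndim else float(out)


def gating_step_first_order(s, tau: float, n_spikes, dt: float):
    """Advance a first-order gating variable (AMPA, background AMPA, GABA,
    or the NMDA rise variable x) by one step of length ``dt``.

    The variable decays exponentially with constant ``tau`` (exact update)
    and each presynaptic spike arriving in the step adds exactly 1.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("gating variable must be non-negative")
    if tau <= 0 or dt <= 0:
        raise ValueError("tau and dt must be positive")
    out = s * np.exp(-dt / tau) + np.asarray(n_spikes, dtype=float)
    return out if out.ndim else float(out)


def gating_step_nmda(s, x, kin: SynapseKinetics, n_spikes, dt: float):
    """Advance the NMDA gating pair (s, x) by one step.

    x decays with ``tau_NMDA_rise`` (exact) and gains +1 per spike; s decays
    with ``tau_NMDA_decay`` and is driven by ``alpha * x * (1 - s)`` (forward
    Euler on the nonlinear term, using the step-start x).  The (1 - s)
    saturation keeps s in [0, 1] for admissible dt.
    """
    s = np.asarray(s, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("NMDA gating variable must lie in [0, 1]")
    if np.any(x < 0):
        raise ValueError("NMDA rise variable must be non-negative")
    s_new = s + dt * (-s / kin.tau_NMDA_decay + kin.alpha * x * (1.0 - s))
    x_new = x * np.exp(-dt / kin.tau_NMDA_rise) + np.asarray(n_spikes, float)
    if np.any(s_new < 0) or np.any(s_new > 1):
        raise ValueError(
            "NMDA gating variable left [0, 1] after the step; dt too large"
        )
    if s_new.ndim:
        return s_new, x_new
    return float(s_new), float(x_new)


def total_synaptic_current(
    state: NeuronState,
    kin: SynapseKinetics,
    params: CellTypeParams,
    I_ext: float = 0.0,
):
    """Total synaptic current I_syn in pA.

    Sum of the external DC term, background AMPA, recurrent AMPA, NMDA
    (with the magnesium-block factor applied) and GABA-A currents.  Currents
    are computed as ``g . s . (V_rev - V)`` so that AMPA/NMDA depolarize for
    V < V_E and GABA hyperpolarizes/shunts for V > V_I.  The inhibitory
    reversal V_I is the postsynaptic neuron's own resting potential.
    """
    V = state.V
    if not np.all(np.isfinite(np.asarray(V))):
        raise ValueError("non-finite membrane potential")
    drive_E = kin.V_E - V
    drive_I = params.V_rest - V
    I_bg = kin.g_AMPA * drive_E * state.s_AMPA_bg
    I_ampa = kin.g_AMPA * drive_E * state.s_AMPA
    I_nmda = kin.g_NMDA * drive_E * nmda_voltage_factor(V, kin) * state.s_NMDA
    I_gaba = kin.g_GABA * drive_I * state.s_GABA
    return I_ext + I_bg + I_ampa + I_nmda + I_gaba


def membrane_step(
    state: NeuronState,
    params: CellTypeParams,
    I_syn: float,
    dt: float,
) -> tuple[NeuronState, bool]:
    """Advance the membrane potential by one forward-Euler step.

    Returns the updated state and a flag marking whether a spike was emitted
    this step.  During refractoriness V is clamped to V_rest and inputs are
    discarded.  On threshold crossing V resets instantaneously to V_rest and
    the refractory clock is set to ``tau_ref``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (np.isfinite(state.V) and np.isfinite(I_syn)):
        raise ValueError(
            f"non-finite membrane state for neuron of group {params.group_id}"
        )
    spiked = False
    if state.refractory_remaining > 0:
        V = params.V_rest
        refrac = max(state.refractory_remaining - dt, 0.0)
    else:
        V = state.V + dt * (
            -params.g_L * (state.V - params.V_rest) + I_syn
        ) / params.C_m
        refrac = 0.0
        if V >= params.V_th:
            spiked = True
            V = params.V_rest
            refrac = params.tau_ref
    new = NeuronState(
        V=V,
        refractory_remaining=refrac,
        s_AMPA_bg=state.s_AMPA_bg,
        s_AMPA=state.s_AMPA,
        s_GABA=state.s_GABA,
        s_NMDA=state.s_NMDA,
        x_NMDA=state.x_NMDA,
    )
    return new, spiked
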