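"""Pure update rules for leaky integrate-and-fire membranes, adaptation, and
current-based exponential synapses.

All quantities are strict SI (volt, ampere, ohm, farad, siemens, second).
Millivolt/millisecond conveniences exist only at CLI/report boundaries.

The membrane follows an RC circuit driven by leak, synaptic, injected and
(optionally) adaptation currents::

    C_m dV/dt = I_leak + I_syn + I_inj - I_adapt
    I_leak    = -(V - V_r) / R_m
    I_adapt   = g_adapt (V - V_r)

A spike is emitted when V reaches ``Vthres``; V is then reset to ``Vreset``
and pinned there for an absolute refractory period ``tau_r``.  The adaptation
conductance is incremented by ``delta_g_adapt`` on each spike and decays
exponentially with time constant ``tau_adapt``.  Synaptic currents are
decaying exponentials; successive presynaptic spikes superpose linearly on a
single per-edge state variable.

Integration is forward Euler at a fixed step (default ``DEFAULT_DT``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

__all__ = [
    "Polarity",
    "NeuronParameters",
    "NeuronState",
    "SynapseParameters",
    "ClampPolicy",
    "DEFAULT_DT",
    "leak_current",
    "adaptation_current",
    "decay_adaptation",
    "decay_synaptic_current",
    "clamp_voltage",
    "step_neuron",
    "lif_steady_state_voltage",
    "lif_firing_rate",
    "InvalidStepError",
    "NumericalBlowUpError",
]

#: Default fixed integration step (second).
DEFAULT_DT = 1e-4


class InvalidStepError(ValueError):
    """Raised when a forward-Euler step would be unstable (dt >= tau)."""


class NumericalBlowUpError(ArithmeticError):
    """Raised when a membrane update produces a non-finite voltage."""


class Polarity(str, Enum):
    """Sign of a cell's (or generator's) synaptic output."""

    EXCITATORY = "excitatory"
    INHIBITORY = "inhibitory"

    @property
    def sign(self) -> int:
        return 1 if self is Polarity.EXCITATORY else -1


@dataclass(frozen=True)
class NeuronParameters:
    """Static coefficients of a (possibly adaptive) LIF cell.

    Parameters
    ----------
    Cm : float
        Membrane capacitance (farad).
    Rm : float
        Membrane resistance (ohm).
    Vr : float
        Resting potential (volt); the leak current drives V toward it.
    Vreset : float
        Post-spike reset potential (volt).
    Vthres : float
        Firing threshold (volt).
    tau_r : float
        Absolute refractory period (second); V is pinned to ``Vreset``.
    polarity : Polarity
        Sign the cell's outgoing synapses inherit.
    adaptive : bool
        Enable spike-frequency adaptation.
    tau_adapt : float
        Adaptation conductance decay time constant (second).
    delta_g_adapt : float
        Conductance increment per spike (siemens).
    """

    Cm: float = 1.0e-9
    Rm: float = 1.0e8
    Vr: float = -0.065
    Vreset: float = -0.065
    Vthres: float = -0.050
    tau_r: float = 0.002
    polarity: Polarity = Polarity.EXCITATORY
    adaptive: bool = False
    tau_adapt: float = 0.250
    delta_g_adapt: float = 1.0e-9

    def __post_init__(self) -> None:
        if self.Cm <= 0:
            raise ValueError(f"Cm must be positive, got {self.Cm}")
        if self.Rm <= 0:
            raise ValueError(f"Rm must be positive, got {self.Rm}")
        if self.Vreset >= self.Vthres:
            raise ValueError(
                f"Vreset ({self.Vreset}) must lie below Vthres ({self.Vthres})"
            )
        if self.tau_r < 0:
            raise ValueError(f"tau_r must be nonnegative, got {self.tau_r}")
        if self.adaptive and self.tau_adapt <= 0:
            raise ValueError("tau_adapt must be positive for an adaptive cell")
        if self.delta_g_adapt < 0:
            raise ValueError("delta_g_adapt must be nonnegative")
        if isinstance(self.polarity, str) and not isinstance(self.polarity, Polarity):
            object.__setattr__(self, "polarity", Polarity(self.polarity))

    @property
    def tau_m(self) -> float:
        """Membrane time constant R_m * C_m (second)."""
        return self.Rm * self.Cm


@dataclass
class NeuronState:
    """Dynamic state of one cell.

    ``V_observed`` is the voltage a voltmeter sees for the step just taken:
    on a firing step it is the (clamped) threshold-crossing value reached
    *before* the reset, so recorded traces rise to threshold the way the
    membrane actually did; ``V`` itself already holds the reset value.
    """

    V: float
    g_adapt: float = 0.0
    refractory_remaining: float = 0.0
    last_fired: bool = False
    V_observed: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.V_observed is None:
            self.V_observed = self.V


@dataclass(frozen=True)
class SynapseParameters:
    """Current-based synapse: a decaying-exponential current transient.

    ``peak_current`` is the unsigned magnitude Ī of the current jump per
    presynaptic spike; the sign is inherited from the presynaptic node's
    polarity.  ``delay`` is the transmission delay, rounded to whole steps
    (minimum one step) by the engine.
    """

    peak_current: float = 1.0e-9
    tau_syn: float = 0.010
    delay: float = 0.0

    def __post_init__(self) -> None:
        if self.peak_current < 0:
            raise ValueError("peak_current is a magnitude; must be >= 0")
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be positive")
        if self.delay < 0:
            raise ValueError("delay must be nonnegative")


@dataclass(frozen=True)
class ClampPolicy:
    """Hard voltage limits applied after each Euler update.

    Defaults bracket the K+ and Na+ reversal potentials (-90 to +60 mV),
    bounding the excursions a current-based synapse could otherwise produce.
    """

    enabled: bool = True
    v_min: float = -0.090
    v_max: float = 0.060

    def __post_init__(self) -> None:
        if self.v_min >= self.v_max:
            raise ValueError(f"v_min ({self.v_min}) must be below v_max ({self.v_max})")


def leak_current(V: float, params: NeuronParameters) -> float:
    """Leak current -(V - Vr)/Rm driving the membrane toward rest (ampere)."""
    return -(V - params.Vr) / params.Rm


def adaptation_current(g_adapt: float, V: float, params: NeuronParameters) -> float:
    """Adaptation current magnitude g_adapt * (V - Vr) (ampere).

    The caller subtracts this in the membrane equation, so for a depolarized
    membrane it is hyperpolarizing (it opposes firing).
    """
    return g_adapt * (V - params.Vr)


def decay_adaptation(g_adapt: float, dt: float, params: NeuronParameters) -> float:
    """One Euler step of dg/dt = -g/tau_adapt; result stays nonnegative."""
    if dt >= params.tau_adapt:
        raise InvalidStepError(
            f"dt ({dt}) must be smaller than tau_adapt ({params.tau_adapt})"
        )
    return g_adapt * (1.0 - dt / params.tau_adapt)


def decay_synaptic_current(s: float, dt: float, syn: SynapseParameters) -> float:
    """One Euler step of ds/dt = -s/tau_syn for a synaptic current state.

    Spike arrivals are handled separately by adding the (signed) peak current
    to ``s``; kernels from successive spikes therefore superpose linearly.
    """
    if dt >= syn.tau_syn:
        raise InvalidStepError(
            f"dt ({dt}) must be smaller than tau_syn ({syn.tau_syn})"
        )
    return s * (1.0 - dt / syn.tau_syn)


def clamp_voltage(V: float, clamp: ClampPolicy) -> float:
    """Apply the hard voltage limits; identity when disabled."""
    if not clamp.enabled:
        return V
    return min(max(V, clamp.v_min), clamp.v_max)


def step_neuron(
    state: NeuronState,
    params: NeuronParameters,
    I_syn_total: float,
    I_inj_total: float,
    dt: float,
    clamp: ClampPolicy,
) -> tuple[NeuronState, bool]:
    """Advance one cell by one forward-Euler step of length ``dt``.

    Semantics, in order: a refractory cell stays pinned at ``Vreset`` while
    its countdown runs (adaptation still decays).  Otherwise the membrane is
    integrated with the summed currents, clamped, and checked against
    threshold; on a spike V is reset, the refractory countdown starts, and
    (for an adaptive cell) the adaptation conductance is incremented.

    Returns the new state and whether the cell fired this step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")

    g_new = (
        decay_adaptation(state.g_adapt, dt, params) if params.adaptive else state.g_adapt
    )

    if state.refractory_remaining > 0:
        return (
            NeuronState(
                V=params.Vreset,
                g_adapt=g_new,
                refractory_remaining=max(0.0, state.refractory_remaining - dt),
                last_fired=False,
                V_observed=params.Vreset,
            ),
            False,
        )

    I_leak = leak_current(state.V, params)
    I_adapt = adaptation_current(state.g_adapt, state.V, params)
    V_new = state.V + (dt / params.Cm) * (I_leak + I_syn_total + I_inj_total - I_adapt)
    V_new = clamp_voltage(V_new, clamp)
    if not math.isfinite(V_new):
        raise NumericalBlowUpError(
            f"membrane potential became non-finite ({V_new}); "
            "check dt against the smallest time constant and the input currents"
        )

    fired = V_new >= params.Vthres
    if fired:
        return (
            NeuronState(
                V=params.Vreset,
                g_adapt=g_new + (params.delta_g_adapt if params.adaptive else 0.0),
                refractory_remaining=params.tau_r,
                last_fired=True,
                V_observed=V_new,
            ),
            True,
        )
    return (
        NeuronState(
            V=V_new,
            g_adapt=g_new,
            refractory_remaining=0.0,
            last_fired=False,
            V_observed=V_new,
        ),
        False,
    )


def lif_steady_state_voltage(params: NeuronParameters, I: float) -> float:
    """Asymptotic voltage V_inf = Vr + Rm*I under constant current (volt)."""
    return params.Vr + params.Rm * I


def lif_firing_rate(params: NeuronParameters, I: float) -> float:
    """Closed-form steady firing rate of a non-adaptive LIF cell under
    constant current ``I`` (Hz).

    The inter-spike interval is the refractory period plus the RC charging
    time from ``Vreset`` to ``Vthres``::

        ISI = tau_r + tau_m * ln((V_inf - Vreset) / (V_inf - Vthres))

    Returns 0 when V_inf <= Vthres (the cell never reaches threshold).
    """
    V_inf = lif_steady_state_voltage(params, I)
    if V_inf <= params.Vthres:
        return 0.0
    isi = params.tau_r + params.tau_m * math.log(
        (V_inf - params.Vreset) / (V_inf - params.Vthres)
    )
    return 1.0 / isi


def replace_params(params: NeuronParameters, **changes) -> NeuronParameters:
    """Return a copy of ``params`` with the given fields replaced."""
    return replace(params, **changes)
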