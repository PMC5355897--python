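"""Reference circuit motifs and the behavioral experiments built on them.

Five classic teaching circuits are provided as builders returning ordinary
:class:`~lifnet.network.Network` objects:

* ``threshold_demo`` — one DC-driven cell per current level, showing that
  injection must exceed rheobase to fire at all and that rate grows with
  current (the textbook f-I staircase; uses an artificial resting potential
  of 0 mV).
* ``summation`` — several presynaptic cells converging on one output cell:
  one synchronous input is subthreshold, three make the output fire.
* ``touch_inhibition`` — an excitatory and an inhibitory cell both project
  to C; activating the inhibitory path shortly before the excitatory one
  keeps C below threshold.
* ``feedback_inhibition`` — Input -> A -> Output -> B -|> A gain-control
  loop; the output fires slower than the input, and cutting the feedback
  edge raises the output rate.
* ``direction_selectivity`` — a feedforward array with one-sided lateral
  inhibition: each column's inhibitory cell silences the relay cell of the
  column to its right, so only a right-to-left sweep of touches drives the
  output cell.

All synaptic weights and currents below were calibrated once, by simulation,
to satisfy those behavioral contracts with margin; they are committed as
named constants and locked in by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .core import NeuronParameters, Polarity, SynapseParameters
from .engine import RecordingSet, SimulationConfig, run
from .network import Network
from .sensors import RateMeterParams
from .stimulators import CurrentSourceParams, EventSchedule

__all__ = [
    "MOTIF_NAMES",
    "build_motif",
    "build_threshold_demo",
    "build_summation",
    "build_touch_inhibition",
    "build_feedback_inhibition",
    "build_direction_selective",
    "run_threshold_demo",
    "run_summation",
    "run_touch_inhibition",
    "run_feedback_inhibition",
    "run_direction_selectivity",
    "direction_selectivity_index",
]

# --- calibrated constants --------------------------------------------------

#: Current levels (A) for the threshold demo: with Rm = 1e8 ohm these pull
#: the membrane 10, 20 and 30 mV above rest against a 15 mV threshold gap.
THRESHOLD_DEMO_LEVELS = (1.0e-10, 2.0e-10, 3.0e-10)

#: The Vr = 0 cell variant used by the threshold demo.
ZERO_REST_NEURON = NeuronParameters(Vr=0.0, Vreset=0.0, Vthres=0.015)

#: Convergent synapse in the summation circuit: one EPSP peaks ~7.7 mV
#: (subthreshold), three synchronous ones ~23 mV (suprathreshold).
SUMMATION_SYNAPSE = SynapseParameters(peak_current=1.0e-9)

#: Single-shot suprathreshold synapse (~19 mV EPSP peak) used wherever one
#: presynaptic spike must reliably fire the target.
STRONG_SYNAPSE = SynapseParameters(peak_current=2.5e-9)

#: Slow, strong inhibitory synapses. Magnitudes are unsigned; the sign comes
#: from the presynaptic cell's inhibitory polarity.
INHIBITORY_SYNAPSE = SynapseParameters(peak_current=3.0e-9, tau_syn=0.050)
LATERAL_INHIBITION_SYNAPSE = SynapseParameters(peak_current=4.0e-9, tau_syn=0.120)

#: Relay -> output synapse in the direction-selective circuit: one EPSP peaks
#: ~12 mV (subthreshold); EPSPs arriving one sweep interval apart summate
#: past the 15 mV threshold gap by the second relay spike.
RELAY_OUTPUT_SYNAPSE = SynapseParameters(peak_current=1.6e-9)

#: DC drive of the feedback-inhibition circuit (~14 Hz input rate).
FEEDBACK_DC_AMPLITUDE = 3.0e-10

INHIBITORY = NeuronParameters(polarity=Polarity.INHIBITORY)

MOTIF_NAMES = (
    "threshold_demo",
    "summation",
    "touch_inhibition",
    "feedback_inhibition",
    "direction_selectivity",
)


# --- builders --------------------------------------------------------------


def build_threshold_demo(
    current_levels: Sequence[float] = THRESHOLD_DEMO_LEVELS,
) -> Network:
    """One DC source + cell + voltmeter per current level (Vr = 0 variant)."""
    if len(current_levels) < 2:
        raise ValueError("threshold demo needs at least two current levels")
    net = Network()
    for i, level in enumerate(current_levels):
        src = net.add("dc_source", CurrentSourceParams(amplitude=level))
        cell = net.add("neuron", ZERO_REST_NEURON, label=f"cell{i}")
        meter = net.add("voltmeter")
        net.connect(src, cell)
        net.connect(cell, meter)
    return net


def build_summation(n_inputs: int = 3, activation_time: float = 0.05) -> Network:
    """``n_inputs`` touch-driven presynaptic cells converging on one output.

    All event sources activate simultaneously at ``activation_time``.
    """
    if n_inputs < 1:
        raise ValueError("summation needs at least one input")
    net = Network()
    out = net.add("neuron", label="output")
    for i in range(n_inputs):
        touch = net.add("event_source", EventSchedule((activation_time,)))
        pre = net.add("neuron", label=f"pre{i}")
        net.connect(touch, pre)
        net.connect(pre, out, SUMMATION_SYNAPSE)
    detector = net.add("spike_detector")
    net.connect(out, detector)
    return net


def build_touch_inhibition(
    a_times: Sequence[float] = (0.1,), b_times: Sequence[float] = ()
) -> Network:
    """Touch -> excitatory A and touch -> inhibitory B, both projecting to C."""
    net = Network()
    touch_a = net.add("event_source", EventSchedule(tuple(a_times)))
    touch_b = net.add("event_source", EventSchedule(tuple(b_times)))
    a = net.add("neuron", label="A")
    b = net.add("neuron", INHIBITORY, label="B")
    c = net.add("neuron", label="C")
    meter = net.add("voltmeter")
    net.connect(touch_a, a)
    net.connect(touch_b, b)
    net.connect(a, c, STRONG_SYNAPSE)
    net.connect(b, c, INHIBITORY_SYNAPSE)
    net.connect(c, meter)
    return net


def build_feedback_inhibition(
    dc_amplitude: float = FEEDBACK_DC_AMPLITUDE, include_feedback: bool = True
) -> Network:
    """DC -> Input -> A -> Output -> inhibitory B -|> A gain-control loop."""
    net = Network()
    dc = net.add("dc_source", CurrentSourceParams(amplitude=dc_amplitude))
    inp = net.add("neuron", label="Input")
    a = net.add("neuron", label="A")
    out = net.add("neuron", label="Output")
    b = net.add("neuron", INHIBITORY, label="B")
    net.connect(dc, inp)
    net.connect(inp, a, STRONG_SYNAPSE)
    net.connect(a, out, STRONG_SYNAPSE)
    net.connect(out, b, STRONG_SYNAPSE)
    if include_feedback:
        net.connect(b, a, INHIBITORY_SYNAPSE)
    meter_in = net.add("firing_rate_meter", RateMeterParams(sigma_w=0.25))
    meter_out = net.add("firing_rate_meter", RateMeterParams(sigma_w=0.25))
    net.connect(inp, meter_in)
    net.connect(out, meter_out)
    return net


def build_direction_selective(
    n_columns: int = 4,
    sweep: str = "right_to_left",
    inter_touch_interval: float = 0.1,
    sweep_start: float = 0.05,
) -> Network:
    """Feedforward array with one-sided lateral inhibition.

    Per column (indexed left to right): touch -> input cell -> {relay cell,
    inhibitory cell}; the inhibitory cell of column i suppresses the relay
    cell of column i+1; all relays converge on one output cell.  The touch
    schedule sweeps across columns in the requested direction at
    ``inter_touch_interval`` spacing.
    """
    if n_columns < 2:
        raise ValueError("direction-selective circuit needs at least two columns")
    if sweep not in ("right_to_left", "left_to_right"):
        raise ValueError(f"unknown sweep direction: {sweep!r}")
    net = Network()
    out = net.add("neuron", label="output")
    inputs, relays, inhibitors = [], [], []
    for i in range(n_columns):
        order = (n_columns - 1 - i) if sweep == "right_to_left" else i
        t_touch = sweep_start + order * inter_touch_interval
        touch = net.add("event_source", EventSchedule((t_touch,)))
        inp = net.add("neuron", label=f"input{i}")
        relay = net.add("neuron", label=f"relay{i}")
        inhib = net.add("neuron", INHIBITORY, label=f"inh{i}")
        net.connect(touch, inp)
        net.connect(inp, relay, STRONG_SYNAPSE)
        net.connect(inp, inhib, STRONG_SYNAPSE)
        net.connect(relay, out, RELAY_OUTPUT_SYNAPSE)
        inputs.append(inp)
        relays.append(relay)
        inhibitors.append(inhib)
    for i in range(n_columns - 1):
        net.connect(inhibitors[i], relays[i + 1], LATERAL_INHIBITION_SYNAPSE)
    return net


_BUILDERS = {
    "threshold_demo": build_threshold_demo,
    "summation": build_summation,
    "touch_inhibition": build_touch_inhibition,
    "feedback_inhibition": build_feedback_inhibition,
    "direction_selectivity": build_direction_selective,
}


def build_motif(name: str, **params) -> Network:
    """Build a motif by name; parameters are forwarded to its builder."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ValueError(
            f"unknown motif {name!r}; known: {', '.join(MOTIF_NAMES)}"
        ) from None
    return builder(**params)


# --- behavioral experiments ------------------------------------------------


def run_threshold_demo(
    current_levels: Sequence[float] = THRESHOLD_DEMO_LEVELS,
    duration: float = 2.0,
    dt: float = 1e-4,
    seed: int = 0,
) -> list[int]:
    """Spike count of each cell over ``duration`` (one per current level)."""
    net = build_threshold_demo(current_levels)
    rec = run(net, SimulationConfig(duration=duration, dt=dt, seed=seed))
    return [rec.spike_count(net.by_label(f"cell{i}")) for i in range(len(current_levels))]


def run_summation(
    n_inputs: int, duration: float = 0.5, dt: float = 1e-4, seed: int = 0
) -> int:
    """Output spike count after one synchronous activation of all inputs."""
    net = build_summation(n_inputs)
    rec = run(net, SimulationConfig(duration=duration, dt=dt, seed=seed))
    return rec.spike_count(net.by_label("output"))


def run_touch_inhibition(dt: float = 1e-4, seed: int = 0) -> tuple[int, int]:
    """Spike counts of C: (A activated alone, B activated shortly before A)."""
    cfg = SimulationConfig(duration=0.5, dt=dt, seed=seed)
    net_a = build_touch_inhibition(a_times=(0.1,), b_times=())
    count_alone = run(net_a, cfg).spike_count(net_a.by_label("C"))
    net_ba = build_touch_inhibition(a_times=(0.12,), b_times=(0.1,))
    count_inhibited = run(net_ba, cfg).spike_count(net_ba.by_label("C"))
    return count_alone, count_inhibited


def run_feedback_inhibition(
    duration: float = 2.0, dt: float = 1e-4, seed: int = 0
) -> dict:
    """Mean rates (Hz) of Input and Output, with and without the feedback edge."""
    cfg = SimulationConfig(duration=duration, dt=dt, seed=seed)
    net = build_feedback_inhibition(include_feedback=True)
    rec = run(net, cfg)
    net_open = build_feedback_inhibition(include_feedback=False)
    rec_open = run(net_open, cfg)
    return {
        "input_rate": rec.mean_rate(net.by_label("Input")),
        "output_rate": rec.mean_rate(net.by_label("Output")),
        "output_rate_no_feedback": rec_open.mean_rate(net_open.by_label("Output")),
    }


def direction_selectivity_index(preferred: int, null: int) -> float:
    """(preferred - null) / (preferred + null) spike counts; 1 means the
    null direction is completely suppressed."""
    if preferred + null == 0:
        raise ValueError("no output spikes in either direction")
    return (preferred - null) / (preferred + null)


def run_direction_selectivity(
    n_columns: int = 4,
    inter_touch_interval: float = 0.1,
    dt: float = 1e-4,
    seed: int = 0,
) -> dict:
    """Output spike counts for both sweep directions and the resulting DSI."""
    duration = 0.05 + n_columns * inter_touch_interval + 0.3
    cfg = SimulationConfig(duration=duration, dt=dt, seed=seed)
    counts = {}
    for sweep in ("right_to_left", "left_to_right"):
        net = build_direction_selective(
            n_columns, sweep, inter_touch_interval=inter_touch_interval
        )
        counts[sweep] = run(net, cfg).spike_count(net.by_label("output"))
    return {
        "preferred": counts["right_to_left"],
        "null": counts["left_to_right"],
        "dsi": direction_selectivity_index(
            counts["right_to_left"], counts["left_to_right"]
        ),
    }
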