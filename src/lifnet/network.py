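"""The network container: a directed multigraph of typed nodes (neurons,
stimulators, sensors) and synapse edges, with construction-time validation.

Allowed edges: stimulator -> neuron, neuron -> neuron, neuron -> sensor.
Sensors never drive anything.  Current sources (dc/ac) attach as direct
current injections; spike sources and neurons attach through current-based
synapses whose sign is inherited from the presynaptic node's polarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .core import NeuronParameters, Polarity, SynapseParameters
from .receptive_fields import ReceptiveFieldKernel, VisualStimulus
from .sensors import RateMeterParams
from .stimulators import CurrentSourceParams, EventSchedule, GeneratorParams

__all__ = [
    "NodeKind",
    "NodeSpec",
    "Edge",
    "Network",
    "VisualInputParams",
    "NetworkError",
    "NEURON_KINDS",
    "CURRENT_SOURCE_KINDS",
    "SPIKE_SOURCE_KINDS",
    "SENSOR_KINDS",
    "STIMULATOR_KINDS",
]


class NetworkError(ValueError):
    """Invalid network construction (unknown node, bad pairing, duplicate label)."""


NEURON_KINDS = frozenset({"neuron"})
CURRENT_SOURCE_KINDS = frozenset({"dc_source", "ac_source"})
SPIKE_SOURCE_KINDS = frozenset(
    {"regular_generator", "poisson_generator", "event_source", "visual_input"}
)
SENSOR_KINDS = frozenset({"voltmeter", "spike_detector", "firing_rate_meter"})
STIMULATOR_KINDS = CURRENT_SOURCE_KINDS | SPIKE_SOURCE_KINDS
NODE_KINDS = NEURON_KINDS | STIMULATOR_KINDS | SENSOR_KINDS

NodeKind = str

#: Event (touch-like) sources use a strong but brief default synapse: the
#: kick reliably fires a resting default neuron one hop downstream, and has
#: decayed away by the end of that neuron's refractory period so it fires
#: exactly once per activation.
TOUCH_SYNAPSE = SynapseParameters(peak_current=1.0e-8, tau_syn=0.002)


@dataclass(frozen=True)
class VisualInputParams:
    """Receptive-field spike generator: kernel, static frame, and gain.

    ``gain`` converts the (dimensionless, rectified) field response into a
    per-step firing probability gain*response*dt.
    """

    kernel: ReceptiveFieldKernel
    image: VisualStimulus
    gain: float = 100.0
    polarity: Polarity = Polarity.EXCITATORY

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise ValueError("gain must be nonnegative")
        if self.kernel.shape != self.image.image.shape:
            raise ValueError("kernel and stimulus shapes must match")


_PARAM_TYPES = {
    "neuron": NeuronParameters,
    "dc_source": CurrentSourceParams,
    "ac_source": CurrentSourceParams,
    "regular_generator": GeneratorParams,
    "poisson_generator": GeneratorParams,
    "event_source": EventSchedule,
    "visual_input": VisualInputParams,
    "voltmeter": type(None),
    "spike_detector": type(None),
    "firing_rate_meter": RateMeterParams,
}

_DEFAULT_PARAMS = {
    "neuron": NeuronParameters,
    "dc_source": CurrentSourceParams,
    "ac_source": lambda: CurrentSourceParams(frequency=10.0),
    "regular_generator": GeneratorParams,
    "poisson_generator": GeneratorParams,
    "event_source": EventSchedule,
    "voltmeter": lambda: None,
    "spike_detector": lambda: None,
    "firing_rate_meter": RateMeterParams,
}


@dataclass(frozen=True)
class NodeSpec:
    """A typed node: kind, kind-specific parameters, optional unique label."""

    kind: NodeKind
    params: object = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise NetworkError(f"unknown node kind: {self.kind!r}")
        params = self.params
        if params is None and self.kind != "visual_input":
            factory = _DEFAULT_PARAMS[self.kind]
            params = factory()
            object.__setattr__(self, "params", params)
        expected = _PARAM_TYPES[self.kind]
        if not isinstance(params, expected):
            raise NetworkError(
                f"node kind {self.kind!r} requires {expected.__name__} parameters, "
                f"got {type(params).__name__}"
            )


@dataclass(frozen=True)
class Edge:
    """Directed connection; ``synapse`` is None for injection and sensor edges."""

    source: int
    target: int
    synapse: Optional[SynapseParameters] = None


class Network:
    """Directed multigraph of nodes and edges with sequential integer ids."""

    def __init__(self, allow_self_loops: bool = False) -> None:
        self.nodes: dict[int, NodeSpec] = {}
        self.edges: list[Edge] = []
        self.workspace: dict = {"units": "SI"}
        self.allow_self_loops = allow_self_loops
        self._next_id = 0

    # -- construction -------------------------------------------------------

    def add_node(self, spec: NodeSpec) -> int:
        """Register a node and return its fresh id; labels must be unique."""
        if spec.label is not None:
            for other in self.nodes.values():
                if other.label == spec.label:
                    raise NetworkError(f"duplicate node label: {spec.label!r}")
        nid = self._next_id
        self._next_id += 1
        self.nodes[nid] = spec
        return nid

    def add(self, kind: NodeKind, params: object = None, label: Optional[str] = None) -> int:
        """Convenience wrapper: build the NodeSpec and add it."""
        return self.add_node(NodeSpec(kind, params, label))

    def connect(
        self, src: int, dst: int, syn: Optional[SynapseParameters] = None
    ) -> int:
        """Append an edge and return its index.

        Spike-carrying edges (spike source or neuron -> neuron) get default
        SynapseParameters when none are given (event sources get the strong
        touch default).  Injection (dc/ac -> neuron) and sensor edges carry
        no synapse.
        """
        for endpoint in (src, dst):
            if endpoint not in self.nodes:
                raise NetworkError(f"unknown node id: {endpoint}")
        src_kind = self.nodes[src].kind
        dst_kind = self.nodes[dst].kind

        if src_kind in SENSOR_KINDS:
            raise NetworkError(f"sensors cannot drive other nodes (node {src})")
        if dst_kind in SENSOR_KINDS:
            if src_kind not in NEURON_KINDS:
                raise NetworkError(
                    f"only neurons can be recorded by sensors "
                    f"({src_kind} {src} -> {dst_kind} {dst})"
                )
            syn = None
        elif dst_kind in NEURON_KINDS:
            if src == dst and not self.allow_self_loops:
                raise NetworkError(f"self-loop synapse on neuron {src} not allowed")
            if src_kind in CURRENT_SOURCE_KINDS:
                syn = None  # direct injection, no synapse dynamics
            elif syn is None:
                syn = TOUCH_SYNAPSE if src_kind == "event_source" else SynapseParameters()
        else:
            raise NetworkError(
                f"edges must target a neuron or a sensor "
                f"({src_kind} {src} -> {dst_kind} {dst})"
            )

        self.edges.append(Edge(src, dst, syn))
        return len(self.edges) - 1

    # -- queries ------------------------------------------------------------

    def node_ids(self, *kinds: NodeKind) -> list[int]:
        """Ids of nodes of the given kinds (all nodes if none given), sorted."""
        if not kinds:
            return sorted(self.nodes)
        return sorted(i for i, s in self.nodes.items() if s.kind in kinds)

    def by_label(self, label: str) -> int:
        """Id of the node carrying ``label``."""
        for nid, spec in self.nodes.items():
            if spec.label == label:
                return nid
        raise NetworkError(f"no node labeled {label!r}")

    def incoming(self, nid: int) -> list[Edge]:
        return [e for e in self.edges if e.target == nid]

    def outgoing(self, nid: int) -> list[Edge]:
        return [e for e in self.edges if e.source == nid]

    def remove_edge(self, index: int) -> Edge:
        """Remove and return the edge at ``index`` (used by paired experiments)."""
        return self.edges.pop(index)

    def polarity_of(self, nid: int) -> Polarity:
        """Output sign of a neuron or spike source."""
        spec = self.nodes[nid]
        params = spec.params
        if hasattr(params, "polarity"):
            return params.polarity
        return Polarity.EXCITATORY

    def summary(self) -> str:
        kinds: dict[str, int] = {}
        for spec in self.nodes.values():
            kinds[spec.kind] = kinds.get(spec.kind, 0) + 1
        parts = ", ".join(f"{n} {k}" for k, n in sorted(kinds.items()))
        return f"{len(self.nodes)} nodes ({parts}), {len(self.edges)} edges"
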