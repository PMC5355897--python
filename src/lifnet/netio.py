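"""JSON serialization of networks.

A saved document has exactly four top-level keys::

    {"fileFormatVersion": 3, "edges": [...], "nodes": [...], "workspace": {...}}

``fileFormatVersion`` is 3 and is this schema's version; earlier versions are
rejected as unsupported.  Node properties use snake_case names mirroring the
in-memory parameter types, with all quantities in SI units (a ``"units":
"SI"`` marker lives in the workspace metadata).  Unknown workspace content is
preserved opaquely across a load/save round trip.  Serialization is canonical
(sorted keys, two-space indent, trailing newline), so save -> load -> save is
byte-identical.

A JSON-Schema document describing the format ships in
``lifnet/schemas/network.schema.json``; validation itself is performed by the
checks in this module so the package has no schema-library dependency.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Union

from .core import NeuronParameters, Polarity, SynapseParameters
from .network import (
    NODE_KINDS,
    Network,
    NodeSpec,
    VisualInputParams,
)
from .receptive_fields import VisualStimulus, make_kernel
from .sensors import RateMeterParams
from .stimulators import CurrentSourceParams, EventSchedule, GeneratorParams

__all__ = [
    "FILE_FORMAT_VERSION",
    "NetIOError",
    "UnsupportedVersionError",
    "DanglingEdgeError",
    "save_network",
    "load_network",
    "network_to_document",
    "document_to_network",
    "validate_document",
    "canonical_json",
]

FILE_FORMAT_VERSION = 3
_TOP_LEVEL_KEYS = {"fileFormatVersion", "edges", "nodes", "workspace"}


class NetIOError(ValueError):
    """Malformed or invalid network document."""


class UnsupportedVersionError(NetIOError):
    """Document version not recognized by this loader."""


class DanglingEdgeError(NetIOError):
    """Edge endpoint does not resolve to a declared node."""


# --- serialization ---------------------------------------------------------


def _node_properties(spec: NodeSpec) -> dict:
    p = spec.params
    if spec.kind == "neuron":
        d = asdict(p)
        d["polarity"] = p.polarity.value
        return d
    if spec.kind in ("dc_source", "ac_source"):
        return {"amplitude": p.amplitude, "frequency": p.frequency}
    if spec.kind in ("regular_generator", "poisson_generator"):
        return {"rate": p.rate, "polarity": p.polarity.value}
    if spec.kind == "event_source":
        return {
            "activation_times": list(p.activation_times),
            "polarity": p.polarity.value,
        }
    if spec.kind == "visual_input":
        H, W = p.kernel.shape
        return {
            "kernel": {"kind": p.kernel.kind, "H": H, "W": W, **p.kernel.params},
            "image": [[float(v) for v in row] for row in p.image.image],
            "gain": p.gain,
            "polarity": p.polarity.value,
        }
    if spec.kind == "firing_rate_meter":
        return {"sigma_w": p.sigma_w, "rate_min": p.rate_min, "rate_max": p.rate_max}
    return {}  # voltmeter, spike_detector


def _node_from_entry(entry: dict) -> NodeSpec:
    kind = entry["kind"]
    props = dict(entry.get("properties", {}))
    if kind == "neuron":
        params = NeuronParameters(**{**props, "polarity": Polarity(props.get("polarity", "excitatory"))})
    elif kind in ("dc_source", "ac_source"):
        params = CurrentSourceParams(**props)
    elif kind in ("regular_generator", "poisson_generator"):
        params = GeneratorParams(
            rate=props.get("rate", 10.0),
            polarity=Polarity(props.get("polarity", "excitatory")),
        )
    elif kind == "event_source":
        params = EventSchedule(
            activation_times=tuple(props.get("activation_times", ())),
            polarity=Polarity(props.get("polarity", "excitatory")),
        )
    elif kind == "visual_input":
        kspec = dict(props["kernel"])
        kind_name, H, W = kspec.pop("kind"), kspec.pop("H"), kspec.pop("W")
        params = VisualInputParams(
            kernel=make_kernel(kind_name, H, W, kspec),
            image=VisualStimulus(props["image"]),
            gain=props.get("gain", 100.0),
            polarity=Polarity(props.get("polarity", "excitatory")),
        )
    elif kind == "firing_rate_meter":
        params = RateMeterParams(**props)
    elif kind in NODE_KINDS:
        params = None
    else:
        raise NetIOError(f"unknown node kind: {kind!r}")
    return NodeSpec(kind=kind, params=params, label=entry.get("label"))


def network_to_document(net: Network) -> dict:
    """Serialize a network into the plain-dict document form."""
    nodes = []
    for nid in sorted(net.nodes):
        spec = net.nodes[nid]
        entry = {"id": nid, "kind": spec.kind, "properties": _node_properties(spec)}
        if spec.label is not None:
            entry["label"] = spec.label
        nodes.append(entry)
    edges = []
    for e in net.edges:
        entry = {"source": e.source, "target": e.target}
        entry["synapse"] = asdict(e.synapse) if e.synapse is not None else None
        edges.append(entry)
    return {
        "fileFormatVersion": FILE_FORMAT_VERSION,
        "edges": edges,
        "nodes": nodes,
        "workspace": dict(net.workspace),
    }


def validate_document(doc: dict) -> None:
    """Raise a :class:`NetIOError` subclass if the document is invalid."""
    if not isinstance(doc, dict):
        raise NetIOError("document must be a JSON object")
    keys = set(doc)
    if keys != _TOP_LEVEL_KEYS:
        raise NetIOError(
            f"top-level keys must be exactly {sorted(_TOP_LEVEL_KEYS)}, "
            f"got {sorted(keys)}"
        )
    version = doc["fileFormatVersion"]
    if version != FILE_FORMAT_VERSION:
        raise UnsupportedVersionError(
            f"unsupported fileFormatVersion: found {version!r}, "
            f"supported: {FILE_FORMAT_VERSION}"
        )
    if not isinstance(doc["nodes"], list) or not isinstance(doc["edges"], list):
        raise NetIOError("'nodes' and 'edges' must be arrays")
    if not isinstance(doc["workspace"], dict):
        raise NetIOError("'workspace' must be an object")
    ids = set()
    for entry in doc["nodes"]:
        if not isinstance(entry, dict) or "id" not in entry or "kind" not in entry:
            raise NetIOError(f"malformed node entry: {entry!r}")
        if entry["kind"] not in NODE_KINDS:
            raise NetIOError(f"unknown node kind: {entry['kind']!r}")
        if entry["id"] in ids:
            raise NetIOError(f"duplicate node id: {entry['id']}")
        ids.add(entry["id"])
    for entry in doc["edges"]:
        if not isinstance(entry, dict) or "source" not in entry or "target" not in entry:
            raise NetIOError(f"malformed edge entry: {entry!r}")
        for end in ("source", "target"):
            if entry[end] not in ids:
                raise DanglingEdgeError(
                    f"edge {end} references missing node id {entry[end]}"
                )


def document_to_network(doc: dict) -> Network:
    """Rebuild a network from a validated document.

    Node ids are reassigned sequentially in ascending document-id order and
    edge endpoints remapped accordingly; defaults fill omitted properties.
    """
    validate_document(doc)
    net = Network()
    net.workspace = dict(doc["workspace"])
    id_map = {}
    for entry in sorted(doc["nodes"], key=lambda e: e["id"]):
        id_map[entry["id"]] = net.add_node(_node_from_entry(entry))
    for entry in doc["edges"]:
        syn = entry.get("synapse")
        net.connect(
            id_map[entry["source"]],
            id_map[entry["target"]],
            SynapseParameters(**syn) if syn is not None else None,
        )
    return net


def canonical_json(doc: dict) -> str:
    """Canonical text form: sorted keys, two-space indent, trailing newline."""
    return json.dumps(doc, sort_keys=True, indent=2, allow_nan=False) + "\n"


def save_network(net: Network, destination: Union[str, Path, None] = None) -> dict:
    """Serialize ``net``; if ``destination`` is given, write the canonical
    JSON text there.  Returns the document dict."""
    doc = network_to_document(net)
    if destination is not None:
        Path(destination).write_text(canonical_json(doc), encoding="utf-8")
    return doc


def load_network(source: Union[str, Path, dict]) -> Network:
    """Load a network from a path, JSON text, or already-parsed document."""
    if isinstance(source, dict):
        return document_to_network(source)
    path = Path(source)
    try:
        text = path.read_text(encoding="utf-8")
    except (OSError, ValueError) as exc:
        raise NetIOError(f"cannot read network file {source!r}: {exc}") from exc
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise NetIOError(f"malformed JSON in {source!r}: {exc}") from exc
    return document_to_network(doc)
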