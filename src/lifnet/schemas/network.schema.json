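{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "https://example.org/lifnet/network.schema.json",
  "title": "lifnet network document",
  "description": "A saved network: typed nodes, synapse edges, and opaque workspace metadata. All physical quantities are SI floats (volt, ampere, ohm, farad, siemens, second, hertz).",
  "type": "object",
  "required": ["fileFormatVersion", "edges", "nodes", "workspace"],
  "additionalProperties": false,
  "properties": {
    "fileFormatVersion": {
      "const": 3,
      "description": "Schema version; earlier versions are rejected by the loader."
    },
    "nodes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "kind", "properties"],
        "additionalProperties": false,
        "properties": {
          "id": {"type": "integer", "minimum": 0},
          "kind": {
            "enum": [
              "neuron",
              "dc_source",
              "ac_source",
              "regular_generator",
              "poisson_generator",
              "event_source",
              "visual_input",
              "voltmeter",
              "spike_detector",
              "firing_rate_meter"
            ]
          },
          "label": {"type": "string"},
          "properties": {
            "type": "object",
            "description": "Kind-specific snake_case parameters; omitted entries take the library defaults.",
            "properties": {
              "Cm": {"type": "number", "exclusiveMinimum": 0},
              "Rm": {"type": "number", "exclusiveMinimum": 0},
              "Vr": {"type": "number"},
              "Vreset": {"type": "number"},
              "Vthres": {"type": "number"},
              "tau_r": {"type": "number", "minimum": 0},
              "polarity": {"enum": ["excitatory", "inhibitory"]},
              "adaptive": {"type": "boolean"},
              "tau_adapt": {"type": "number", "exclusiveMinimum": 0},
              "delta_g_adapt": {"type": "number", "minimum": 0},
              "amplitude": {"type": "number"},
              "frequency": {"type": "number", "minimum": 0},
              "rate": {"type": "number", "minimum": 0},
              "activation_times": {
                "type": "array",
                "items": {"type": "number", "minimum": 0}
              },
              "kernel": {
                "type": "object",
                "required": ["kind", "H", "W"],
                "properties": {
                  "kind": {"enum": ["edge", "dog", "gabor"]},
                  "H": {"type": "integer", "minimum": 2},
                  "W": {"type": "integer", "minimum": 2}
                }
              },
              "image": {
                "type": "array",
                "items": {
                  "type": "array",
                  "items": {"type": "number", "minimum": 0, "maximum": 1}
                }
              },
              "gain": {"type": "number", "minimum": 0},
              "sigma_w": {"type": "number", "exclusiveMinimum": 0},
              "rate_min": {"type": "number"},
              "rate_max": {"type": "number"}
            }
          }
        }
      }
    },
    "edges": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["source", "target", "synapse"],
        "additionalProperties": false,
        "properties": {
          "source": {"type": "integer"},
          "target": {"type": "integer"},
          "synapse": {
            "oneOf": [
              {"type": "null"},
              {
                "type": "object",
                "additionalProperties": false,
                "properties": {
                  "peak_current": {"type": "number", "minimum": 0},
                  "tau_syn": {"type": "number", "exclusiveMinimum": 0},
                  "delay": {"type": "number", "minimum": 0}
                }
              }
            ]
          }
        }
      }
    },
    "workspace": {
      "type": "object",
      "description": "Free-form metadata (e.g. the units marker, editor view state); preserved opaquely and ignored by the engine."
    }
  }
}
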