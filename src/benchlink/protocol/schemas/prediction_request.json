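{
  "$defs": {
    "SequenceRecord": {
      "additionalProperties": false,
      "properties": {
        "sequence_id": {
          "minLength": 1,
          "title": "Sequence Id",
          "type": "string"
        },
        "sequence": {
          "title": "Sequence",
          "type": "string"
        }
      },
      "required": [
        "sequence_id",
        "sequence"
      ],
      "title": "SequenceRecord",
      "type": "object"
    },
    "TaskSpec": {
      "additionalProperties": false,
      "description": "One requested prediction task: a phenomenon in a biological context.\n\n``molecule`` is a free label (a TF name, a histone mark, \"mRNA\", ...) and\nmay be empty when the phenomenon implies it.  No assay-type field exists:\ntasks describe the biochemical phenomenon, never the assay that measured\nit.",
      "properties": {
        "task_id": {
          "minLength": 1,
          "title": "Task Id",
          "type": "string"
        },
        "phenomenon": {
          "enum": [
            "binding",
            "accessibility",
            "conformation",
            "expression"
          ],
          "title": "Phenomenon",
          "type": "string"
        },
        "molecule": {
          "default": "",
          "title": "Molecule",
          "type": "string"
        },
        "cell_type": {
          "default": "",
          "title": "Cell Type",
          "type": "string"
        },
        "species": {
          "default": "",
          "title": "Species",
          "type": "string"
        },
        "readout": {
          "default": "point",
          "enum": [
            "point",
            "track"
          ],
          "title": "Readout",
          "type": "string"
        },
        "strand_policy": {
          "default": "sense",
          "enum": [
            "sense",
            "antisense",
            "unstranded"
          ],
          "title": "Strand Policy",
          "type": "string"
        },
        "prediction_window": {
          "anyOf": [
            {
              "maxItems": 2,
              "minItems": 2,
              "prefixItems": [
                {
                  "type": "integer"
                },
                {
                  "type": "integer"
                }
              ],
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Prediction Window"
        },
        "upstream_flank": {
          "default": "",
          "title": "Upstream Flank",
          "type": "string"
        },
        "downstream_flank": {
          "default": "",
          "title": "Downstream Flank",
          "type": "string"
        }
      },
      "required": [
        "task_id",
        "phenomenon"
      ],
      "title": "TaskSpec",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "Everything an evaluator sends to a predictor in one exchange.\n\n``sequences`` is an ordered list of records rather than a mapping so that\nduplicate sequence ids arriving on the wire are detectable and rejected.\n``accepted_formats`` is the format negotiation: the request itself always\ntravels as JSON-capable content, and the predictor replies in the first\nlisted format it supports.",
  "properties": {
    "message_type": {
      "const": "prediction_request",
      "default": "prediction_request",
      "title": "Message Type",
      "type": "string"
    },
    "protocol_version": {
      "default": "1.0.0",
      "title": "Protocol Version",
      "type": "string"
    },
    "request_id": {
      "minLength": 1,
      "title": "Request Id",
      "type": "string"
    },
    "tasks": {
      "items": {
        "$ref": "#/$defs/TaskSpec"
      },
      "title": "Tasks",
      "type": "array"
    },
    "sequences": {
      "items": {
        "$ref": "#/$defs/SequenceRecord"
      },
      "title": "Sequences",
      "type": "array"
    },
    "accepted_formats": {
      "items": {
        "enum": [
          "json",
          "msgpack"
        ],
        "type": "string"
      },
      "title": "Accepted Formats",
      "type": "array"
    }
  },
  "required": [
    "request_id",
    "tasks",
    "sequences"
  ],
  "title": "PredictionRequest",
  "type": "object"
}
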