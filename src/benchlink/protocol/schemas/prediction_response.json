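{
  "$defs": {
    "Decline": {
      "additionalProperties": false,
      "properties": {
        "task_id": {
          "title": "Task Id",
          "type": "string"
        },
        "reason": {
          "minLength": 1,
          "title": "Reason",
          "type": "string"
        }
      },
      "required": [
        "task_id",
        "reason"
      ],
      "title": "Decline",
      "type": "object"
    },
    "LabelTriplet": {
      "additionalProperties": false,
      "properties": {
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
        "molecule": {
          "default": "",
          "title": "Molecule",
          "type": "string"
        }
      },
      "title": "LabelTriplet",
      "type": "object"
    },
    "PredictionRecord": {
      "additionalProperties": false,
      "properties": {
        "task_id": {
          "title": "Task Id",
          "type": "string"
        },
        "sequence_id": {
          "title": "Sequence Id",
          "type": "string"
        },
        "value": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "$ref": "#/$defs/Track"
            }
          ],
          "title": "Value"
        }
      },
      "required": [
        "task_id",
        "sequence_id",
        "value"
      ],
      "title": "PredictionRecord",
      "type": "object"
    },
    "Track": {
      "additionalProperties": false,
      "description": "Positional prediction values: ``values[i]`` covers the half-open bin\n``[origin + i*bin_width, origin + (i+1)*bin_width)`` in benchmark\nsequence coordinates.",
      "properties": {
        "values": {
          "items": {
            "type": "number"
          },
          "title": "Values",
          "type": "array"
        },
        "bin_width": {
          "minimum": 1,
          "title": "Bin Width",
          "type": "integer"
        },
        "origin": {
          "default": 0,
          "minimum": 0,
          "title": "Origin",
          "type": "integer"
        }
      },
      "required": [
        "values",
        "bin_width"
      ],
      "title": "Track",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "Predictor reply: per-(task, sequence) predictions plus explicit\ndeclines.  ``resolved_tasks`` records the concrete labels the model\nactually used so the evaluator can audit matcher substitutions.",
  "properties": {
    "message_type": {
      "const": "prediction_response",
      "default": "prediction_response",
      "title": "Message Type",
      "type": "string"
    },
    "protocol_version": {
      "default": "1.0.0",
      "title": "Protocol Version",
      "type": "string"
    },
    "request_id": {
      "title": "Request Id",
      "type": "string"
    },
    "predictions": {
      "items": {
        "$ref": "#/$defs/PredictionRecord"
      },
      "title": "Predictions",
      "type": "array"
    },
    "resolved_tasks": {
      "additionalProperties": {
        "$ref": "#/$defs/LabelTriplet"
      },
      "title": "Resolved Tasks",
      "type": "object"
    },
    "declines": {
      "items": {
        "$ref": "#/$defs/Decline"
      },
      "title": "Declines",
      "type": "array"
    }
  },
  "required": [
    "request_id"
  ],
  "title": "PredictionResponse",
  "type": "object"
}
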