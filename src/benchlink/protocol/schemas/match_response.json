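{
  "additionalProperties": false,
  "properties": {
    "message_type": {
      "const": "match_response",
      "default": "match_response",
      "title": "Message Type",
      "type": "string"
    },
    "protocol_version": {
      "default": "1.0.0",
      "title": "Protocol Version",
      "type": "string"
    },
    "best_choice": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Best Choice"
    },
    "tier": {
      "default": "none",
      "enum": [
        "exact",
        "lexical",
        "syntactic",
        "semantic",
        "none"
      ],
      "title": "Tier",
      "type": "string"
    },
    "confidence": {
      "default": 0.0,
      "maximum": 1.0,
      "minimum": 0.0,
      "title": "Confidence",
      "type": "number"
    }
  },
  "title": "MatchResponse",
  "type": "object"
}
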