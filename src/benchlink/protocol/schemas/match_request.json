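{
  "additionalProperties": false,
  "description": "Ask the matcher to align a fuzzy label onto a predictor's choices.",
  "properties": {
    "message_type": {
      "const": "match_request",
      "default": "match_request",
      "title": "Message Type",
      "type": "string"
    },
    "protocol_version": {
      "default": "1.0.0",
      "title": "Protocol Version",
      "type": "string"
    },
    "term": {
      "minLength": 1,
      "title": "Term",
      "type": "string"
    },
    "choices": {
      "items": {
        "type": "string"
      },
      "minItems": 1,
      "title": "Choices",
      "type": "array"
    },
    "category": {
      "enum": [
        "cell_type",
        "species",
        "molecule"
      ],
      "title": "Category",
      "type": "string"
    }
  },
  "required": [
    "term",
    "choices",
    "category"
  ],
  "title": "MatchRequest",
  "type": "object"
}
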