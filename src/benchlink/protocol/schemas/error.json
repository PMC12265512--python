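{
  "additionalProperties": false,
  "description": "Protocol-level error reply (validation failure, framing trouble).",
  "properties": {
    "message_type": {
      "const": "error",
      "default": "error",
      "title": "Message Type",
      "type": "string"
    },
    "protocol_version": {
      "default": "1.0.0",
      "title": "Protocol Version",
      "type": "string"
    },
    "error": {
      "title": "Error",
      "type": "string"
    },
    "field": {
      "default": "",
      "title": "Field",
      "type": "string"
    },
    "request_id": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Request Id"
    }
  },
  "required": [
    "error"
  ],
  "title": "ErrorMessage",
  "type": "object"
}
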