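"""Predictor service: a scoring function served over the wire protocol."""

from __future__ import annotations

import logging
from typing import Optional

from ..protocol import (
    ErrorMessage,
    MessageServer,
    PredictionRequest,
)
from ..protocol.codec import MAX_PAYLOAD
from .handler import MatcherLike, Model, handle_request
from .manifest import CapabilityManifest

log = logging.getLogger("benchlink.predictor")


def build_predictor_handler(
    model: Model,
    manifest: CapabilityManifest,
    matcher: Optional[MatcherLike] = None,
):
    def handler(message):
        if not isinstance(message, PredictionRequest):
            return ErrorMessage(
                error=f"predictor cannot handle {message.message_type!r}",
                field="message_type",
            )
        response = handle_request(message, model, manifest, matcher)
        log.info(
            "request %s: %d tasks, %d predictions, %d declines",
            message.request_id, len(message.tasks),
            len(response.predictions), len(response.declines),
        )
        return response

    return handler


def build_predictor_server(
    host: str = "127.0.0.1",
    port: int = 0,
    model: Model = None,
    manifest: CapabilityManifest = None,
    matcher: Optional[MatcherLike] = None,
    max_payload: int = MAX_PAYLOAD,
) -> MessageServer:
    """Construct (but do not start) a predictor server."""
    return MessageServer(
        host,
        port,
        build_predictor_handler(model, manifest, matcher),
        name=manifest.name if manifest else "predictor",
        max_payload=max_payload,
    )


def serve_predictor(
    host: str,
    port: int,
    model: Model,
    manifest: CapabilityManifest,
    matcher: Optional[MatcherLike] = None,
) -> None:
    """Blocking entry point used by the CLI."""
    server = build_predictor_server(host, port, model, manifest, matcher)
    try:
        server.serve_forever()
    finally:
        server.stop()
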