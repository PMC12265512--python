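"""Matcher service: answers MatchRequest messages over the wire protocol.

Stateless between requests; one backend per category so synonym lookups use
the right vocabulary.  An external language-model backend can be plugged in
through :class:`RemoteMatchBackend`, which speaks the same request/response
contract against another matcher-compatible endpoint (disabled by default —
the deterministic backend needs no model download and is reproducible).
"""

from __future__ import annotations

from typing import Optional, Sequence

from ..protocol import (
    ErrorMessage,
    MatchRequest,
    MatchResponse,
    Message,
    MessageServer,
    request as wire_request,
)
from .core import SynonymTable, match_one, tournament_match


def build_match_handler(table: Optional[SynonymTable] = None, chunk_size: int = 20):
    tbl = table if table is not None else SynonymTable.default()

    def handler(message: Message) -> Message:
        if not isinstance(message, MatchRequest):
            return ErrorMessage(
                error=f"matcher cannot handle {message.message_type!r}",
                field="message_type",
            )
        def backend(term: str, choices: Sequence[str]) -> MatchResponse:
            return match_one(term, choices, tbl, message.category)
        return tournament_match(message.term, message.choices, chunk_size, backend)

    return handler


def build_matcher_server(
    host: str = "127.0.0.1",
    port: int = 0,
    table: Optional[SynonymTable] = None,
    chunk_size: int = 20,
) -> MessageServer:
    """Construct (but do not start) a matcher server; ``server.port`` holds
    the bound port, useful with ``port=0``."""
    return MessageServer(
        host, port, build_match_handler(table, chunk_size), name="matcher"
    )


def serve_matcher(
    host: str,
    port: int,
    table: Optional[SynonymTable] = None,
    chunk_size: int = 20,
) -> None:
    """Blocking entry point used by the CLI."""
    server = build_matcher_server(host, port, table, chunk_size)
    try:
        server.serve_forever()
    finally:
        server.stop()


class MatcherClient:
    """Thin client: one MatchRequest/MatchResponse exchange per call."""

    def __init__(self, host: str, port: int, *, timeout: float = 30.0):
        self.host, self.port, self.timeout = host, port, timeout

    def match(self, term: str, choices: Sequence[str], category: str) -> MatchResponse:
        reply = wire_request(
            self.host,
            self.port,
            MatchRequest(term=term, choices=list(choices), category=category),
            timeout=self.timeout,
        )
        if isinstance(reply, MatchResponse):
            return reply
        raise RuntimeError(f"matcher returned {reply.message_type}: {reply}")


class RemoteMatchBackend:
    """Backend interface for an external (e.g. LLM-served) matcher endpoint.

    Satisfies the same ``(term, choices) -> MatchResponse`` contract as the
    deterministic backend, so :func:`tournament_match` can chunk candidate
    lists to fit a bounded context window.  Configuration only — no model is
    bundled or downloaded.
    """

    def __init__(self, host: str, port: int, category: str = "cell_type",
                 *, timeout: float = 60.0):
        self._client = MatcherClient(host, port, timeout=timeout)
        self.category = category

    def __call__(self, term: str, choices: Sequence[str]) -> MatchResponse:
        return self._client.match(term, choices, self.category)
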