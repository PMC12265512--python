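"""TCP transport: a sequential message server and a client helper.

Servers bind to a user-specified host and port (port 0 picks a free one),
listen, and serve connections one at a time; each connection may carry any
number of request/response exchanges.  Concurrency is deliberately absent:
sequential service is the protocol contract, and it keeps request handling
a pure function of its inputs.
"""

from __future__ import annotations

import logging
import socket
import threading
from typing import Callable, Optional

from .codec import (
    FramingError,
    MAX_PAYLOAD,
    UnsupportedFormatError,
    decode_envelope,
    encode_message,
)
from .messages import (
    ErrorMessage,
    Message,
    MessageValidationError,
    PredictionRequest,
    ProtocolError,
)

log = logging.getLogger("benchlink.transport")


class EndpointError(ProtocolError):
    pass


class BindError(EndpointError):
    pass


class ConnectError(EndpointError):
    pass


class IdleTimeoutError(EndpointError):
    pass


Handler = Callable[[Message], Message]


def _reply_format(message: Message, arrival_format: str, supported: tuple[str, ...]) -> str:
    """Format negotiation: a prediction request names its accepted formats and
    the server answers in the first one it supports; every other message is
    answered in the format it arrived in."""
    if isinstance(message, PredictionRequest):
        for fmt in message.accepted_formats:
            if fmt in supported:
                return fmt
        return "json"
    return arrival_format if arrival_format in supported else "json"


class MessageServer:
    """Serve a ``Message -> Message`` handler over loopback or network TCP.

    Use as a context manager or call :meth:`start` / :meth:`stop`; the bound
    port is available as :attr:`port` (useful with ``port=0``).
    """

    def __init__(
        self,
        host: str,
        port: int,
        handler: Handler,
        *,
        supported_formats: tuple[str, ...] = ("json", "msgpack"),
        max_payload: int = MAX_PAYLOAD,
        name: str = "server",
    ):
        self.host = host
        self.handler = handler
        self.supported_formats = supported_formats
        self.max_payload = max_payload
        self.name = name
        self._stop = threading.Event()
        self._thread: Optional[threading.Thread] = None
        try:
            self._sock = socket.create_server((host, port))
        except OSError as exc:
            raise BindError(f"cannot bind {name} to {host}:{port}: {exc}") from exc
        self._sock.settimeout(0.1)
        self.port = self._sock.getsockname()[1]

    def start(self) -> "MessageServer":
        self._thread = threading.Thread(target=self.serve_forever, daemon=True)
        self._thread.start()
        return self

    def stop(self) -> None:
        self._stop.set()
        if self._thread is not None:
            self._thread.join(timeout=5)
            self._thread = None
        self._sock.close()

    def __enter__(self) -> "MessageServer":
        return self.start()

    def __exit__(self, *exc) -> None:
        self.stop()

    def serve_forever(self) -> None:
        while not self._stop.is_set():
            try:
                conn, addr = self._sock.accept()
            except socket.timeout:
                continue
            except OSError:
                break
            with conn:
                self._serve_connection(conn, addr)

    def _serve_connection(self, conn: socket.socket, addr) -> None:
        conn.settimeout(30)
        reader = conn.makefile("rb")
        while not self._stop.is_set():
            try:
                message, fmt = decode_envelope(reader, max_payload=self.max_payload)
            except FramingError as exc:
                if exc.kind == "short header" and "closed" in str(exc):
                    return  # clean end of connection
                log.warning("%s: framing error from %s: %s", self.name, addr, exc)
                self._send_error(conn, f"framing error: {exc}", "json")
                return
            except UnsupportedFormatError as exc:
                self._send_error(conn, str(exc), "json")
                return
            except MessageValidationError as exc:
                self._send_error(conn, str(exc), "json", field=exc.field,
                                 request_id=exc.request_id)
                continue
            except (socket.timeout, OSError) as exc:
                log.warning("%s: connection error from %s: %s", self.name, addr, exc)
                return
            reply_fmt = _reply_format(message, fmt, self.supported_formats)
            try:
                reply = self.handler(message)
            except Exception as exc:  # handler bug: report, keep serving
                log.exception("%s: handler failure", self.name)
                reply = ErrorMessage(error=f"internal error: {exc}")
            try:
                conn.sendall(encode_message(reply, reply_fmt))
            except OSError as exc:
                log.warning("%s: send failed to %s: %s", self.name, addr, exc)
                return

    def _send_error(self, conn, msg: str, fmt: str, field: str = "",
                    request_id: Optional[str] = None) -> None:
        try:
            conn.sendall(encode_message(
                ErrorMessage(error=msg, field=field, request_id=request_id), fmt))
        except OSError:
            pass


class Connection:
    """Client side of one TCP connection; supports repeated exchanges."""

    def __init__(self, host: str, port: int, *, timeout: float = 30.0):
        self.host, self.port = host, port
        try:
            self._sock = socket.create_connection((host, port), timeout=timeout)
        except ConnectionRefusedError as exc:
            raise ConnectError(f"connection refused by {host}:{port}") from exc
        except (socket.timeout, OSError) as exc:
            raise ConnectError(f"cannot connect to {host}:{port}: {exc}") from exc
        self._reader = self._sock.makefile("rb")

    def exchange(self, message: Message, format: str = "json") -> Message:
        try:
            self._sock.sendall(encode_message(message, format))
            reply, _ = decode_envelope(self._reader)
        except socket.timeout as exc:
            raise IdleTimeoutError(
                f"timeout waiting for {self.host}:{self.port}") from exc
        return reply

    def close(self) -> None:
        self._reader.close()
        self._sock.close()

    def __enter__(self) -> "Connection":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def request(host: str, port: int, message: Message, *, format: str = "json",
            timeout: float = 30.0) -> Message:
    """One request/response exchange on a fresh connection."""
    with Connection(host, port, timeout=timeout) as conn:
        return conn.exchange(message, format)
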