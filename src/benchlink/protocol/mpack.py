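"""Minimal MessagePack codec.

Implements the subset of the MessagePack wire format the protocol needs:
nil, booleans, integers, float32/float64, UTF-8 strings, raw bytes, arrays
and string-keyed maps.  Encoding is canonical for protocol payloads (floats
always as float64, shortest integer family member); decoding accepts the
full integer/float/str/bin/array/map families.
"""

from __future__ import annotations

import struct
from io import BytesIO
from typing import Any, BinaryIO


class MsgpackError(ValueError):
    pass


def packb(obj: Any) -> bytes:
    buf = BytesIO()
    _pack(obj, buf)
    return buf.getvalue()


def unpackb(data: bytes) -> Any:
    buf = BytesIO(data)
    obj = _unpack(buf)
    if buf.read(1):
        raise MsgpackError("trailing bytes after msgpack object")
    return obj


def _pack(obj: Any, out: BinaryIO) -> None:
    if obj is None:
        out.write(b"\xc0")
    elif obj is True:
        out.write(b"\xc3")
    elif obj is False:
        out.write(b"\xc2")
    elif isinstance(obj, int):
        _pack_int(obj, out)
    elif isinstance(obj, float):
        out.write(b"\xcb" + struct.pack(">d", obj))
    elif isinstance(obj, str):
        raw = obj.encode("utf-8")
        n = len(raw)
        if n <= 31:
            out.write(bytes([0xA0 | n]))
        elif n <= 0xFF:
            out.write(b"\xd9" + bytes([n]))
        elif n <= 0xFFFF:
            out.write(b"\xda" + struct.pack(">H", n))
        else:
            out.write(b"\xdb" + struct.pack(">I", n))
        out.write(raw)
    elif isinstance(obj, (bytes, bytearray)):
        n = len(obj)
        if n <= 0xFF:
            out.write(b"\xc4" + bytes([n]))
        elif n <= 0xFFFF:
            out.write(b"\xc5" + struct.pack(">H", n))
        else:
            out.write(b"\xc6" + struct.pack(">I", n))
        out.write(bytes(obj))
    elif isinstance(obj, (list, tuple)):
        n = len(obj)
        if n <= 15:
            out.write(bytes([0x90 | n]))
        elif n <= 0xFFFF:
            out.write(b"\xdc" + struct.pack(">H", n))
        else:
            out.write(b"\xdd" + struct.pack(">I", n))
        for item in obj:
            _pack(item, out)
    elif isinstance(obj, dict):
        n = len(obj)
        if n <= 15:
            out.write(bytes([0x80 | n]))
        elif n <= 0xFFFF:
            out.write(b"\xde" + struct.pack(">H", n))
        else:
            out.write(b"\xdf" + struct.pack(">I", n))
        for k, v in obj.items():
            if not isinstance(k, str):
                raise MsgpackError(f"map keys must be strings, got {type(k).__name__}")
            _pack(k, out)
            _pack(v, out)
    else:
        raise MsgpackError(f"cannot serialize type {type(obj).__name__}")


def _pack_int(i: int, out: BinaryIO) -> None:
    if 0 <= i <= 0x7F:
        out.write(bytes([i]))
    elif -32 <= i < 0:
        out.write(struct.pack("b", i))
    elif 0 <= i <= 0xFF:
        out.write(b"\xcc" + bytes([i]))
    elif 0 <= i <= 0xFFFF:
        out.write(b"\xcd" + struct.pack(">H", i))
    elif 0 <= i <= 0xFFFFFFFF:
        out.write(b"\xce" + struct.pack(">I", i))
    elif 0 <= i <= 0xFFFFFFFFFFFFFFFF:
        out.write(b"\xcf" + struct.pack(">Q", i))
    elif -0x80 <= i < 0:
        out.write(b"\xd0" + struct.pack("b", i))
    elif -0x8000 <= i < 0:
        out.write(b"\xd1" + struct.pack(">h", i))
    elif -0x80000000 <= i < 0:
        out.write(b"\xd2" + struct.pack(">i", i))
    elif -0x8000000000000000 <= i < 0:
        out.write(b"\xd3" + struct.pack(">q", i))
    else:
        raise MsgpackError(f"integer out of 64-bit range: {i}")


def _read(buf: BinaryIO, n: int) -> bytes:
    data = buf.read(n)
    if len(data) != n:
        raise MsgpackError("truncated msgpack data")
    return data


def _unpack(buf: BinaryIO) -> Any:
    head = _read(buf, 1)[0]
    if head <= 0x7F:
        return head
    if head >= 0xE0:
        return head - 0x100
    if 0x80 <= head <= 0x8F:
        return _unpack_map(buf, head & 0x0F)
    if 0x90 <= head <= 0x9F:
        return _unpack_array(buf, head & 0x0F)
    if 0xA0 <= head <= 0xBF:
        return _read(buf, head & 0x1F).decode("utf-8")
    if head == 0xC0:
        return None
    if head == 0xC2:
        return False
    if head == 0xC3:
        return True
    if head == 0xC4:
        return _read(buf, _read(buf, 1)[0])
    if head == 0xC5:
        return _read(buf, struct.unpack(">H", _read(buf, 2))[0])
    if head == 0xC6:
        return _read(buf, struct.unpack(">I", _read(buf, 4))[0])
    if head == 0xCA:
        return struct.unpack(">f", _read(buf, 4))[0]
    if head == 0xCB:
        return struct.unpack(">d", _read(buf, 8))[0]
    if head == 0xCC:
        return _read(buf, 1)[0]
    if head == 0xCD:
        return struct.unpack(">H", _read(buf, 2))[0]
    if head == 0xCE:
        return struct.unpack(">I", _read(buf, 4))[0]
    if head == 0xCF:
        return struct.unpack(">Q", _read(buf, 8))[0]
    if head == 0xD0:
        return struct.unpack("b", _read(buf, 1))[0]
    if head == 0xD1:
        return struct.unpack(">h", _read(buf, 2))[0]
    if head == 0xD2:
        return struct.unpack(">i", _read(buf, 4))[0]
    if head == 0xD3:
        return struct.unpack(">q", _read(buf, 8))[0]
    if head == 0xD9:
        return _read(buf, _read(buf, 1)[0]).decode("utf-8")
    if head == 0xDA:
        return _read(buf, struct.unpack(">H", _read(buf, 2))[0]).decode("utf-8")
    if head == 0xDB:
        return _read(buf, struct.unpack(">I", _read(buf, 4))[0]).decode("utf-8")
    if head == 0xDC:
        return _unpack_array(buf, struct.unpack(">H", _read(buf, 2))[0])
    if head == 0xDD:
        return _unpack_array(buf, struct.unpack(">I", _read(buf, 4))[0])
    if head == 0xDE:
        return _unpack_map(buf, struct.unpack(">H", _read(buf, 2))[0])
    if head == 0xDF:
        return _unpack_map(buf, struct.unpack(">I", _read(buf, 4))[0])
    raise MsgpackError(f"unsupported msgpack type byte 0x{head:02x}")


def _unpack_array(buf: BinaryIO, n: int) -> list:
    return [_unpack(buf) for _ in range(n)]


def _unpack_map(buf: BinaryIO, n: int) -> dict:
    out = {}
    for _ in range(n):
        k = _unpack(buf)
        if not isinstance(k, str):
            raise MsgpackError("map keys must be strings")
        out[k] = _unpack(buf)
    return out
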