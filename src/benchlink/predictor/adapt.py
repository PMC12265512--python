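"""Sequence adaptation: flanks, padding, cropping, strand handling.

Models have input contracts (fixed length, flank expectations) that benchmark
sequences rarely satisfy.  Adaptation attaches task flanks, then pads with N
or center-crops to the model's input length, tracking which interval of the
original benchmark sequence survives and where it sits in the adapted
sequence, so predictions can be mapped back to benchmark coordinates.
Cropping never removes the prediction window: the crop is shifted to contain
it, and if the window is wider than the model input the task is declined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from ..protocol.messages import TaskSpec

_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


class DeclineTask(Exception):
    """A task cannot be fulfilled; ``reason`` is a controlled short string."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class AdaptedSequence:
    """A model-ready sequence plus the offset map back to benchmark coords.

    ``orig_start``/``orig_end`` delimit the surviving interval of the
    unmodified benchmark sequence; ``adapted_start`` is where ``orig_start``
    sits inside ``sequence``.
    """

    sequence: str
    orig_start: int
    orig_end: int
    adapted_start: int

    def to_adapted(self, pos: int) -> int:
        """Benchmark coordinate -> adapted-sequence coordinate."""
        return pos - self.orig_start + self.adapted_start

    def to_original(self, pos: int) -> int:
        """Adapted-sequence coordinate -> benchmark coordinate."""
        return pos - self.adapted_start + self.orig_start


def adapt_sequence(seq: str, task: TaskSpec, L: Optional[int]) -> AdaptedSequence:
    """Attach flanks, then pad (with N, centered) or center-crop to length L.

    Raises :class:`DeclineTask` when the prediction window cannot survive.
    """
    up, down = task.upstream_flank, task.downstream_flank
    full = up + seq + down
    ups = len(up)
    window = task.prediction_window

    if L is None or len(full) == L:
        return AdaptedSequence(full, 0, len(seq), ups)

    if len(full) < L:
        left = (L - len(full)) // 2
        right = L - len(full) - left
        return AdaptedSequence("N" * left + full + "N" * right, 0, len(seq), left + ups)

    # Crop.  Window coordinates are on the unflanked benchmark sequence.
    if window is not None:
        ws_f, we_f = ups + window[0], ups + window[1]
        if we_f - ws_f > L:
            raise DeclineTask("window exceeds model input")
    else:
        ws_f = we_f = None

    c = (len(full) - L) // 2  # centered crop start
    if window is not None:
        lo = max(0, we_f - L)
        hi = min(ws_f, len(full) - L)
        c = min(max(c, lo), hi)

    orig_start = max(0, c - ups)
    orig_end = min(len(seq), c + L - ups)
    if orig_end <= orig_start:
        raise DeclineTask("no sequence within model input")
    return AdaptedSequence(full[c : c + L], orig_start, orig_end, ups + orig_start - c)
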