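"""Aggregation of model output: bins -> point, replicate tracks -> track."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from ..protocol.messages import Track


def aggregate_to_point(track: Track, window: tuple[int, int]) -> float:
    """Coverage-weighted mean of bin values over a half-open window.

    Bin ``i`` covers ``[origin + i*bw, origin + (i+1)*bw)``; each bin
    contributes its value weighted by its overlap with the window:
    ``sum(v_b * overlap_b) / sum(overlap_b)``.
    """
    ws, we = window
    if we <= ws:
        raise ValueError(f"empty window {window}")
    bw, origin = track.bin_width, track.origin
    values = np.asarray(track.values, dtype=float)
    starts = origin + bw * np.arange(len(values))
    overlaps = np.minimum(starts + bw, we) - np.maximum(starts, ws)
    overlaps = np.clip(overlaps, 0, None).astype(float)
    total = overlaps.sum()
    if total <= 0:
        raise RuntimeError(f"track does not overlap window {window}")
    return float((values * overlaps).sum() / total)


def aggregate_tracks(tracks: Sequence[Track], reduction: str = "mean") -> Track:
    """Element-wise reduction of replicate tracks with identical geometry."""
    if reduction != "mean":
        raise ValueError(f"unsupported reduction {reduction!r}")
    if not tracks:
        raise ValueError("no tracks to aggregate")
    first = tracks[0]
    for t in tracks[1:]:
        if (len(t.values), t.bin_width, t.origin) != (
            len(first.values), first.bin_width, first.origin,
        ):
            raise RuntimeError("track shape/geometry mismatch in aggregation")
    mean = np.mean([t.values for t in tracks], axis=0)
    return Track(values=[float(v) for v in mean], bin_width=first.bin_width,
                 origin=first.origin)
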