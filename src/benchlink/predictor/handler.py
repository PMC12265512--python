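"""Turning a scoring function + manifest into a protocol-compliant predictor.

The model plug-in contract: a callable ``model(sequence, labels)`` taking the
adapted DNA string and the resolved (cell_type, species, molecule) triplet,
returning either a scalar (point models) or a 1-D array of per-bin values
over the adapted sequence (track models, bin width from the manifest).  The
handler does everything else: task resolution (optionally via a matcher),
sequence adaptation, strand policy, readout aggregation, and assembling the
response with explicit declines.  ``handle_request`` is a pure function of
(request, model, manifest, matcher): identical requests yield identical
responses.
"""

from __future__ import annotations

import logging
from typing import Callable, Optional, Protocol, Union

import numpy as np

from ..protocol.messages import (
    Decline,
    LabelTriplet,
    PredictionRecord,
    PredictionRequest,
    PredictionResponse,
    TaskSpec,
    Track,
    PROTOCOL_VERSION,
    versions_compatible,
)
from .adapt import AdaptedSequence, DeclineTask, adapt_sequence, reverse_complement
from .aggregate import aggregate_to_point
from .manifest import CapabilityManifest

log = logging.getLogger("benchlink.predictor")

ModelOutput = Union[float, np.ndarray, list]
Model = Callable[[str, LabelTriplet], ModelOutput]

LABEL_FIELDS = ("cell_type", "species", "molecule")


class MatcherLike(Protocol):
    def match(self, term: str, choices: list[str], category: str): ...


def resolve_task(
    task: TaskSpec,
    manifest: CapabilityManifest,
    matcher: Optional[MatcherLike] = None,
    _cache: Optional[dict] = None,
) -> LabelTriplet:
    """Map a task's requested labels onto labels the model supports.

    Exact matches short-circuit; otherwise each label field is sent to the
    matcher against the manifest's choices for that field.  An empty
    requested field is unconstrained and resolves to the manifest's first
    value.  Raises :class:`DeclineTask` with a controlled reason when the
    phenomenon is unsupported, a field cannot be resolved, or the matcher is
    needed but unreachable.
    """
    if task.phenomenon not in manifest.phenomena:
        raise DeclineTask("unsupported phenomenon")
    triplets = manifest.phenomena[task.phenomenon]

    for t in triplets:  # exact triplet match needs no matcher round trip
        if all(
            getattr(task, f) == "" or getattr(task, f) == getattr(t, f)
            for f in LABEL_FIELDS
        ):
            return LabelTriplet(
                cell_type=t.cell_type, species=t.species, molecule=t.molecule
            )

    resolved = {}
    for field in LABEL_FIELDS:
        requested = getattr(task, field)
        choices = manifest.label_choices(task.phenomenon, field)
        if not requested or requested in choices:
            resolved[field] = requested if requested else (choices[0] if choices else "")
            continue
        if not choices:
            raise DeclineTask(f"unresolved {field}")
        if matcher is None:
            raise DeclineTask(f"unresolved {field}")
        key = (field, requested, tuple(choices))
        if _cache is not None and key in _cache:
            response = _cache[key]
        else:
            try:
                response = matcher.match(requested, choices, field)
            except Exception as exc:
                log.warning("matcher unreachable for %r: %s", requested, exc)
                raise DeclineTask("matcher unavailable") from exc
            if _cache is not None:
                _cache[key] = response
        if response.tier == "none":
            raise DeclineTask(f"unresolved {field}")
        resolved[field] = response.best_choice
    return LabelTriplet(**resolved)


def _score_track(model: Model, seq: str, labels: LabelTriplet) -> np.ndarray:
    out = np.asarray(model(seq, labels), dtype=float).ravel()
    if not np.all(np.isfinite(out)):
        raise RuntimeError("model produced non-finite track values")
    return out


def _apply_strand_policy(
    model: Model, adapted: AdaptedSequence, labels: LabelTriplet, task: TaskSpec,
    native_track: bool,
) -> Union[float, np.ndarray]:
    """Score under the requested strand policy.

    sense: the sequence as given.  antisense: the reverse complement, with
    track output reversed so coordinates stay on the benchmark orientation.
    unstranded: the mean of both orientations.
    """
    seq = adapted.sequence
    if native_track:
        fwd = _score_track(model, seq, labels)
        if task.strand_policy == "sense":
            return fwd
        rev = _score_track(model, reverse_complement(seq), labels)[::-1]
        if task.strand_policy == "antisense":
            return rev
        return (fwd + rev) / 2.0
    fwd = float(model(seq, labels))
    if task.strand_policy == "sense":
        return fwd
    rev = float(model(reverse_complement(seq), labels))
    if task.strand_policy == "antisense":
        return rev
    return (fwd + rev) / 2.0


def _track_to_benchmark(
    values: np.ndarray,
    adapted: AdaptedSequence,
    bin_width: int,
    window: tuple[int, int],
) -> Track:
    """Extract the bins overlapping a benchmark-coordinate window and re-home
    the track origin onto benchmark coordinates."""
    wa_s, wa_e = adapted.to_adapted(window[0]), adapted.to_adapted(window[1])
    covered = bin_width * len(values)
    if wa_s < 0 or wa_e > covered:
        raise DeclineTask("window exceeds model input")
    b0 = wa_s // bin_width
    b1 = -(-wa_e // bin_width)
    # never emit bins that start before benchmark coordinate 0
    min_b = max(0, -(-(adapted.adapted_start - adapted.orig_start) // bin_width))
    b0 = max(b0, min_b)
    origin = adapted.to_original(b0 * bin_width)
    return Track(
        values=[float(v) for v in values[b0:b1]], bin_width=bin_width, origin=origin
    )


def predict_task_sequence(
    model: Model,
    manifest: CapabilityManifest,
    task: TaskSpec,
    seq: str,
    labels: LabelTriplet,
) -> Union[float, Track]:
    """Adapt, score, and aggregate one (task, sequence) pair."""
    adapted = adapt_sequence(seq, task, manifest.input_length)
    window = task.prediction_window or (adapted.orig_start, adapted.orig_end)
    if not (adapted.orig_start <= window[0] and window[1] <= adapted.orig_end):
        raise DeclineTask("window exceeds model input")

    native_track = manifest.native_output == "track"
    out = _apply_strand_policy(model, adapted, labels, task, native_track)

    if task.readout == "point":
        if not native_track:
            return float(out)
        track = Track(
            values=[float(v) for v in out],
            bin_width=manifest.native_bin_width,
            origin=0,
        )
        wa = (adapted.to_adapted(window[0]), adapted.to_adapted(window[1]))
        return aggregate_to_point(track, wa)
    # track readout
    if not native_track:
        raise DeclineTask("track readout unsupported")
    return _track_to_benchmark(out, adapted, manifest.native_bin_width, window)


def handle_request(
    request: PredictionRequest,
    model: Model,
    manifest: CapabilityManifest,
    matcher: Optional[MatcherLike] = None,
) -> PredictionResponse:
    """Fulfil a prediction request task by task, sequence by sequence.

    Every (task, sequence) pair of the request ends up in exactly one of
    ``predictions`` or (via its task) ``declines`` — per-task failures become
    declines, never silent omissions.
    """
    predictions: list[PredictionRecord] = []
    resolved_tasks: dict[str, LabelTriplet] = {}
    declines: list[Decline] = []

    if not versions_compatible(request.protocol_version, PROTOCOL_VERSION):
        return PredictionResponse(
            request_id=request.request_id,
            declines=[
                Decline(task_id=t.task_id, reason="protocol version mismatch")
                for t in request.tasks
            ],
        )

    match_cache: dict = {}
    for task in request.tasks:
        try:
            labels = resolve_task(task, manifest, matcher, match_cache)
            records = [
                PredictionRecord(
                    task_id=task.task_id,
                    sequence_id=rec.sequence_id,
                    value=predict_task_sequence(
                        model, manifest, task, rec.sequence, labels
                    ),
                )
                for rec in request.sequences
            ]
        except DeclineTask as d:
            declines.append(Decline(task_id=task.task_id, reason=d.reason))
            continue
        predictions.extend(records)
        resolved_tasks[task.task_id] = labels

    return PredictionResponse(
        request_id=request.request_id,
        predictions=predictions,
        resolved_tasks=resolved_tasks,
        declines=declines,
    )
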