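"""Protocol message types.

Every message exchanged between an evaluator client, a predictor server and
the matcher service is one of the pydantic models below.  Messages carry a
``message_type`` discriminator so a decoded payload can be dispatched without
out-of-band context.  All coordinates are 0-based, half-open, and refer to the
unmodified benchmark sequence (flanks excluded).
"""

from __future__ import annotations

import math
from typing import Literal, Optional, Union

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

PROTOCOL_VERSION = "1.0.0"

DNA_ALPHABET = frozenset("ACGTN")

Phenomenon = Literal["binding", "accessibility", "conformation", "expression"]
Readout = Literal["point", "track"]
StrandPolicy = Literal["sense", "antisense", "unstranded"]
WireFormat = Literal["json", "msgpack"]
MatchCategory = Literal["cell_type", "species", "molecule"]
MatchTier = Literal["exact", "lexical", "syntactic", "semantic", "none"]


class ProtocolError(Exception):
    """Base class for protocol-level failures."""


class MessageValidationError(ProtocolError):
    """A message violated its schema; ``field`` names the offending field."""

    def __init__(self, msg: str, field: str = "", request_id: Optional[str] = None):
        super().__init__(msg)
        self.field = field
        self.request_id = request_id


def normalize_dna(seq: str, *, field: str = "sequence", allow_empty: bool = False) -> str:
    """Upcase a DNA string and reject characters outside ACGTN."""
    s = seq.upper()
    if not s and not allow_empty:
        raise ValueError(f"{field}: empty sequence")
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{field}: invalid characters {sorted(bad)!r}")
    return s


class StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class TaskSpec(StrictModel):
    """One requested prediction task: a phenomenon in a biological context.

    ``molecule`` is a free label (a TF name, a histone mark, "mRNA", ...) and
    may be empty when the phenomenon implies it.  No assay-type field exists:
    tasks describe the biochemical phenomenon, never the assay that measured
    it.
    """

    task_id: str = Field(min_length=1)
    phenomenon: Phenomenon
    molecule: str = ""
    cell_type: str = ""
    species: str = ""
    readout: Readout = "point"
    strand_policy: StrandPolicy = "sense"
    prediction_window: Optional[tuple[int, int]] = None
    upstream_flank: str = ""
    downstream_flank: str = ""

    @field_validator("upstream_flank", "downstream_flank")
    @classmethod
    def _flank_dna(cls, v: str) -> str:
        return normalize_dna(v, field="flank", allow_empty=True)

    @field_validator("prediction_window")
    @classmethod
    def _window_ok(cls, v):
        if v is not None:
            start, end = v
            if not (0 <= start < end):
                raise ValueError(f"prediction_window: need 0 <= start < end, got {v}")
        return v


class SequenceRecord(StrictModel):
    sequence_id: str = Field(min_length=1)
    sequence: str

    @field_validator("sequence")
    @classmethod
    def _seq_dna(cls, v: str) -> str:
        return normalize_dna(v)


class PredictionRequest(StrictModel):
    """Everything an evaluator sends to a predictor in one exchange.

    ``sequences`` is an ordered list of records rather than a mapping so that
    duplicate sequence ids arriving on the wire are detectable and rejected.
    ``accepted_formats`` is the format negotiation: the request itself always
    travels as JSON-capable content, and the predictor replies in the first
    listed format it supports.
    """

    message_type: Literal["prediction_request"] = "prediction_request"
    protocol_version: str = PROTOCOL_VERSION
    request_id: str = Field(min_length=1)
    tasks: list[TaskSpec]
    sequences: list[SequenceRecord]
    accepted_formats: list[WireFormat] = Field(default_factory=lambda: ["json"])

    @model_validator(mode="after")
    def _invariants(self) -> "PredictionRequest":
        ids = [s.sequence_id for s in self.sequences]
        if len(set(ids)) != len(ids):
            raise ValueError("sequences: duplicate sequence_ids")
        if not self.sequences:
            raise ValueError("sequences: at least one sequence required")
        tids = [t.task_id for t in self.tasks]
        if len(set(tids)) != len(tids):
            raise ValueError("tasks: duplicate task_ids")
        if "json" not in self.accepted_formats:
            raise ValueError("accepted_formats: must contain 'json'")
        min_len = min(len(s.sequence) for s in self.sequences)
        for t in self.tasks:
            if t.prediction_window is not None and t.prediction_window[1] > min_len:
                raise ValueError(
                    f"tasks: prediction_window {t.prediction_window} of task "
                    f"{t.task_id!r} exceeds shortest sequence (len {min_len})"
                )
        return self

    @property
    def sequence_map(self) -> dict[str, str]:
        return {s.sequence_id: s.sequence for s in self.sequences}


class Track(StrictModel):
    """Positional prediction values: ``values[i]`` covers the half-open bin
    ``[origin + i*bin_width, origin + (i+1)*bin_width)`` in benchmark
    sequence coordinates."""

    values: list[float]
    bin_width: int = Field(ge=1)
    origin: int = Field(ge=0, default=0)

    @field_validator("values")
    @classmethod
    def _finite(cls, v):
        if not v:
            raise ValueError("values: empty track")
        if not all(math.isfinite(x) for x in v):
            raise ValueError("values: non-finite value in track")
        return v


class PredictionRecord(StrictModel):
    task_id: str
    sequence_id: str
    value: Union[float, Track]

    @field_validator("value")
    @classmethod
    def _finite(cls, v):
        if isinstance(v, float) and not math.isfinite(v):
            raise ValueError("value: non-finite prediction")
        return v


class LabelTriplet(StrictModel):
    cell_type: str = ""
    species: str = ""
    molecule: str = ""


class Decline(StrictModel):
    task_id: str
    reason: str = Field(min_length=1)


class PredictionResponse(StrictModel):
    """Predictor reply: per-(task, sequence) predictions plus explicit
    declines.  ``resolved_tasks`` records the concrete labels the model
    actually used so the evaluator can audit matcher substitutions."""

    message_type: Literal["prediction_response"] = "prediction_response"
    protocol_version: str = PROTOCOL_VERSION
    request_id: str
    predictions: list[PredictionRecord] = Field(default_factory=list)
    resolved_tasks: dict[str, LabelTriplet] = Field(default_factory=dict)
    declines: list[Decline] = Field(default_factory=list)

    @model_validator(mode="after")
    def _invariants(self) -> "PredictionResponse":
        declined = {d.task_id for d in self.declines}
        if len(declined) != len(self.declines):
            raise ValueError("declines: duplicate task_ids")
        keys = [(p.task_id, p.sequence_id) for p in self.predictions]
        if len(set(keys)) != len(keys):
            raise ValueError("predictions: duplicate (task_id, sequence_id) pairs")
        for p in self.predictions:
            if p.task_id in declined:
                raise ValueError(
                    f"predictions: task {p.task_id!r} appears in both predictions and declines"
                )
        return self

    def prediction_map(self) -> dict[tuple[str, str], Union[float, Track]]:
        return {(p.task_id, p.sequence_id): p.value for p in self.predictions}


class MatchRequest(StrictModel):
    """Ask the matcher to align a fuzzy label onto a predictor's choices."""

    message_type: Literal["match_request"] = "match_request"
    protocol_version: str = PROTOCOL_VERSION
    term: str = Field(min_length=1)
    choices: list[str] = Field(min_length=1)
    category: MatchCategory


class MatchResponse(StrictModel):
    message_type: Literal["match_response"] = "match_response"
    protocol_version: str = PROTOCOL_VERSION
    best_choice: Optional[str] = None
    tier: MatchTier = "none"
    confidence: float = Field(ge=0.0, le=1.0, default=0.0)

    @model_validator(mode="after")
    def _invariants(self) -> "MatchResponse":
        if (self.best_choice is None) != (self.tier == "none"):
            raise ValueError("best_choice: present iff tier != 'none'")
        return self


class ErrorMessage(StrictModel):
    """Protocol-level error reply (validation failure, framing trouble)."""

    message_type: Literal["error"] = "error"
    protocol_version: str = PROTOCOL_VERSION
    error: str
    field: str = ""
    request_id: Optional[str] = None


Message = Union[
    PredictionRequest,
    PredictionResponse,
    MatchRequest,
    MatchResponse,
    ErrorMessage,
]

MESSAGE_REGISTRY: dict[str, type[BaseModel]] = {
    "prediction_request": PredictionRequest,
    "prediction_response": PredictionResponse,
    "match_request": MatchRequest,
    "match_response": MatchResponse,
    "error": ErrorMessage,
}


def parse_message(payload: dict) -> Message:
    """Validate a decoded payload dict into its message model."""
    if not isinstance(payload, dict):
        raise MessageValidationError("payload is not an object", field="payload")
    mtype = payload.get("message_type")
    model = MESSAGE_REGISTRY.get(mtype)
    if model is None:
        raise MessageValidationError(
            f"unknown message_type {mtype!r}", field="message_type"
        )
    try:
        return model.model_validate(payload)
    except Exception as exc:  # pydantic ValidationError
        field = ""
        errors = getattr(exc, "errors", None)
        if callable(errors):
            errs = errors()
            if errs:
                field = ".".join(str(p) for p in errs[0].get("loc", ()))
        raise MessageValidationError(
            str(exc), field=field, request_id=payload.get("request_id")
        ) from exc


def major_version(v: str) -> int:
    try:
        return int(v.split(".", 1)[0])
    except ValueError:
        return -1


def versions_compatible(a: str, b: str) -> bool:
    """Frozen-module comparability: only the major version must agree."""
    return major_version(a) == major_version(b) and major_version(a) >= 0
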