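"""Seeded random generation of valid protocol messages.

Used by round-trip and validation-completeness checks: any generated message
must survive encode/decode in both wire formats unchanged, and targeted
single-field corruptions of its payload must be rejected by validation.
"""

from __future__ import annotations

import numpy as np

from .messages import (
    Decline,
    LabelTriplet,
    MatchRequest,
    MatchResponse,
    Message,
    PredictionRecord,
    PredictionRequest,
    PredictionResponse,
    SequenceRecord,
    TaskSpec,
    Track,
)

_PHENOMENA = ["binding", "accessibility", "conformation", "expression"]
_READOUTS = ["point", "track"]
_STRANDS = ["sense", "antisense", "unstranded"]
_LABELS = ["K562", "HepG2", "GM12878", "hek-293", "A549", "", "Homo sapiens"]
_TIERS = ["exact", "lexical", "syntactic", "semantic"]


def _dna(rng: np.random.Generator, lo: int = 1, hi: int = 60) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list("ACGTN"), size=n))


def random_task(rng: np.random.Generator, task_id: str, max_window: int) -> TaskSpec:
    window = None
    if rng.random() < 0.4 and max_window >= 2:
        start = int(rng.integers(0, max_window - 1))
        end = int(rng.integers(start + 1, max_window + 1))
        window = (start, end)
    return TaskSpec(
        task_id=task_id,
        phenomenon=str(rng.choice(_PHENOMENA)),
        molecule=str(rng.choice(["", "mRNA", "NF-kB", "H3K27ac"])),
        cell_type=str(rng.choice(_LABELS)),
        species=str(rng.choice(["", "Homo sapiens", "mouse"])),
        readout=str(rng.choice(_READOUTS)),
        strand_policy=str(rng.choice(_STRANDS)),
        prediction_window=window,
        upstream_flank=_dna(rng, 0, 8) if rng.random() < 0.3 else "",
        downstream_flank=_dna(rng, 0, 8) if rng.random() < 0.3 else "",
    )


def random_prediction_request(rng: np.random.Generator) -> PredictionRequest:
    n_seq = int(rng.integers(1, 6))
    min_len = int(rng.integers(4, 40))
    sequences = [
        SequenceRecord(
            sequence_id=f"s{i}", sequence=_dna(rng, min_len, min_len + 20)
        )
        for i in range(n_seq)
    ]
    n_tasks = int(rng.integers(0, 4))
    tasks = [random_task(rng, f"t{i}", min_len) for i in range(n_tasks)]
    formats = ["json", "msgpack"] if rng.random() < 0.5 else ["json"]
    return PredictionRequest(
        request_id=f"req{int(rng.integers(1e6))}",
        tasks=tasks,
        sequences=sequences,
        accepted_formats=formats,
    )


def random_prediction_response(rng: np.random.Generator) -> PredictionResponse:
    n = int(rng.integers(0, 6))
    predictions = []
    for i in range(n):
        if rng.random() < 0.5:
            value = float(rng.normal())
        else:
            value = Track(
                values=[float(v) for v in rng.normal(size=int(rng.integers(1, 10)))],
                bin_width=int(rng.integers(1, 5)),
                origin=int(rng.integers(0, 10)),
            )
        predictions.append(
            PredictionRecord(task_id=f"t{i % 3}", sequence_id=f"s{i}", value=value)
        )
    declines = [
        Decline(task_id=f"d{i}", reason="unsupported phenomenon")
        for i in range(int(rng.integers(0, 3)))
    ]
    return PredictionResponse(
        request_id=f"req{int(rng.integers(1e6))}",
        predictions=predictions,
        resolved_tasks={
            f"t{i}": LabelTriplet(cell_type="K562", species="Homo sapiens")
            for i in range(int(rng.integers(0, 3)))
        },
        declines=declines,
    )


def random_match_message(rng: np.random.Generator) -> Message:
    if rng.random() < 0.5:
        return MatchRequest(
            term=str(rng.choice([l for l in _LABELS if l])),
            choices=[str(c) for c in rng.choice(_LABELS[:5], size=int(rng.integers(1, 5)))],
            category=str(rng.choice(["cell_type", "species", "molecule"])),
        )
    if rng.random() < 0.3:
        return MatchResponse(best_choice=None, tier="none", confidence=0.0)
    return MatchResponse(
        best_choice=str(rng.choice([l for l in _LABELS if l])),
        tier=str(rng.choice(_TIERS)),
        confidence=float(rng.uniform(0.5, 1.0)),
    )


def random_message(rng: np.random.Generator) -> Message:
    u = rng.random()
    if u < 0.4:
        return random_prediction_request(rng)
    if u < 0.8:
        return random_prediction_response(rng)
    return random_match_message(rng)


# (payload mutator, name of the violated field) pairs applied to a valid
# prediction-request payload; every mutation must be rejected by validation.
REQUEST_CORRUPTIONS = [
    (lambda p: p.__setitem__("phenomenon_typo", 1), "extra field"),
    (lambda p: p["tasks"].append(dict(p["tasks"][0])) if p["tasks"] else None,
     "duplicate task_id"),
    (lambda p: p["sequences"].append(dict(p["sequences"][0])), "duplicate sequence_id"),
    (lambda p: p["sequences"][0].__setitem__("sequence", "ACGTX"), "alphabet"),
    (lambda p: p["sequences"][0].__setitem__("sequence", ""), "empty sequence"),
    (lambda p: p.__setitem__("accepted_formats", ["msgpack"]), "json required"),
    (lambda p: p.__setitem__("accepted_formats", []), "empty formats"),
    (lambda p: p["tasks"][0].__setitem__("phenomenon", "telepathy") if p["tasks"] else None,
     "phenomenon enum"),
    (lambda p: p["tasks"][0].__setitem__("prediction_window", [3, 3]) if p["tasks"] else None,
     "empty window"),
    (lambda p: p["tasks"][0].__setitem__("upstream_flank", "AC-GT") if p["tasks"] else None,
     "flank alphabet"),
    (lambda p: p.__setitem__("request_id", ""), "empty request_id"),
    (lambda p: p.__setitem__("sequences", []), "no sequences"),
]
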