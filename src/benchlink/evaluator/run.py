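"""Evaluation driver: request building, prediction collection, scoring.

``run_evaluation`` performs the full evaluation flow: build one request per
benchmark (one task per condition, sequences attached once), exchange it with
a predictor endpoint, verify that predictions plus declines exactly cover the
request, compute per-condition correlations and all pairwise between-
condition differentials, and assemble a standard report.  Large benchmarks
can be split into parts, each sent as its own request; metrics are computed
once on the merged prediction set, so splitting never changes the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Union

import numpy as np
import pandas as pd

from ..protocol import (
    ConnectError,
    Connection,
    EndpointError,
    ErrorMessage,
    PredictionRequest,
    PredictionResponse,
    SequenceRecord,
    Track,
)
from .benchmark import Benchmark, TaskTemplate, split_benchmark
from .metrics import METRICS, UndefinedMetric, paired_complete, differential_metric
from .report import (
    DifferentialRecord,
    EvaluationReport,
    MetricRecord,
    SkippedRecord,
)

log = logging.getLogger("benchlink.evaluator")


class PredictorClient:
    """Client for a predictor endpoint; one connection per request."""

    def __init__(self, host: str, port: int, *, format: str = "json",
                 timeout: float = 120.0):
        self.host, self.port = host, port
        self.format = format
        self.timeout = timeout

    @property
    def identity(self) -> str:
        return f"{self.host}:{self.port}"

    def predict(self, request: PredictionRequest) -> PredictionResponse:
        with Connection(self.host, self.port, timeout=self.timeout) as conn:
            reply = conn.exchange(request, self.format)
        if isinstance(reply, ErrorMessage):
            raise RuntimeError(f"predictor error: {reply.error}")
        if not isinstance(reply, PredictionResponse):
            raise RuntimeError(f"unexpected reply type {reply.message_type!r}")
        if reply.request_id != request.request_id:
            raise RuntimeError(
                f"response id {reply.request_id!r} does not echo request "
                f"{request.request_id!r}"
            )
        return reply


def build_request(
    benchmark: Benchmark,
    *,
    request_id: Optional[str] = None,
    accepted_formats: Optional[list[str]] = None,
) -> PredictionRequest:
    """One task per condition label; sequences attached once, not per task.

    Only phenomenon-level metadata travels: no assay information exists in
    the protocol, so models cannot fit assay-specific biases.
    """
    tasks = [
        benchmark.template.task_for(f"{benchmark.name}:{cond}", cond)
        for cond in benchmark.conditions
    ]
    return PredictionRequest(
        request_id=request_id or f"eval-{benchmark.name}",
        tasks=tasks,
        sequences=[
            SequenceRecord(sequence_id=sid, sequence=seq)
            for sid, seq in benchmark.sequences.items()
        ],
        accepted_formats=accepted_formats or ["json"],
    )


def check_response_partition(
    request: PredictionRequest, response: PredictionResponse
) -> None:
    """Every (task, sequence) pair appears in exactly one of predictions or
    (via its task) declines; track values cover the prediction window."""
    declined = {d.task_id for d in response.declines}
    got = set(response.prediction_map())
    expected = {
        (t.task_id, s.sequence_id)
        for t in request.tasks
        if t.task_id not in declined
        for s in request.sequences
    }
    if got != expected:
        missing = sorted(expected - got)[:3]
        extra = sorted(got - expected)[:3]
        raise RuntimeError(
            f"response does not partition request: missing {missing}, extra {extra}"
        )
    windows = {t.task_id: t.prediction_window for t in request.tasks}
    for p in response.predictions:
        if isinstance(p.value, Track) and windows.get(p.task_id) is not None:
            ws, we = windows[p.task_id]
            covered_end = p.value.origin + p.value.bin_width * len(p.value.values)
            if p.value.origin > ws or covered_end < we:
                raise RuntimeError(
                    f"track for {p.task_id}/{p.sequence_id} does not cover "
                    f"window [{ws},{we})"
                )


@dataclass
class CollectedPredictions:
    """Merged predictions across request parts."""

    values: dict[tuple[str, str], Union[float, Track]]
    resolved: dict[str, object]
    declines: dict[str, str]  # task_id -> reason


def collect_predictions(
    benchmark: Benchmark, client: PredictorClient, split: int = 1
) -> CollectedPredictions:
    parts = split_benchmark(benchmark, split) if split > 1 else [benchmark]
    values: dict[tuple[str, str], Union[float, Track]] = {}
    resolved: dict[str, object] = {}
    declines: dict[str, str] = {}
    for i, part in enumerate(parts):
        request = build_request(
            part, request_id=f"eval-{benchmark.name}-part{i + 1}of{len(parts)}"
        )
        response = client.predict(request)
        check_response_partition(request, response)
        values.update(response.prediction_map())
        resolved.update(response.resolved_tasks)
        for d in response.declines:
            declines[d.task_id] = d.reason
    return CollectedPredictions(values, resolved, declines)


def _point_table(
    benchmark: Benchmark, collected: CollectedPredictions
) -> pd.DataFrame:
    data = {}
    for cond in benchmark.conditions:
        task_id = f"{benchmark.name}:{cond}"
        if task_id in collected.declines:
            continue
        data[cond] = {
            sid: collected.values[(task_id, sid)] for sid in benchmark.sequences
        }
    return pd.DataFrame(data).reindex(list(benchmark.sequences))


def _track_values(track: Track, window: tuple[int, int]) -> Optional[np.ndarray]:
    """Per-base values of a track over a benchmark-coordinate window, or None
    when the track does not cover it."""
    ws, we = window
    covered_end = track.origin + track.bin_width * len(track.values)
    if track.origin > ws or covered_end < we:
        return None
    values = np.repeat(np.asarray(track.values, float), track.bin_width)
    off = ws - track.origin
    return values[off : off + (we - ws)]


def run_evaluation(
    benchmark: Benchmark,
    predictor: Union[PredictorClient, tuple[str, int]],
    *,
    metric: str = "pearson",
    split: int = 1,
    differential: bool = True,
) -> EvaluationReport:
    """Evaluate a predictor endpoint on a benchmark and build the report."""
    if isinstance(predictor, tuple):
        predictor = PredictorClient(*predictor)
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")

    task_ids = [f"{benchmark.name}:{c}" for c in benchmark.conditions]
    report = EvaluationReport(
        benchmark=benchmark.name, predictor=predictor.identity
    ).stamped()

    try:
        collected = collect_predictions(benchmark, predictor, split)
    except (ConnectError, EndpointError) as exc:
        log.warning("predictor unreachable: %s", exc)
        report.skipped = [
            SkippedRecord(task_id=tid, condition=cond, reason="predictor unreachable")
            for tid, cond in zip(task_ids, benchmark.conditions)
        ]
        return report

    for cond in benchmark.conditions:
        task_id = f"{benchmark.name}:{cond}"
        if task_id in collected.declines:
            report.skipped.append(
                SkippedRecord(
                    task_id=task_id, condition=cond,
                    reason=collected.declines[task_id],
                )
            )
            continue
        resolved = collected.resolved.get(task_id)
        if benchmark.template.readout == "point":
            record = _score_point_condition(
                benchmark, collected, cond, task_id, metric, resolved
            )
        else:
            record = _score_track_condition(
                benchmark, collected, cond, task_id, metric, resolved
            )
        report.records.append(record)

    if differential and benchmark.template.readout == "point":
        obs = benchmark.measurements
        pred = _point_table(benchmark, collected)
        scored = [c for c in benchmark.conditions if c in pred.columns]
        for pair in combinations(scored, 2):
            try:
                value, n = differential_metric(obs, pred, pair, metric)
                report.differentials.append(
                    DifferentialRecord(
                        conditions=pair, metric=f"differential_{metric}",
                        value=value, n=n,
                    )
                )
            except UndefinedMetric as exc:
                report.differentials.append(
                    DifferentialRecord(
                        conditions=pair, metric=f"differential_{metric}",
                        value=None, n=0, note=str(exc),
                    )
                )

    report.check_partition(task_ids)
    return report


def _score_point_condition(
    benchmark, collected, cond, task_id, metric, resolved
) -> MetricRecord:
    obs = benchmark.measurements
    pred = _point_table(benchmark, collected)
    try:
        o, p = paired_complete(obs, pred, [cond])
        value = METRICS[metric](o[cond], p[cond])
        return MetricRecord(
            task_id=task_id, condition=cond, metric=metric,
            value=value, n=len(o), resolved=resolved,
        )
    except UndefinedMetric as exc:
        return MetricRecord(
            task_id=task_id, condition=cond, metric=metric,
            value=None, n=0, resolved=resolved, note=str(exc),
        )


def _score_track_condition(
    benchmark, collected, cond, task_id, metric, resolved
) -> MetricRecord:
    """Mean of per-sequence correlations between measured and predicted
    signal (pooling would conflate between- and within-sequence structure)."""
    per_seq = benchmark.measurements.get(cond, {})
    rs = []
    for sid, signal in per_seq.items():
        track = collected.values.get((task_id, sid))
        if not isinstance(track, Track):
            continue
        window = benchmark.template.prediction_window or (0, len(signal))
        predicted = _track_values(track, window)
        if predicted is None:
            continue
        observed = np.asarray(signal, float)[window[0] : window[1]]
        try:
            rs.append(METRICS[metric](observed, predicted))
        except UndefinedMetric:
            continue
    if not rs:
        return MetricRecord(
            task_id=task_id, condition=cond, metric=f"mean_per_sequence_{metric}",
            value=None, n=0, resolved=resolved, note="no scorable sequences",
        )
    return MetricRecord(
        task_id=task_id, condition=cond, metric=f"mean_per_sequence_{metric}",
        value=float(np.mean(rs)), n=len(rs), resolved=resolved,
    )


@dataclass
class ConsistencyResult:
    """Forward vs reverse-complement prediction agreement."""

    readout: str
    value: Optional[float]
    n: int
    reason: str = ""


def consistency_evaluate(
    predictor: Union[PredictorClient, tuple[str, int]],
    sequences: dict[str, str],
    template: TaskTemplate,
    *,
    condition: str = "",
    metric: str = "pearson",
) -> ConsistencyResult:
    """Correlate predictions for each sequence with its reverse complement.

    Both orientations are requested as sense-strand tasks, so the result
    measures the model's intrinsic strand symmetry.  Point readout: one
    correlation over the paired per-sequence values.  Track readout: each
    reverse-complement track is reversed back onto forward coordinates, then
    the mean of per-sequence correlations is reported.  Identical forward and
    reverse predictions short-circuit to a correlation of exactly 1.  The
    task template's prediction window is ignored (whole sequences are
    compared): a fixed window would address different bases in the two
    orientations.
    """
    from ..predictor.adapt import reverse_complement

    if isinstance(predictor, tuple):
        predictor = PredictorClient(*predictor)
    if len(sequences) < 3:
        raise ValueError("need >= 3 sequences for a consistency evaluation")

    task = TaskTemplate(
        phenomenon=template.phenomenon,
        molecule=template.molecule,
        species=template.species,
        readout=template.readout,
        strand_policy="sense",
        upstream_flank=template.upstream_flank,
        downstream_flank=template.downstream_flank,
    ).task_for("consistency", condition)
    records = []
    for sid, seq in sequences.items():
        records.append(SequenceRecord(sequence_id=sid, sequence=seq))
        records.append(
            SequenceRecord(sequence_id=f"{sid}__rc", sequence=reverse_complement(seq))
        )
    request = PredictionRequest(
        request_id="consistency-eval", tasks=[task], sequences=records
    )
    response = predictor.predict(request)
    check_response_partition(request, response)
    if response.declines:
        return ConsistencyResult(
            readout=template.readout, value=None, n=0,
            reason=response.declines[0].reason,
        )
    values = response.prediction_map()

    if template.readout == "point":
        fwd = np.array([values[("consistency", sid)] for sid in sequences])
        rev = np.array([values[("consistency", f"{sid}__rc")] for sid in sequences])
        if np.array_equal(fwd, rev):
            return ConsistencyResult("point", 1.0, len(fwd))
        return ConsistencyResult("point", METRICS[metric](fwd, rev), len(fwd))

    rs = []
    for sid in sequences:
        f = np.asarray(values[("consistency", sid)].values, float)
        r = np.asarray(values[("consistency", f"{sid}__rc")].values, float)[::-1]
        if np.array_equal(f, r):
            rs.append(1.0)
            continue
        try:
            rs.append(METRICS[metric](f, r))
        except UndefinedMetric:
            continue
    if not rs:
        return ConsistencyResult("track", None, 0, reason="no scorable sequences")
    return ConsistencyResult("track", float(np.mean(rs)), len(rs))
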