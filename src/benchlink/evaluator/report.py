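"""Standard evaluation report: JSON with a fixed schema plus a flat TSV twin.

Every requested task appears exactly once, either as a metric record or as a
skipped record carrying the predictor's decline reason — the report never
silently drops a task.  Differential (between-condition) metrics are extra
records keyed by the condition pair.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import Field, model_validator

from .. import __version__ as package_version
from ..protocol.messages import PROTOCOL_VERSION, LabelTriplet, StrictModel

REPORT_SCHEMA_VERSION = "1.0"


class MetricRecord(StrictModel):
    task_id: str
    condition: str = ""
    metric: str
    value: Optional[float] = None
    n: int = 0
    resolved: Optional[LabelTriplet] = None
    note: str = ""

    @model_validator(mode="after")
    def _correlation_needs_n(self) -> "MetricRecord":
        if self.value is not None and self.metric in ("pearson", "spearman") and self.n <= 2:
            raise ValueError(f"correlation metric with N={self.n} <= 2")
        return self


class DifferentialRecord(StrictModel):
    conditions: tuple[str, str]
    metric: str
    value: Optional[float] = None
    n: int = 0
    note: str = ""


class SkippedRecord(StrictModel):
    task_id: str
    condition: str = ""
    reason: str


class EvaluationReport(StrictModel):
    benchmark: str
    predictor: str
    records: list[MetricRecord] = Field(default_factory=list)
    differentials: list[DifferentialRecord] = Field(default_factory=list)
    skipped: list[SkippedRecord] = Field(default_factory=list)
    protocol_version: str = PROTOCOL_VERSION
    report_schema_version: str = REPORT_SCHEMA_VERSION
    package_version: str = package_version
    timestamp: str = ""

    def stamped(self) -> "EvaluationReport":
        return self.model_copy(
            update={
                "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat()
            }
        )

    def check_partition(self, task_ids: list[str]) -> None:
        """Every requested task appears exactly once as metric-or-skipped."""
        seen = [r.task_id for r in self.records] + [s.task_id for s in self.skipped]
        if sorted(seen) != sorted(task_ids):
            raise ValueError(
                f"report does not partition tasks: requested {sorted(task_ids)}, "
                f"reported {sorted(seen)}"
            )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.model_dump(mode="json"), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "EvaluationReport":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))

    def to_tsv(self, path) -> None:
        rows = []
        for r in self.records:
            rows.append(
                ("metric", r.task_id, r.condition, r.metric, r.value, r.n, r.note)
            )
        for d in self.differentials:
            rows.append(
                ("differential", "|".join(d.conditions), "", d.metric, d.value, d.n, d.note)
            )
        for s in self.skipped:
            rows.append(("skipped", s.task_id, s.condition, "", None, 0, s.reason))
        pd.DataFrame(
            rows,
            columns=["record", "task", "condition", "metric", "value", "n", "note"],
        ).to_csv(Path(path), sep="\t", index=False)
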