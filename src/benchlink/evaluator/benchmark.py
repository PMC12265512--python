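"""Benchmark container and on-disk layout.

A benchmark directory holds three plain-text files:

* ``sequences.fasta``   — the assayed sequences
* ``measurements.tsv``  — long table; point benchmarks: (sequence_id,
  condition, activity); track benchmarks: (sequence_id, condition, position,
  value)
* ``metadata.json``     — name, readout, phenomenon, molecule, species,
  strand policy, flanks, prediction window, condition labels

This is the layout MPRA-style point benchmarks (scalar activity per sequence
per cell type) and accessibility-style track benchmarks (per-position signal)
share.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ..protocol.messages import TaskSpec, normalize_dna

METADATA_FILE = "metadata.json"
FASTA_FILE = "sequences.fasta"
TSV_FILE = "measurements.tsv"


class BenchmarkError(ValueError):
    pass


@dataclass(frozen=True)
class TaskTemplate:
    """The task metadata shared by every condition of a benchmark."""

    phenomenon: str = "expression"
    molecule: str = "mRNA"
    species: str = "Homo sapiens"
    readout: str = "point"
    strand_policy: str = "sense"
    prediction_window: Optional[tuple[int, int]] = None
    upstream_flank: str = ""
    downstream_flank: str = ""

    def task_for(self, task_id: str, cell_type: str) -> TaskSpec:
        return TaskSpec(
            task_id=task_id,
            phenomenon=self.phenomenon,
            molecule=self.molecule,
            cell_type=cell_type,
            species=self.species,
            readout=self.readout,
            strand_policy=self.strand_policy,
            prediction_window=self.prediction_window,
            upstream_flank=self.upstream_flank,
            downstream_flank=self.downstream_flank,
        )


@dataclass
class Benchmark:
    """Sequences plus measured activities plus the task template.

    ``measurements``: point benchmarks use a DataFrame indexed by sequence_id
    with one column per condition; track benchmarks use a nested dict
    ``condition -> sequence_id -> signal array``.
    """

    name: str
    sequences: dict[str, str]
    measurements: object
    template: TaskTemplate = field(default_factory=TaskTemplate)
    conditions: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.sequences:
            raise BenchmarkError("benchmark has no sequences")
        if not self.conditions:
            raise BenchmarkError("benchmark has no conditions")
        for sid, seq in self.sequences.items():
            self.sequences[sid] = normalize_dna(seq, field=f"sequence {sid!r}")
        if self.template.readout == "point":
            df = self.measurements
            if not isinstance(df, pd.DataFrame):
                raise BenchmarkError("point benchmark needs a DataFrame of activities")
            unknown = set(df.index) - set(self.sequences)
            if unknown:
                raise BenchmarkError(f"measured ids missing from sequences: {sorted(unknown)[:3]}")
            missing_cond = set(self.conditions) - set(df.columns)
            if missing_cond:
                raise BenchmarkError(f"conditions without measurements: {sorted(missing_cond)}")
            finite = df[self.conditions].apply(
                lambda c: c.map(lambda v: pd.isna(v) or math.isfinite(v))
            )
            if not finite.all().all():
                raise BenchmarkError("non-finite activity values")
        else:
            for cond, per_seq in self.measurements.items():
                unknown = set(per_seq) - set(self.sequences)
                if unknown:
                    raise BenchmarkError(
                        f"measured ids missing from sequences: {sorted(unknown)[:3]}"
                    )
                for sid, sig in per_seq.items():
                    if not np.all(np.isfinite(sig)):
                        raise BenchmarkError(f"non-finite signal for {sid!r}")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        records = [
            SeqRecord(Seq(seq), id=sid, description="")
            for sid, seq in self.sequences.items()
        ]
        SeqIO.write(records, directory / FASTA_FILE, "fasta")
        if self.template.readout == "point":
            long = (
                self.measurements[self.conditions]
                .reset_index(names="sequence_id")
                .melt(id_vars="sequence_id", var_name="condition", value_name="activity")
                .dropna(subset=["activity"])
            )
            long.to_csv(directory / TSV_FILE, sep="\t", index=False)
        else:
            rows = []
            for cond, per_seq in self.measurements.items():
                for sid, sig in per_seq.items():
                    for pos, v in enumerate(np.asarray(sig, float)):
                        rows.append((sid, cond, pos, v))
            pd.DataFrame(
                rows, columns=["sequence_id", "condition", "position", "value"]
            ).to_csv(directory / TSV_FILE, sep="\t", index=False)
        meta = {
            "name": self.name,
            "conditions": self.conditions,
            "phenomenon": self.template.phenomenon,
            "molecule": self.template.molecule,
            "species": self.template.species,
            "readout": self.template.readout,
            "strand_policy": self.template.strand_policy,
            "prediction_window": list(self.template.prediction_window)
            if self.template.prediction_window
            else None,
            "upstream_flank": self.template.upstream_flank,
            "downstream_flank": self.template.downstream_flank,
        }
        with open(directory / METADATA_FILE, "w") as fh:
            json.dump(meta, fh, indent=2)
            fh.write("\n")

    @classmethod
    def load(cls, directory) -> "Benchmark":
        directory = Path(directory)
        with open(directory / METADATA_FILE) as fh:
            meta = json.load(fh)
        sequences = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(directory / FASTA_FILE, "fasta")
        }
        template = TaskTemplate(
            phenomenon=meta["phenomenon"],
            molecule=meta["molecule"],
            species=meta["species"],
            readout=meta["readout"],
            strand_policy=meta["strand_policy"],
            prediction_window=tuple(meta["prediction_window"])
            if meta.get("prediction_window")
            else None,
            upstream_flank=meta.get("upstream_flank", ""),
            downstream_flank=meta.get("downstream_flank", ""),
        )
        table = pd.read_csv(directory / TSV_FILE, sep="\t")
        if meta["readout"] == "point":
            measurements = table.pivot(
                index="sequence_id", columns="condition", values="activity"
            )
            # preserve FASTA order of sequences
            measurements = measurements.reindex(
                [s for s in sequences if s in measurements.index]
            )
        else:
            measurements = {}
            for cond, sub in table.groupby("condition", sort=False):
                per_seq = {}
                for sid, rows in sub.groupby("sequence_id", sort=False):
                    per_seq[sid] = rows.sort_values("position")["value"].to_numpy()
                measurements[cond] = per_seq
        return cls(
            name=meta["name"],
            sequences=sequences,
            measurements=measurements,
            template=template,
            conditions=list(meta["conditions"]),
        )


def split_benchmark(benchmark: Benchmark, k: int) -> list[Benchmark]:
    """Deterministic contiguous split into k parts whose union reconstructs
    the benchmark; enables parallel evaluation of large sequence sets."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ids = list(benchmark.sequences)
    if k > len(ids):
        raise ValueError(f"cannot split {len(ids)} sequences into {k} parts")
    parts = []
    for idx in np.array_split(np.arange(len(ids)), k):
        part_ids = [ids[i] for i in idx]
        if benchmark.template.readout == "point":
            meas = benchmark.measurements.loc[
                [i for i in part_ids if i in benchmark.measurements.index]
            ]
        else:
            meas = {
                cond: {sid: sig for sid, sig in per.items() if sid in set(part_ids)}
                for cond, per in benchmark.measurements.items()
            }
        parts.append(
            Benchmark(
                name=benchmark.name,
                sequences={i: benchmark.sequences[i] for i in part_ids},
                measurements=meas,
                template=benchmark.template,
                conditions=list(benchmark.conditions),
            )
        )
    return parts
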