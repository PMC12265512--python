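"""Synthetic benchmarks with known statistical structure.

An MPRA-style point benchmark (scalar activity per sequence per cell type)
is emulated as: i.i.d. uniform random sequences, a ground-truth k-mer weight
model with an independent weight vector per condition, and additive Gaussian
measurement noise.  Because the ground truth is returned alongside the data,
an oracle predictor can be built (noiseless evaluation must give r = 1), and
the expected correlation under noise has the closed form

    E[r] = sigma / sqrt(sigma^2 + tau^2)

for signal standard deviation sigma and noise standard deviation tau — the
calibration target used by the attenuation tests.

A track-style accessibility benchmark uses the same model in track mode
(per-position k-mer weight, bin width 1).  Matcher fixtures plant one true
synonym of a term among distractors verified to match at no tier.

Everything is deterministic given the seed.  These generators emulate the
statistical shape of regulatory benchmarks, not their biology: there is no
regulatory grammar, no positional structure, and by default no GC skew.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .evaluator.benchmark import Benchmark, TaskTemplate
from .matcher.core import SynonymTable, match_one, normalize_label
from .models import KmerWeightModel, kmer_score, kmer_track, random_kmer_weights
import pandas as pd

DEFAULT_CONDITIONS = ["K562", "HepG2", "GM12878"]


def random_sequences(
    n: int, length: int, rng: np.random.Generator, gc: float = 0.5
) -> dict[str, str]:
    """n i.i.d. random sequences; ``gc`` sets the G+C fraction (default no
    skew, the simplest null)."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    return {
        f"seq{i:05d}": "".join(rng.choice(bases, size=length, p=p))
        for i in range(n)
    }


def noise_sd_for_target_r(signal_sd: float, target_r: float) -> float:
    """The tau for which E[r] = target under additive independent noise."""
    if not 0 < target_r <= 1:
        raise ValueError("target_r must be in (0, 1]")
    return signal_sd * np.sqrt(1.0 / target_r**2 - 1.0)


def generate_point_benchmark(
    n: int = 2000,
    length: int = 200,
    conditions: Optional[list[str]] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    k: int = 3,
    gc: float = 0.5,
    name: str = "synthetic-mpra",
    out_dir=None,
) -> tuple[Benchmark, KmerWeightModel]:
    """MPRA-style benchmark plus its ground-truth model.

    activity(seq, condition) = kmer_score(seq; weights[condition]) + N(0, tau).
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if length < k:
        raise ValueError(f"length must be >= k ({k})")
    conditions = list(conditions) if conditions else list(DEFAULT_CONDITIONS)
    rng = np.random.default_rng(seed)
    sequences = random_sequences(n, length, rng, gc)
    weights = random_kmer_weights(k, conditions, rng)
    model = KmerWeightModel(weights, k=k, mode="point")
    data = {
        cond: [
            kmer_score(seq, weights[cond], k) + (rng.normal(0, noise_sd) if noise_sd else 0.0)
            for seq in sequences.values()
        ]
        for cond in conditions
    }
    measurements = pd.DataFrame(data, index=list(sequences))
    measurements.index.name = "sequence_id"
    benchmark = Benchmark(
        name=name,
        sequences=sequences,
        measurements=measurements,
        template=TaskTemplate(phenomenon="expression", readout="point"),
        conditions=conditions,
    )
    if out_dir is not None:
        benchmark.save(out_dir)
        model.to_json(Path(out_dir) / "ground_truth_model.json")
    return benchmark, model


def generate_track_benchmark(
    n: int = 100,
    length: int = 200,
    seed: int = 0,
    k: int = 3,
    condition: str = "K562",
    noise_sd: float = 0.0,
    name: str = "synthetic-accessibility",
    out_dir=None,
) -> tuple[Benchmark, KmerWeightModel]:
    """Accessibility-style track benchmark: per-position signal from the
    track-mode k-mer model (bin width 1), plus optional Gaussian noise."""
    if n < 3:
        raise ValueError("n must be >= 3")
    if length < k:
        raise ValueError(f"length must be >= k ({k})")
    rng = np.random.default_rng(seed)
    sequences = random_sequences(n, length, rng)
    weights = random_kmer_weights(k, [condition], rng)
    model = KmerWeightModel(weights, k=k, mode="track")
    per_seq = {}
    for sid, seq in sequences.items():
        signal = kmer_track(seq, weights[condition], k)
        if noise_sd:
            signal = signal + rng.normal(0, noise_sd, size=len(signal))
        per_seq[sid] = signal
    benchmark = Benchmark(
        name=name,
        sequences=sequences,
        measurements={condition: per_seq},
        template=TaskTemplate(
            phenomenon="accessibility", molecule="", readout="track"
        ),
        conditions=[condition],
    )
    if out_dir is not None:
        benchmark.save(out_dir)
        model.to_json(Path(out_dir) / "ground_truth_model.json")
    return benchmark, model


@dataclass(frozen=True)
class MatcherFixture:
    term: str
    choices: list[str]
    planted_choice: str
    planted_index: int
    category: str = "cell_type"


# syntactic variants used to plant a true positive for common terms
_PLANT_VARIANTS = {
    "K562": ["K-562", "k562", "chronic myelogenous leukemia cell line"],
    "HEK293": ["hek-293", "HEK 293", "human embryonic kidney 293"],
    "SK-N-SH": ["SKNSH", "sk-n-sh"],
    "A549": ["a-549", "lung adenocarcinoma cell line"],
}


def generate_matcher_fixture(
    n_choices: int = 100,
    planted_term: str = "K562",
    seed: int = 0,
    table: Optional[SynonymTable] = None,
) -> MatcherFixture:
    """One planted synonym/variant of ``planted_term`` at a seeded random
    position among distractors guaranteed to match at no tier."""
    rng = np.random.default_rng(seed)
    tbl = table if table is not None else SynonymTable.default()
    variants = _PLANT_VARIANTS.get(planted_term)
    if variants:
        planted = variants[int(rng.integers(len(variants)))]
    else:
        # generic syntactic variant: lowercase with hyphens between characters
        planted = "-".join(planted_term.lower())
    norm_term = normalize_label(planted_term)
    alphabet = list("BDEFHIJLMOPQRUVWXYZ")
    distractors: list[str] = []
    while len(distractors) < n_choices - 1:
        label = "".join(rng.choice(alphabet, size=4)) + str(rng.integers(100, 999))
        if normalize_label(label) == norm_term:
            continue
        if match_one(planted_term, [label], tbl).tier != "none":
            continue
        distractors.append(label)
    pos = int(rng.integers(n_choices))
    choices = distractors[:pos] + [planted] + distractors[pos:]
    return MatcherFixture(
        term=planted_term, choices=choices, planted_choice=planted, planted_index=pos
    )
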