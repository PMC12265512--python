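"""Deterministic toy sequence-to-activity models.

These stand in for trained models in tests and demos: their behaviour has a
closed form, so every pipeline stage can be verified exactly.  All models
follow the predictor plug-in contract ``model(sequence, labels) -> scalar or
per-position array``.

* :class:`KmerWeightModel` — activity is the sum of learned-looking (but
  fixed) weights of all overlapping k-mers, with per-condition weight
  vectors.  Its track mode emits the per-position k-mer weight (bin width 1),
  so point score == sum(track) and bin aggregation paths are exercised
  nontrivially.
* :func:`gc_model` — GC fraction; invariant under reverse complement, so it
  doubles as a strand-consistency reference.
* :func:`symmetrize` — wraps any model g as f(s) = (g(s) + g(rc(s)))/2,
  making f exactly strand-symmetric.
"""

from __future__ import annotations

import itertools
import json
import logging
from typing import Optional

import numpy as np

from .predictor.adapt import reverse_complement
from .predictor.manifest import CapabilityManifest
from .protocol.messages import LabelTriplet

log = logging.getLogger("benchlink.models")

BASES = "ACGT"


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(BASES, repeat=k)]


def kmer_score(seq: str, weights: dict[str, float], k: int) -> float:
    """Sum of weights of all overlapping k-mers; k-mers containing N score 0."""
    if len(seq) < k:
        log.warning("sequence shorter than k=%d; score is 0", k)
        return 0.0
    return float(
        sum(
            weights.get(seq[i : i + k], 0.0)
            for i in range(len(seq) - k + 1)
            if "N" not in seq[i : i + k]
        )
    )


def kmer_track(seq: str, weights: dict[str, float], k: int) -> np.ndarray:
    """Per-position k-mer weights: t[i] = weight of the k-mer starting at i
    (0 past the last full k-mer), so sum(t) == kmer_score."""
    t = np.zeros(len(seq))
    for i in range(max(0, len(seq) - k + 1)):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            t[i] = weights.get(kmer, 0.0)
    return t


def random_kmer_weights(
    k: int, conditions: list[str], rng: np.random.Generator
) -> dict[str, dict[str, float]]:
    """Per-condition standard-normal weight vectors over all 4^k k-mers."""
    kmers = all_kmers(k)
    return {
        cond: dict(zip(kmers, rng.standard_normal(len(kmers)).tolist()))
        for cond in conditions
    }


class KmerWeightModel:
    """Per-condition k-mer weight model; the condition is the cell type."""

    def __init__(
        self,
        weights: dict[str, dict[str, float]],
        k: int = 3,
        mode: str = "point",
    ):
        if mode not in ("point", "track"):
            raise ValueError(f"mode must be 'point' or 'track', got {mode!r}")
        self.weights = weights
        self.k = k
        self.mode = mode

    def __call__(self, seq: str, labels: LabelTriplet):
        w = self.weights.get(labels.cell_type)
        if w is None:
            raise KeyError(f"no weights for condition {labels.cell_type!r}")
        if self.mode == "point":
            return kmer_score(seq, w, self.k)
        return kmer_track(seq, w, self.k)

    @property
    def conditions(self) -> list[str]:
        return list(self.weights)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"k": self.k, "mode": self.mode, "weights": self.weights}, fh)

    @classmethod
    def from_json(cls, path) -> "KmerWeightModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["weights"], k=d["k"], mode=d.get("mode", "point"))


def gc_model(seq: str, labels: Optional[LabelTriplet] = None) -> float:
    """GC fraction among non-N bases (0.0 for all-N input)."""
    informative = [b for b in seq if b != "N"]
    if not informative:
        return 0.0
    return sum(b in "GC" for b in informative) / len(informative)


class symmetrize:
    """f(s) = (g(s) + g(reverse_complement(s))) / 2, exactly strand-symmetric.

    For track models the reverse-complement track is reversed before
    averaging, keeping coordinates on the input orientation.
    """

    def __init__(self, model):
        self.model = model

    def __call__(self, seq: str, labels: Optional[LabelTriplet] = None):
        fwd = self.model(seq, labels)
        rev = self.model(reverse_complement(seq), labels)
        if np.ndim(fwd) >= 1:
            return (np.asarray(fwd, float) + np.asarray(rev, float)[::-1]) / 2.0
        return (float(fwd) + float(rev)) / 2.0


def manifest_for_conditions(
    conditions: list[str],
    *,
    name: str = "toy-predictor",
    phenomenon: str = "expression",
    species: str = "Homo sapiens",
    molecule: str = "mRNA",
    native_output: str = "point",
    native_bin_width: int = 1,
    input_length: Optional[int] = None,
) -> CapabilityManifest:
    """A capability manifest listing one label triplet per condition."""
    return CapabilityManifest(
        name=name,
        phenomena={
            phenomenon: [
                LabelTriplet(cell_type=c, species=species, molecule=molecule)
                for c in conditions
            ]
        },
        native_output=native_output,
        native_bin_width=native_bin_width,
        input_length=input_length,
    )
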