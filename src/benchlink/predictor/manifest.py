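"""Capability manifests: what a model can predict and what it needs as input."""

from __future__ import annotations

import json
from typing import Literal, Optional

from pydantic import Field, model_validator

from ..protocol.messages import LabelTriplet, Phenomenon, Readout, StrictModel


class CapabilityManifest(StrictModel):
    """Machine-readable declaration of a predictor's scope.

    ``phenomena`` maps each supported phenomenon to the (cell_type, species,
    molecule) label triplets the model was trained to predict.  The matcher
    aligns requested labels onto these.  ``input_length`` is the fixed model
    input size in bases (None = any length); sequences are padded/cropped to
    it before scoring.
    """

    name: str = "predictor"
    phenomena: dict[Phenomenon, list[LabelTriplet]]
    input_length: Optional[int] = Field(default=None, ge=1)
    native_output: Readout = "point"
    native_bin_width: int = Field(default=1, ge=1)
    strand_handling: Literal["single_strand", "averages_strands"] = "single_strand"

    @model_validator(mode="after")
    def _invariants(self) -> "CapabilityManifest":
        if not self.phenomena:
            raise ValueError("phenomena: at least one supported phenomenon required")
        for ph, triplets in self.phenomena.items():
            if not triplets:
                raise ValueError(f"phenomena: empty label list for {ph!r}")
        return self

    def label_choices(self, phenomenon: Phenomenon, field: str) -> list[str]:
        """Distinct non-empty values of one label field, in manifest order."""
        seen: list[str] = []
        for t in self.phenomena[phenomenon]:
            v = getattr(t, field)
            if v and v not in seen:
                seen.append(v)
        return seen

    @classmethod
    def from_json(cls, path) -> "CapabilityManifest":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.model_dump(mode="json"), fh, indent=2)
            fh.write("\n")
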