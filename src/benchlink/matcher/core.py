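"""Deterministic label matching.

Benchmark metadata and model capability lists rarely agree verbatim on cell
type, species or molecule names ("hek-293" vs "HEK293", "chronic myelogenous
leukemia cell line" vs "K562").  The matcher aligns a requested term onto the
closest member of a candidate list by applying four tiers in strict order:

1. exact      — string equality
2. lexical    — the term occurs as a whole token inside a choice, or a choice
                occurs as a whole token of the term
3. syntactic  — equality after normalization (case folding, punctuation
                stripping), covering dashes, spacing and capitalization
                variants of the same label
4. semantic   — the term and a choice belong to the same synonym group of a
                curated table, covering distinct names for the same entity

The first tier with at least one hit wins; ties within a tier break by the
earliest position in the choice list.  Confidence is a fixed per-tier value,
not a calibrated score.

Long candidate lists are handled by tournament elimination: the list is
chunked, a champion is selected per chunk, and a championship round matches
among the champions, recursing while the champion list itself is too long.
With the deterministic backend this is exactly equivalent to matching over
the full list in one round; the chunked path exists so that a backend with a
bounded context window (e.g. an external language-model service) can be
substituted without changing the result contract.
"""

from __future__ import annotations

import json
import re
from importlib import resources
from typing import Callable, Optional, Sequence

from ..protocol import MatchResponse

TIER_CONFIDENCE = {
    "exact": 1.0,
    "lexical": 0.9,
    "syntactic": 0.8,
    "semantic": 0.7,
    "none": 0.0,
}

_NON_ALNUM = re.compile(r"[^A-Z0-9]+")
_TOKEN_SPLIT = re.compile(r"[^A-Za-z0-9]+")


def normalize_label(s: str) -> str:
    """Case-fold to upper and strip everything outside ``[A-Z0-9]``.

    Idempotent; the workhorse of the syntactic tier ("hek-293" -> "HEK293").
    """
    return _NON_ALNUM.sub("", s.upper())


def tokenize(s: str) -> list[str]:
    """Split a label on non-alphanumeric runs; drops empty tokens."""
    return [t for t in _TOKEN_SPLIT.split(s) if t]


class SynonymTable:
    """Per-category synonym groups with one designated canonical form.

    The bundled default table is a deterministic stand-in for a knowledge-
    backed semantic tier: it covers common cell line, molecule and species
    aliases and is the reproducible default backend.  Membership lookup is
    case-insensitive.
    """

    def __init__(self, groups: dict[str, list[dict]]):
        self._canonical: dict[str, dict[str, str]] = {}
        self._group_of: dict[str, dict[str, int]] = {}
        for category, cat_groups in groups.items():
            lookup: dict[str, int] = {}
            canon: dict[str, str] = {}
            for gi, group in enumerate(cat_groups):
                members = group["synonyms"]
                if group["canonical"] not in members:
                    raise ValueError(
                        f"synonym table: canonical {group['canonical']!r} "
                        f"not a member of its group"
                    )
                for m in members:
                    key = m.casefold()
                    if key in lookup:
                        raise ValueError(
                            f"synonym table: {m!r} appears in two groups of "
                            f"category {category!r}"
                        )
                    lookup[key] = gi
                    canon[key] = group["canonical"]
            self._group_of[category] = lookup
            self._canonical[category] = canon

    @classmethod
    def from_json(cls, path) -> "SynonymTable":
        with open(path) as fh:
            return cls(json.load(fh))

    @classmethod
    def default(cls) -> "SynonymTable":
        ref = resources.files("benchlink.matcher.data") / "synonyms.json"
        return cls(json.loads(ref.read_text()))

    def same_group(self, category: str, a: str, b: str) -> bool:
        lookup = self._group_of.get(category, {})
        ga = lookup.get(a.casefold())
        return ga is not None and ga == lookup.get(b.casefold())

    def canonical(self, category: str, s: str) -> Optional[str]:
        return self._canonical.get(category, {}).get(s.casefold())


def _exact(term: str, choice: str) -> bool:
    return term == choice


def _lexical(term: str, choice: str) -> bool:
    return term in tokenize(choice) or choice in tokenize(term)


def _syntactic(term: str, choice: str) -> bool:
    nt, nc = normalize_label(term), normalize_label(choice)
    if not nt or not nc:
        return False
    if nt == nc:
        return True
    choice_tokens = {normalize_label(t) for t in tokenize(choice)}
    term_tokens = {normalize_label(t) for t in tokenize(term)}
    return nt in choice_tokens or nc in term_tokens


def match_one(
    term: str,
    choices: Sequence[str],
    table: Optional[SynonymTable] = None,
    category: str = "cell_type",
) -> MatchResponse:
    """Match ``term`` against ``choices`` through the four tiers in order."""
    if not choices:
        raise ValueError("choices must be non-empty")
    if table is None:
        table = SynonymTable.default()
    tiers: list[tuple[str, Callable[[str, str], bool]]] = [
        ("exact", _exact),
        ("lexical", _lexical),
        ("syntactic", _syntactic),
        ("semantic", lambda t, c: table.same_group(category, t, c)),
    ]
    for tier, pred in tiers:
        for choice in choices:  # earliest position wins within a tier
            if pred(term, choice):
                return MatchResponse(
                    best_choice=choice, tier=tier, confidence=TIER_CONFIDENCE[tier]
                )
    return MatchResponse(best_choice=None, tier="none", confidence=0.0)


MatchBackend = Callable[[str, Sequence[str]], MatchResponse]


def deterministic_backend(
    table: Optional[SynonymTable] = None, category: str = "cell_type"
) -> MatchBackend:
    """The default, fully reproducible backend: tiers + synonym table."""
    tbl = table if table is not None else SynonymTable.default()

    def backend(term: str, choices: Sequence[str]) -> MatchResponse:
        return match_one(term, choices, tbl, category)

    return backend


class LocalMatcher:
    """In-process matcher with the same ``match`` interface as the TCP
    client, for predictors that bundle their own synonym table."""

    def __init__(self, table: Optional[SynonymTable] = None, chunk_size: int = 20):
        self.table = table if table is not None else SynonymTable.default()
        self.chunk_size = chunk_size

    def match(self, term: str, choices: Sequence[str], category: str) -> MatchResponse:
        return tournament_match(
            term, choices, self.chunk_size, deterministic_backend(self.table, category)
        )


def tournament_match(
    term: str,
    choices: Sequence[str],
    chunk_size: int = 20,
    backend: Optional[MatchBackend] = None,
) -> MatchResponse:
    """Tournament elimination over chunks of at most ``chunk_size`` choices.

    Each chunk yields at most one champion (chunks where the backend finds no
    match yield none); champions meet in a championship round, recursively if
    they still exceed ``chunk_size``.
    """
    if chunk_size < 2:
        raise ValueError("chunk_size must be >= 2")
    if backend is None:
        backend = deterministic_backend()
    choices = list(choices)
    if not choices:
        raise ValueError("choices must be non-empty")
    if len(choices) <= chunk_size:
        return backend(term, choices)
    champions: list[str] = []
    for i in range(0, len(choices), chunk_size):
        result = backend(term, choices[i : i + chunk_size])
        if result.tier != "none":
            champions.append(result.best_choice)
    if not champions:
        return MatchResponse(best_choice=None, tier="none", confidence=0.0)
    return tournament_match(term, champions, chunk_size, backend)
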