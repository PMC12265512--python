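"""Align fuzzy cell type / molecule labels onto a model's capability list.

Walks the four matching tiers on canonical examples, then shows tournament
elimination finding a single planted synonym in a 100-candidate list.
"""

from benchlink.matcher import SynonymTable, match_one, tournament_match
from benchlink.synthetic import generate_matcher_fixture

table = SynonymTable.default()

cases = [
    ("K562", ["K562", "HepG2"], "cell_type"),
    ("A549", ["HepG2", "lung adenocarcinoma cell line: A549"], "cell_type"),
    ("hek-293", ["K562", "HEK293"], "cell_type"),
    ("chronic myelogenous leukemia cell line", ["K562", "GM12878"], "cell_type"),
    ("NF-kB", ["NFKB1", "TP53"], "molecule"),
]
for term, choices, category in cases:
    r = match_one(term, choices, table, category)
    print(f"{term!r:45} -> {r.best_choice!r:40} tier={r.tier} "
          f"confidence={r.confidence}")

fx = generate_matcher_fixture(n_choices=100, planted_term="K562", seed=7)
result = tournament_match(fx.term, fx.choices, chunk_size=10)
print(f"\nplanted {fx.planted_choice!r} at position {fx.planted_index} "
      f"among 100 candidates")
print(f"tournament (chunks of 10) found: {result.best_choice!r} "
      f"(tier {result.tier})")
# The tier tells you *why* the match holds: exact string equality, shared
# token, same label after normalization, or a curated synonym relationship.
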