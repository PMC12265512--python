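# Methods

This note documents the framework's design in enough detail to reimplement
it: the protocol semantics, the matching procedure, the predictor-side
sequence handling, the evaluation metrics, and what the synthetic data does
and does not emulate.

## Protocol

### Messages and validation

Five message types cross the wire: `PredictionRequest`,
`PredictionResponse`, `MatchRequest`, `MatchResponse` and `ErrorMessage`.
All are pydantic models with `extra="forbid"`; the JSON Schema exports in
`src/benchlink/protocol/schemas/` are generated from the models and a test
pins them against drift. A request carries an ordered task list, an ordered
sequence list and the accepted response formats; a response partitions the
request exactly — every `(task, sequence)` pair appears either in
`predictions` or, via its task, in `declines`. Sequences are upcased on
validation and restricted to `ACGTN`; anything else is rejected rather than
silently coerced, so soft-masked input cannot change behaviour between
predictors. Sequences and tasks are serialized as lists (not JSON objects)
so duplicate identifiers are detectable on the wire instead of being
silently deduplicated by the JSON object model.

Tasks deliberately contain **no assay field**. They name a phenomenon
(binding, accessibility, conformation, expression), a molecule, a cell type,
a species, a readout (point or track), a strand policy, optional constant
flanks, and an optional prediction window. Coordinates are 0-based,
half-open, on the unmodified benchmark sequence, flanks excluded — stated
once here, used everywhere.

### Framing and formats

A message travels as: 1 format-tag byte (`0x01` JSON, `0x02` MessagePack),
an 8-byte big-endian unsigned payload length, then the payload. The length
prefix makes message boundaries independent of TCP segmentation, and the tag
lets one connection mix formats. Format negotiation is explicit: the request
lists `accepted_formats` (JSON always included) and the server replies in the
first format it supports. The MessagePack codec is implemented in-package
(`protocol/mpack.py`) over the subset the protocol needs — nil, booleans,
all integer families, float64, strings, bytes, arrays, string-keyed maps —
and is property-tested for agreement with JSON semantics on all
JSON-expressible values. Frames above 2^31 bytes are rejected; a benchmark
too large for one frame should be split (see *Splitting*), not enlarged.

`protocol_version` is a semantic version checked for **major**-version
equality only; a predictor receiving an incompatible major version declines
every task with reason `protocol version mismatch` rather than failing the
connection, keeping frozen modules comparable as minor versions evolve.

### Transport

Servers are strictly sequential: one connection at a time, any number of
request/response exchanges per connection. Sequential service keeps request
handling a pure function of its inputs and is sufficient for the contract;
parallelism belongs at the benchmark-splitting level. Malformed payloads are
answered with an `ErrorMessage` naming the failing field — never a silent
drop. Transport failures (bind, connect, idle timeout) are distinct error
types carrying `host:port`.

## Matching

`normalize_label` upcases and strips every character outside `[A-Z0-9]`
(idempotent). `match_one` applies four tiers in strict order and stops at
the first tier with a hit:

1. **exact** — string equality (confidence 1.0);
2. **lexical** — the term is a whole token of a choice, or vice versa,
   tokenizing on non-alphanumeric runs (0.9);
3. **syntactic** — equality of normalized forms, or normalized-token
   containment, covering dash/case/spacing variants (0.8);
4. **semantic** — term and choice share a synonym group in the table (0.7).

Ties within a tier break by earliest list position; both rules are
deterministic and documented because candidate order is part of a
predictor's manifest. Confidences are fixed per tier, not calibrated —
the tier is the information, the number is only a monotone encoding of it.

The bundled synonym table (`matcher/data/synonyms.json`) covers common cell
line, molecule and species aliases and is the default, fully reproducible
semantic backend. A knowledge-richer backend (e.g. an external
language-model service) can be substituted through the same
`(term, choices) -> MatchResponse` contract (`RemoteMatchBackend`); none is
bundled, keeping results reproducible with no model download.

**Tournament matching.** Lists longer than `chunk_size` (default 20, chosen
as a conservative context budget for substitutable backends; the
deterministic backend has no real limit) are split into consecutive chunks;
the backend picks at most one champion per chunk (no-match chunks yield
none); champions meet in a championship round, recursing while they still
exceed `chunk_size`. Because each tier predicate depends only on
`(term, choice)`, the tournament provably returns the same answer as one
exhaustive round for the deterministic backend — property-tested across
random lists and chunk sizes, and exercised with planted-synonym fixtures
whose distractors are verified to match at no tier.

## Predictor kit

A model plugs in as a callable `model(sequence, labels) -> scalar | array`
plus a capability manifest (supported phenomena, label triplets, input
length, native readout, bin width, strand handling).

**Task resolution.** An exact triplet match short-circuits (empty requested
fields are wildcards). Otherwise each field is matched against the
manifest's values for that field — via the configured matcher, memoized per
unique `(field, term, choices)` within a request. Any unresolvable field
declines the task with a controlled reason (`unsupported phenomenon`,
`unresolved cell_type` / `species` / `molecule`, `matcher unavailable`);
controlled strings keep reports machine-checkable. Any tier above `none` is
accepted, and the resolved triplet is echoed in `resolved_tasks` so the
evaluator can audit substitutions.

**Sequence adaptation.** Flanks attach first (`upstream + seq +
downstream`). Shorter than the model input `L`: pad with `N` symmetrically
(left pad `floor((L-len)/2)`) — `N` because it is the standard unknown base,
centered to keep context symmetric. Longer: center-crop, but the crop is
shifted as needed so the prediction window survives whole; if the window is
wider than `L` the task is declined (`window exceeds model input`) — a
silently cropped window would corrupt the benchmark. The offset map records
which interval of the original sequence survives and where, so the window
round-trips exactly between coordinate systems (property-tested).

**Strand policy.** `sense` scores the sequence as given; `antisense` scores
the reverse complement, with track output reversed so coordinates stay on
the benchmark orientation; `unstranded` averages both orientations. Wrapping
any model `g` as `f(s) = (g(s) + g(rc(s)))/2` (`models.symmetrize`) makes
all three policies coincide exactly.

**Aggregation.** Track-to-point uses the coverage-weighted mean over the
window, `sum(v_b * overlap_b) / sum(overlap_b)`; replicate tracks reduce by
element-wise mean. A point-native model asked for a track readout declines
(`track readout unsupported`) — inventing positional structure would be
worse than refusing.

## Evaluator kit

`build_request` emits one task per condition label with the sequences
attached once. Responses are verified against the partition invariant and
track-coverage invariant before any metric is computed.

Metrics are Pearson and Spearman correlations (scipy.stats underneath),
requiring n ≥ 3 and nonzero variance; violations yield an *undefined-metric
record* (value null, note set), never a crash. The differential metric for a
condition pair correlates per-sequence observed differences with predicted
differences; it is computed for **all** unordered pairs of scored
conditions. Missing measurement cells are dropped pairwise per metric with
the effective N recorded. Track benchmarks report the mean of per-sequence
correlations rather than one pooled correlation, because pooling conflates
between-sequence signal (mostly sequence composition) with the
within-sequence positional signal the readout is about.

**Consistency evaluation** requests each sequence and its reverse complement
as sense-strand tasks; point readout correlates the paired values, track
readout reverses each reverse-complement track onto forward coordinates and
averages per-sequence correlations. Identical forward/reverse predictions
short-circuit to exactly 1.0, avoiding spurious unit-ulp deviations from the
correlation arithmetic. Any prediction window is ignored here: a fixed
window would address different bases in the two orientations.

**Splitting.** `split_benchmark(b, k)` produces k contiguous parts whose
union reconstructs the benchmark; `run_evaluation(..., split=k)` sends one
request per part and computes metrics once on the merged prediction set, so
metrics are exactly invariant to k (tested for k ∈ {1, 2, 5, n}).

**Reports** are JSON (fixed, versioned schema) plus a flat TSV twin. The
partition invariant — metric records + skipped records = requested tasks —
is enforced by `check_partition`. Reports are identical across repeated runs
up to the timestamp (and the endpoint identity when ephemeral ports are
used).

## Synthetic data

`generate_point_benchmark(n, L, conditions, noise_sd, seed)` draws i.i.d.
uniform `ACGT` sequences (optional GC skew; uniform is the simplest null,
skew exists to make GC-based models non-degenerate), one standard-normal
weight per k-mer per condition (k = 3 by default: 64 weights, large enough
for rich variation, small enough that every k-mer occurs many times per
sequence), and sets

```
activity(i, c) = kmer_score(seq_i; w_c) + Normal(0, tau)
```

Defaults (n = 2000 sequences, length 200, three cell-type conditions)
emulate the scale of a down-sampled MPRA evaluation while keeping a full
evaluation under a few seconds. Because the ground truth is returned, an
oracle predictor closes the loop: at `tau = 0`, every per-task and
differential correlation must equal 1 to within 1e-9 — any deviation
indicates a pipeline defect. With noise, independent of the signal,

```
E[r] = sigma / sqrt(sigma^2 + tau^2)
```

and `noise_sd_for_target_r` inverts this; the attenuation check calibrates
tau on the generated signal's sd (per condition — each condition has its own
weight draw, hence its own sigma) and requires the observed r at n = 2000 to
fall within ±0.02 of the 0.9 target. The track generator emits per-position
k-mer weights (bin width 1, `track[i]` = weight of the k-mer starting at i,
so the track sums to the point score and bin aggregation is exercised
nontrivially).

What this synthetic data does **not** emulate: regulatory grammar, motif
positional effects, GC isochores, heteroscedastic or count-based assay
noise, and replicate structure. Passing tests therefore demonstrate the
*plumbing* — protocol, resolution, adaptation, bookkeeping, metric
arithmetic — is exact, not that any model predicts real regulatory activity.

Matcher fixtures plant one synonym/variant of a term at a seeded position
among distractor labels drawn from a disjoint alphabet and explicitly
verified to match at no tier.

## Numerical and degenerate-input choices

* Correlations: scipy implementations; n < 3 or zero variance → undefined
  record. Exact-identity prediction pairs short-circuit to 1.0 in the
  consistency evaluator only.
* k-mer scoring: k-mers containing `N` contribute 0; sequences shorter than
  k score 0 with a logged warning.
* GC content: fraction among non-`N` bases; all-`N` input scores 0.
* Envelope limit 2^31 bytes; oversized frames are a framing error.
* All generators take an explicit integer seed and are fully deterministic
  given it (same seed → byte-identical benchmark files).

## Limitations

* The semantic matching tier is only as good as the bundled synonym table;
  there is no ontology traversal. The backend interface exists for richer
  matchers, none is shipped.
* Conformation (matrix-valued) readouts are not modelled; the protocol
  covers point and track readouts only.
* Sequential, unencrypted, unauthenticated transport: the framework assumes
  trusted networks (loopback or private links).
* Predictor declines are per task, not per (task, sequence): if one sequence
  of a task cannot be adapted, the whole task is declined, which is
  conservative but keeps decline semantics simple.
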