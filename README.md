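# benchlink

**Standardized benchmarking of sequence-to-activity genomics models over a
common wire protocol.**

Sequence-to-activity models — networks that map DNA sequence to expression,
chromatin accessibility, DNA binding or 3D conformation — are usually
evaluated ad hoc, inside the paper that introduces them. Comparing models
across papers then conflates differences in architecture, training data and
evaluation procedure. `benchlink` separates those concerns with an API-style
contract:

* an **Evaluator** is a client that owns a benchmark dataset and its metrics;
* a **Predictor** is a server that owns a model and either fulfils a
  prediction request or *declines* it explicitly;
* a **Matcher** is a service that aligns the labels an Evaluator asks for
  (cell type, species, molecule) with the labels a Predictor supports, via
  lexical, syntactic and semantic tiers, scaling to long candidate lists by
  tournament elimination over chunks.

Every module speaks the same typed message protocol (JSON or MessagePack
payloads in length-prefixed envelopes over TCP), so any benchmark can drive
any model, locally or across a network. Tasks describe the biochemical
phenomenon being predicted — never the assay that measured it — so models
cannot score points by fitting assay-specific biases.

The package ships deterministic toy models (k-mer weight models, GC content)
and synthetic benchmark generators with known ground truth, so the entire
pipeline is testable end to end, exactly, without trained models or external
data.

## The quantities it computes

For a point (one scalar per sequence) benchmark with observed activities
$y_{ic}$ and predictions $\hat y_{ic}$ over sequences $i$ and conditions
(cell types) $c$:

* **per-condition performance** — Pearson $r(y_{\cdot c}, \hat y_{\cdot c})$
  (or Spearman);
* **differential performance** for each condition pair $(a, b)$ — Pearson
  between the per-sequence differences,
  $r(y_{\cdot a} - y_{\cdot b},\; \hat y_{\cdot a} - \hat y_{\cdot b})$,
  which is invariant to shared per-condition shifts and isolates
  condition-specific signal;
* **strand consistency** — Pearson between predictions for each sequence and
  its reverse complement (point), or the mean of per-sequence correlations
  after mapping reverse-complement tracks back onto forward coordinates
  (track). A strand-symmetric model scores exactly 1.

For track benchmarks, per-condition performance is the mean of per-sequence
correlations between measured and predicted positional signal.

Every evaluation produces a standard report (JSON + flat TSV) in which each
requested task appears exactly once — as a metric record or as a skipped
record carrying the predictor's decline reason.

## Worked example

```python
from benchlink import demo_end_to_end
report = demo_end_to_end(seed=0)
```

or `python examples/05_end_to_end_demo.py`, which prints:

```
benchmark: demo-mpra   predictor: 127.0.0.1:33733
  'K562': r = 1.000000 (N=200) -> model used 'K562'
  'hepatocellular carcinoma cell line': r = 1.000000 (N=200) -> model used 'HepG2'
  differential 'K562' vs 'hepatocellular carcinoma cell line': r = 1.000000
  'GM12878': SKIPPED (unresolved cell_type)
```

What happened: a matcher server and a predictor server were started on
loopback ports; the predictor serves the synthetic benchmark's own
ground-truth k-mer model, so correlations are exactly 1. The second
condition was requested under a fuzzy label — the predictor consulted the
matcher, whose semantic tier mapped it onto the model's `HepG2` (the
`resolved` field lets you audit this). The third condition is not in the
predictor's capability manifest and no tier can match it, so it was declined
and appears as a skipped record with a controlled reason string — never a
silent omission.

The other scripts in `examples/` each demonstrate one capability: the wire
format, label matching tiers and tournaments, serving + evaluating with
noise attenuation, and strand consistency.

## Command line

```bash
benchlink simulate-benchmark --n 2000 --length 200 --seed 1 --out bench/
benchlink serve-matcher --port 7780
benchlink serve-predictor --manifest manifest.json --port 7781 --matcher 127.0.0.1:7780
benchlink run-evaluator --benchmark bench/ --predictor 127.0.0.1:7781 --out report.json
benchlink demo
```

Benchmark directories are plain text: `sequences.fasta`, `measurements.tsv`,
`metadata.json`.

## Documentation

* `docs/methods.md` — the model of the framework: protocol semantics,
  matching tiers, sequence adaptation rules, metric definitions, synthetic
  data construction, numerical choices and known limitations.
* `docs/containers.md` — container recipes for deploying each service.
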