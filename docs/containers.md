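# Container recipes

Each service can be containerized so evaluations run identically across
machines and HPC clusters. The recipes below use Apptainer (no root
requirement, no network isolation — containers reach each other directly by
host:port, which the TCP transport relies on). They are shipped as
documentation; build them with `apptainer build <image>.sif <recipe>.def`.

## Matcher service

```
Bootstrap: docker
From: python:3.11-slim

%files
    . /opt/benchlink

%post
    pip install --no-cache-dir /opt/benchlink

%startscript
    benchlink serve-matcher --host 0.0.0.0 --port 7780
```

## Predictor service

A real model wrapper extends this recipe with its own weights and
dependencies; the scoring callable and manifest are the only integration
points (see `benchlink.predictor`).

```
Bootstrap: docker
From: python:3.11-slim

%files
    . /opt/benchlink
    manifest.json /opt/manifest.json

%post
    pip install --no-cache-dir /opt/benchlink

%startscript
    benchlink serve-predictor --manifest /opt/manifest.json \
        --host 0.0.0.0 --port 7781 --matcher matcher-host:7780
```

## Evaluator run

```
Bootstrap: docker
From: python:3.11-slim

%files
    . /opt/benchlink
    benchmark/ /opt/benchmark

%post
    pip install --no-cache-dir /opt/benchlink

%runscript
    benchlink run-evaluator --benchmark /opt/benchmark \
        --predictor "$1" --out /opt/report.json
```

## Module listings

A registry of available evaluators and predictors can be maintained as a
plain JSON list, one entry per module:

```json
[
  {
    "name": "synthetic-mpra-evaluator",
    "kind": "evaluator",
    "description": "MPRA-style point benchmark, 3 cell types, Pearson + differential metrics",
    "container": "https://example.org/records/<id>/evaluator.sif"
  }
]
```

New modules are added by appending an entry; consumers pull the list and
fetch containers from the recorded locations.
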