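"""One-command local end-to-end demo over loopback sockets.

Wires a matcher server, a toy predictor serving the benchmark's own
ground-truth model, and a synthetic benchmark evaluation into the full flow:
request -> matcher consultation -> prediction -> report.  One benchmark
condition is labelled with a fuzzy synonym (resolved by the matcher's
semantic tier) and one is deliberately outside the predictor's capabilities,
so the run exercises both the resolution path and the explicit-decline path.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

from .evaluator import EvaluationReport, PredictorClient, run_evaluation
from .matcher import MatcherClient, build_matcher_server
from .models import manifest_for_conditions
from .predictor import build_predictor_server
from .protocol import BindError
from .synthetic import generate_point_benchmark

log = logging.getLogger("benchlink.demo")

FUZZY_CONDITION = "hepatocellular carcinoma cell line"  # semantic alias of HepG2
UNSUPPORTED_CONDITION = "GM12878"  # absent from the demo predictor's manifest


def demo_end_to_end(
    seed: int = 0,
    ports: tuple[int, int] = (0, 0),
    *,
    n: int = 200,
    length: int = 120,
    noise_sd: float = 0.0,
    out_dir=None,
    host: str = "127.0.0.1",
) -> EvaluationReport:
    """Run the complete evaluation flow locally and return the report.

    The report should show two metric records (r = 1 for the noiseless
    default, the second via matcher resolution of a fuzzy condition label)
    and one skipped record for the unsupported condition.
    """
    benchmark, model = generate_point_benchmark(
        n=n, length=length,
        conditions=["K562", "HepG2", UNSUPPORTED_CONDITION],
        noise_sd=noise_sd, seed=seed, name="demo-mpra",
    )
    # Label one supported condition with a fuzzy synonym: the matcher, not
    # string equality, must map it back onto the model's label.
    benchmark.measurements = benchmark.measurements.rename(
        columns={"HepG2": FUZZY_CONDITION}
    )
    benchmark.conditions = ["K562", FUZZY_CONDITION, UNSUPPORTED_CONDITION]

    manifest = manifest_for_conditions(
        ["K562", "HepG2"], name="demo-oracle-predictor"
    )

    try:
        matcher_server = build_matcher_server(host, ports[0])
    except BindError as exc:
        raise BindError(f"{exc} (pick a free port or pass port=0)") from exc
    with matcher_server:
        matcher_client = MatcherClient(host, matcher_server.port)
        try:
            predictor_server = build_predictor_server(
                host, ports[1], model=model, manifest=manifest,
                matcher=matcher_client,
            )
        except BindError as exc:
            raise BindError(f"{exc} (pick a free port or pass port=0)") from exc
        with predictor_server:
            report = run_evaluation(
                benchmark, PredictorClient(host, predictor_server.port)
            )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_json(out_dir / "report.json")
        report.to_tsv(out_dir / "report.tsv")
        log.info("report written to %s", out_dir)
    return report
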