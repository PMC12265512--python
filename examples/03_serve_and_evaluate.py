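"""Serve a model over TCP and evaluate it on a synthetic MPRA benchmark.

Generates a noiseless benchmark with a known ground-truth k-mer model, serves
that model as a predictor on a loopback socket, and runs the evaluation: the
correlations must be exactly 1 because the predictor *is* the data-generating
function.  A second, noisy benchmark shows the closed-form attenuation
sigma/sqrt(sigma^2 + tau^2) of the observable correlation.
"""

from benchlink.evaluator import PredictorClient, run_evaluation
from benchlink.models import manifest_for_conditions
from benchlink.predictor import build_predictor_server
from benchlink.synthetic import generate_point_benchmark, noise_sd_for_target_r

bench, model = generate_point_benchmark(n=500, length=150, seed=42)
manifest = manifest_for_conditions(bench.conditions, name="oracle")

with build_predictor_server(model=model, manifest=manifest) as server:
    client = PredictorClient("127.0.0.1", server.port)
    report = run_evaluation(bench, client)
    print("noiseless oracle evaluation:")
    for r in report.records:
        print(f"  {r.condition:10} pearson r = {r.value:.12f}  (N={r.n})")
    for d in report.differentials:
        print(f"  {d.conditions[0]} vs {d.conditions[1]:10} "
              f"differential r = {d.value:.12f}")

    sigma = float(bench.measurements["K562"].std())
    tau = noise_sd_for_target_r(sigma, target_r=0.9)
    noisy, _ = generate_point_benchmark(
        n=500, length=150, conditions=["K562"], seed=42, noise_sd=tau
    )
    print(f"\nwith measurement noise tau = {tau:.2f} "
          f"(signal sd {sigma:.2f}, expected r = 0.9):")
    report = run_evaluation(noisy, client)
    print(f"  observed r = {report.records[0].value:.4f}")
# The noiseless run is the oracle-closure check: any deviation from 1 would
# indicate a defect in adaptation, serialization or bookkeeping, not biology.
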