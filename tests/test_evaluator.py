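"""Evaluator kit: benchmark IO, metrics, reports, and the evaluation flow."""

import numpy as np
import pandas as pd
import pytest

from benchlink.evaluator import (
    Benchmark,
    BenchmarkError,
    EvaluationReport,
    PredictorClient,
    TaskTemplate,
    UndefinedMetric,
    build_request,
    consistency_evaluate,
    differential_metric,
    pearson,
    run_evaluation,
    spearman,
    split_benchmark,
)
from benchlink.models import gc_model, manifest_for_conditions, symmetrize
from benchlink.predictor import build_predictor_server, reverse_complement
from benchlink.synthetic import generate_point_benchmark, generate_track_benchmark


def definition_pearson(x, y):
    """From-definition oracle: sum((x-xbar)(y-ybar)) / (n * sx * sy)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    return float(
        ((x - x.mean()) * (y - y.mean())).sum() / (len(x) * x.std() * y.std())
    )


class TestMetrics:
    def test_pearson_exact_linearity(self):
        assert pearson([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_pearson_matches_definition(self):
        x, y = [1, 2, 3, 4], [1, 3, 2, 4]
        assert definition_pearson(x, y) == pytest.approx(0.8)
        assert pearson(x, y) == pytest.approx(definition_pearson(x, y))

    def test_spearman_monotone_and_reversed(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman(x, list(reversed(x))) == pytest.approx(-1.0)

    def test_spearman_tie_case_matches_midrank_computation(self):
        # ranks of [1,2,2,3] with ties averaged: [1, 2.5, 2.5, 4]
        expected = definition_pearson([1, 2.5, 2.5, 4], [1, 2, 3, 4])
        assert spearman([1, 2, 2, 3], [1, 2, 3, 4]) == pytest.approx(expected)

    def test_zero_variance_is_undefined_not_crash(self):
        with pytest.raises(UndefinedMetric, match="zero variance"):
            pearson([1, 1, 1], [1, 2, 3])

    def test_too_few_points_undefined(self):
        with pytest.raises(UndefinedMetric, match=">= 3"):
            pearson([1, 2], [1, 2])


class TestDifferential:
    def obs(self):
        return pd.DataFrame(
            {"A": [1.0, 2.0, 3.0, 4.0], "B": [4.0, 1.0, 3.0, 2.0]},
            index=[f"s{i}" for i in range(4)],
        )

    def test_identity_prediction_gives_one(self):
        obs = self.obs()
        value, n = differential_metric(obs, obs.copy(), ("A", "B"))
        assert value == pytest.approx(1.0) and n == 4

    def test_shared_constant_shift_invariance(self):
        obs = self.obs()
        pred = obs + 17.3
        value, _ = differential_metric(obs, pred, ("A", "B"))
        assert value == pytest.approx(1.0)

    def test_hand_computed_oracle(self):
        obs = self.obs()
        pred = pd.DataFrame(
            {"A": [2.0, 2.5, 1.0, 5.0], "B": [3.0, 0.0, 4.0, 1.0]}, index=obs.index
        )
        expected = definition_pearson(
            (obs["A"] - obs["B"]).to_numpy(), (pred["A"] - pred["B"]).to_numpy()
        )
        value, _ = differential_metric(obs, pred, ("A", "B"))
        assert value == pytest.approx(expected)

    def test_missing_condition_is_undefined(self):
        obs = self.obs()
        with pytest.raises(UndefinedMetric, match="missing"):
            differential_metric(obs, obs[["A"]], ("A", "B"))


class TestBenchmarkContainer:
    def test_save_load_round_trip(self, small_benchmark, tmp_path):
        bench, _ = small_benchmark
        bench.save(tmp_path / "b")
        loaded = Benchmark.load(tmp_path / "b")
        assert loaded.name == bench.name
        assert loaded.sequences == bench.sequences
        assert loaded.conditions == bench.conditions
        pd.testing.assert_frame_equal(
            loaded.measurements[loaded.conditions],
            bench.measurements[bench.conditions],
            check_names=False,
        )

    def test_track_benchmark_round_trip(self, tmp_path):
        bench, _ = generate_track_benchmark(n=5, length=30, seed=2)
        bench.save(tmp_path / "t")
        loaded = Benchmark.load(tmp_path / "t")
        for sid in bench.sequences:
            np.testing.assert_allclose(
                loaded.measurements["K562"][sid], bench.measurements["K562"][sid]
            )

    def test_unknown_measured_id_rejected(self):
        with pytest.raises(BenchmarkError, match="missing from sequences"):
            Benchmark(
                name="bad",
                sequences={"s1": "ACGT"},
                measurements=pd.DataFrame({"A": [1.0]}, index=["ghost"]),
                conditions=["A"],
            )

    def test_empty_benchmark_rejected(self):
        with pytest.raises(BenchmarkError, match="no sequences"):
            Benchmark(name="bad", sequences={}, measurements=pd.DataFrame(),
                      conditions=["A"])


class TestBuildRequest:
    def test_one_task_per_condition_sequences_once(self, small_benchmark):
        bench, _ = small_benchmark
        req = build_request(bench)
        assert len(req.tasks) == 3
        assert len(req.sequences) == 50
        assert len({t.task_id for t in req.tasks}) == 3

    def test_flanks_propagate_to_every_task(self):
        bench, _ = generate_point_benchmark(n=10, length=40, seed=0)
        bench.template = TaskTemplate(
            upstream_flank="AGGACCGGATCAACT", downstream_flank="CATTGCGTGAACCGA"
        )
        req = build_request(bench)
        for t in req.tasks:
            assert t.upstream_flank == "AGGACCGGATCAACT"
            assert t.downstream_flank == "CATTGCGTGAACCGA"

    def test_no_assay_metadata_in_request(self, small_benchmark):
        bench, _ = small_benchmark
        payload = build_request(bench).model_dump()
        flat = str(payload)
        assert "assay" not in flat.lower()


class TestSplit:
    def test_identity_and_singletons(self, small_benchmark):
        bench, _ = small_benchmark
        assert len(split_benchmark(bench, 1)) == 1
        parts = split_benchmark(bench, bench.n_sequences)
        assert all(p.n_sequences == 1 for p in parts)
        union = [sid for p in parts for sid in p.sequences]
        assert union == list(bench.sequences)

    def test_union_reconstructs_measurements(self, small_benchmark):
        bench, _ = small_benchmark
        parts = split_benchmark(bench, 3)
        merged = pd.concat([p.measurements for p in parts])
        pd.testing.assert_frame_equal(merged, bench.measurements)

    def test_invalid_k_rejected(self, small_benchmark):
        bench, _ = small_benchmark
        with pytest.raises(ValueError):
            split_benchmark(bench, 0)
        with pytest.raises(ValueError):
            split_benchmark(bench, bench.n_sequences + 1)


@pytest.fixture(scope="module")
def oracle_server(small_benchmark):
    _, model = small_benchmark
    manifest = manifest_for_conditions(["K562", "HepG2", "GM12878"], name="oracle")
    with build_predictor_server(model=model, manifest=manifest) as srv:
        yield srv


class TestRunEvaluation:
    def test_oracle_closure_all_r_one(self, small_benchmark, oracle_server):
        bench, _ = small_benchmark
        report = run_evaluation(bench, ("127.0.0.1", oracle_server.port))
        assert len(report.records) == 3 and not report.skipped
        for r in report.records:
            assert r.value == pytest.approx(1.0, abs=1e-9)
        for d in report.differentials:
            assert d.value == pytest.approx(1.0, abs=1e-9)

    def test_declined_condition_becomes_skipped_record(self, small_benchmark):
        bench, model = small_benchmark
        manifest = manifest_for_conditions(["K562", "HepG2"], name="partial")
        with build_predictor_server(model=model, manifest=manifest) as srv:
            report = run_evaluation(bench, ("127.0.0.1", srv.port))
        assert len(report.records) == 2
        assert len(report.skipped) == 1
        assert report.skipped[0].condition == "GM12878"
        assert report.skipped[0].reason == "unresolved cell_type"

    def test_report_identical_across_runs_up_to_timestamp(
        self, small_benchmark, oracle_server
    ):
        bench, _ = small_benchmark
        a = run_evaluation(bench, ("127.0.0.1", oracle_server.port))
        b = run_evaluation(bench, ("127.0.0.1", oracle_server.port))
        assert a.model_dump(exclude={"timestamp"}) == b.model_dump(
            exclude={"timestamp"}
        )

    def test_unreachable_predictor_skips_everything(self, small_benchmark):
        bench, _ = small_benchmark
        report = run_evaluation(bench, PredictorClient("127.0.0.1", 1, timeout=1))
        assert not report.records
        assert {s.reason for s in report.skipped} == {"predictor unreachable"}
        report.check_partition([f"{bench.name}:{c}" for c in bench.conditions])

    @pytest.mark.parametrize("k", [1, 2, 5, 50])
    def test_split_invariance(self, small_benchmark, oracle_server, k):
        bench, _ = small_benchmark
        unsplit = run_evaluation(bench, ("127.0.0.1", oracle_server.port))
        split = run_evaluation(bench, ("127.0.0.1", oracle_server.port), split=k)
        assert [r.value for r in split.records] == [r.value for r in unsplit.records]
        assert [d.value for d in split.differentials] == [
            d.value for d in unsplit.differentials
        ]

    def test_msgpack_and_json_clients_agree(self, small_benchmark, oracle_server):
        bench, _ = small_benchmark
        rj = run_evaluation(bench, PredictorClient("127.0.0.1", oracle_server.port))
        rm = run_evaluation(
            bench, PredictorClient("127.0.0.1", oracle_server.port, format="msgpack")
        )
        assert [r.value for r in rj.records] == [r.value for r in rm.records]

    def test_report_json_tsv_round_trip(self, small_benchmark, oracle_server, tmp_path):
        bench, _ = small_benchmark
        report = run_evaluation(bench, ("127.0.0.1", oracle_server.port))
        report.to_json(tmp_path / "r.json")
        report.to_tsv(tmp_path / "r.tsv")
        assert EvaluationReport.from_json(tmp_path / "r.json") == report
        tsv = pd.read_csv(tmp_path / "r.tsv", sep="\t")
        assert len(tsv) == len(report.records) + len(report.differentials)


class TestConsistency:
    def test_symmetrized_model_point_consistency_exactly_one(self, small_benchmark):
        bench, model = small_benchmark
        manifest = manifest_for_conditions(["K562", "HepG2", "GM12878"])
        with build_predictor_server(model=symmetrize(model), manifest=manifest) as srv:
            res = consistency_evaluate(
                ("127.0.0.1", srv.port), bench.sequences, bench.template,
                condition="K562",
            )
        assert res.value == 1.0 and res.n == 50

    def test_track_consistency_symmetrized_exactly_one(self):
        bench, model = generate_track_benchmark(n=10, length=60, seed=4)
        manifest = manifest_for_conditions(
            ["K562"], phenomenon="accessibility", molecule="", native_output="track"
        )
        with build_predictor_server(model=symmetrize(model), manifest=manifest) as srv:
            res = consistency_evaluate(
                ("127.0.0.1", srv.port), bench.sequences, bench.template
            )
        assert res.value == 1.0

    def test_asymmetric_model_matches_brute_force_loop(self, rng):
        """consistency r for g(s) = count of 'A' equals a direct loop
        computing g on each sequence and its reverse complement."""
        seqs = {
            f"s{i}": "".join(rng.choice(list("ACGT"), size=40)) for i in range(30)
        }
        model = lambda s, l: float(s.count("A"))  # noqa: E731
        manifest = manifest_for_conditions(["K562"])
        with build_predictor_server(model=model, manifest=manifest) as srv:
            res = consistency_evaluate(
                ("127.0.0.1", srv.port), seqs, TaskTemplate(), condition="K562"
            )
        fwd = [float(s.count("A")) for s in seqs.values()]
        rev = [float(reverse_complement(s).count("A")) for s in seqs.values()]
        assert res.value == pytest.approx(definition_pearson(fwd, rev))

    def test_palindromic_sequences_give_one_for_any_model(self, rng):
        palindromes = {}
        for i in range(10):
            half = "".join(rng.choice(list("ACGT"), size=10))
            palindromes[f"p{i}"] = half + reverse_complement(half)
        model = lambda s, l: gc_model(s) + s.count("AC") * 0.1  # noqa: E731
        manifest = manifest_for_conditions(["K562"])
        with build_predictor_server(model=model, manifest=manifest) as srv:
            res = consistency_evaluate(
                ("127.0.0.1", srv.port), palindromes, TaskTemplate(), condition="K562"
            )
        assert res.value == 1.0

    def test_declined_task_surfaces_reason(self, rng):
        seqs = {f"s{i}": "ACGTACGTAC" for i in range(3)}
        manifest = manifest_for_conditions(["K562"], phenomenon="accessibility",
                                           molecule="")
        with build_predictor_server(model=gc_model_wrapper, manifest=manifest) as srv:
            res = consistency_evaluate(
                ("127.0.0.1", srv.port), seqs, TaskTemplate(phenomenon="expression")
            )
        assert res.value is None and res.reason == "unsupported phenomenon"


def gc_model_wrapper(seq, labels):
    return gc_model(seq)
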