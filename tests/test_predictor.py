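"""Predictor kit: task resolution, sequence adaptation, aggregation, serving."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from benchlink.matcher import LocalMatcher
from benchlink.models import manifest_for_conditions
from benchlink.predictor import (
    CapabilityManifest,
    DeclineTask,
    adapt_sequence,
    aggregate_to_point,
    aggregate_tracks,
    handle_request,
    resolve_task,
    reverse_complement,
)
from benchlink.protocol import (
    LabelTriplet,
    PredictionRequest,
    SequenceRecord,
    TaskSpec,
    Track,
    encode_message,
)


def task(**kw):
    defaults = dict(task_id="t1", phenomenon="expression", cell_type="K562",
                    species="Homo sapiens", molecule="mRNA")
    defaults.update(kw)
    return TaskSpec(**defaults)


class TestResolveTask:
    def test_exact_match_needs_no_matcher(self, oracle_manifest):
        resolved = resolve_task(task(), oracle_manifest, matcher=None)
        assert resolved.cell_type == "K562"

    def test_fuzzy_cell_type_resolves_through_matcher(self, oracle_manifest, table):
        resolved = resolve_task(
            task(cell_type="chronic myelogenous leukemia cell line"),
            oracle_manifest,
            matcher=LocalMatcher(table),
        )
        assert resolved.cell_type == "K562"

    def test_unsupported_phenomenon_declines(self, table):
        manifest = manifest_for_conditions(
            ["K562"], phenomenon="accessibility", molecule=""
        )
        with pytest.raises(DeclineTask, match="unsupported phenomenon"):
            resolve_task(task(phenomenon="expression"), manifest, LocalMatcher(table))

    def test_unresolvable_label_declines_naming_field(self, oracle_manifest, table):
        with pytest.raises(DeclineTask, match="unresolved cell_type"):
            resolve_task(
                task(cell_type="completely unknown tissue ZZZ"),
                oracle_manifest,
                LocalMatcher(table),
            )

    def test_matcher_needed_but_absent_declines(self, oracle_manifest):
        with pytest.raises(DeclineTask, match="unresolved cell_type"):
            resolve_task(task(cell_type="cml cell line"), oracle_manifest, None)

    def test_unreachable_matcher_declines_not_crashes(self, oracle_manifest):
        from benchlink.matcher import MatcherClient

        dead = MatcherClient("127.0.0.1", 1, timeout=1)
        with pytest.raises(DeclineTask, match="matcher unavailable"):
            resolve_task(task(cell_type="cml cell line"), oracle_manifest, dead)

    def test_empty_requested_field_is_unconstrained(self, oracle_manifest):
        resolved = resolve_task(task(cell_type="", molecule=""), oracle_manifest)
        assert resolved.cell_type == "K562"  # first manifest triplet


class TestAdaptSequence:
    def test_pad_symmetric_with_n(self):
        a = adapt_sequence("ACGT", task(), 8)
        assert a.sequence == "NNACGTNN"
        assert (a.orig_start, a.orig_end, a.adapted_start) == (0, 4, 2)

    def test_center_crop(self):
        a = adapt_sequence("ACGTACGTAC", task(), 4)
        assert a.sequence == "TACG"
        assert (a.orig_start, a.orig_end) == (3, 7)

    def test_window_wider_than_input_declines(self):
        t = task(prediction_window=(0, 10))
        with pytest.raises(DeclineTask, match="window exceeds model input"):
            adapt_sequence("ACGTACGTAC", t, 4)

    def test_crop_shifts_to_preserve_window(self):
        t = task(prediction_window=(0, 3))
        a = adapt_sequence("ACGTACGTAC", t, 4)
        assert a.orig_start == 0 and a.orig_end >= 3
        assert a.sequence == "ACGT"

    def test_flanks_attached_before_sizing(self):
        t = task(upstream_flank="GG", downstream_flank="TT")
        a = adapt_sequence("ACGT", t, 8)
        assert a.sequence == "GGACGTTT"
        assert a.adapted_start == 2

    def test_unbounded_model_keeps_sequence(self):
        a = adapt_sequence("ACGT", task(), None)
        assert a.sequence == "ACGT"

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        seq_len=st.integers(4, 60),
        L=st.integers(4, 80),
        ws=st.integers(0, 30),
        width=st.integers(1, 20),
        flank=st.integers(0, 6),
    )
    def test_offset_map_round_trip(self, seq_len, L, ws, width, flank):
        """Mapping the window into adapted coordinates and back is identity,
        and the window always survives inside the adapted sequence."""
        if ws + width > seq_len:
            ws = max(0, seq_len - width)
            width = min(width, seq_len - ws)
        t = task(prediction_window=(ws, ws + width), upstream_flank="A" * flank)
        try:
            a = adapt_sequence(("ACGT" * seq_len)[:seq_len], t, L)
        except DeclineTask:
            assert width > L  # only reason to decline with a valid window
            return
        for pos in (ws, ws + width):
            assert a.to_original(a.to_adapted(pos)) == pos
        assert 0 <= a.to_adapted(ws) and a.to_adapted(ws + width) <= len(a.sequence)


class TestAggregation:
    def test_coverage_weighted_mean_hand_computed(self):
        # bins [1,3,5], width 10: window [5,15) overlaps 5 bases of each of
        # the first two bins -> (1*5 + 3*5)/10 = 2.0
        t = Track(values=[1.0, 3.0, 5.0], bin_width=10, origin=0)
        assert aggregate_to_point(t, (5, 15)) == pytest.approx(2.0)

    def test_single_bin_window_is_that_bin(self):
        t = Track(values=[1.0, 3.0, 5.0], bin_width=10, origin=0)
        assert aggregate_to_point(t, (10, 20)) == pytest.approx(3.0)

    def test_constant_track_any_window(self):
        t = Track(values=[2.5] * 7, bin_width=3, origin=2)
        assert aggregate_to_point(t, (4, 19)) == pytest.approx(2.5)

    def test_zero_overlap_is_internal_error(self):
        t = Track(values=[1.0], bin_width=4, origin=0)
        with pytest.raises(RuntimeError):
            aggregate_to_point(t, (100, 104))

    def test_track_mean(self):
        a = Track(values=[1.0, 2.0], bin_width=1)
        b = Track(values=[3.0, 4.0], bin_width=1)
        assert aggregate_tracks([a, b]).values == [2.0, 3.0]

    def test_track_aggregation_identity_and_idempotence(self):
        a = Track(values=[1.0, 2.0], bin_width=1)
        assert aggregate_tracks([a]) == a
        assert aggregate_tracks([a, a, a]) == a

    def test_geometry_mismatch_is_internal_error(self):
        a = Track(values=[1.0, 2.0], bin_width=1)
        b = Track(values=[1.0], bin_width=1)
        with pytest.raises(RuntimeError):
            aggregate_tracks([a, b])


class TestStrand:
    @pytest.mark.parametrize("seq,rc", [("AAAC", "GTTT"), ("ACGT", "ACGT")])
    def test_reverse_complement(self, seq, rc):
        assert reverse_complement(seq) == rc

    def test_symmetrized_model_indifferent_to_strand_policy(self, oracle_manifest):
        """f(s) = (g(s)+g(rc(s)))/2 gives identical point outputs under
        sense, antisense and unstranded policies."""
        from benchlink.models import symmetrize

        model = symmetrize(lambda s, l: sum(b == "A" for b in s))
        req = {
            policy: PredictionRequest(
                request_id="r",
                tasks=[task(strand_policy=policy)],
                sequences=[SequenceRecord(sequence_id="s", sequence="AAACGTAC")],
            )
            for policy in ("sense", "antisense", "unstranded")
        }
        values = {
            policy: handle_request(r, model, oracle_manifest).predictions[0].value
            for policy, r in req.items()
        }
        assert values["sense"] == values["antisense"] == values["unstranded"]


class TestHandleRequest:
    def test_partition_bookkeeping(self, oracle_manifest, table):
        """2 tasks (one resolvable, one not) x 3 sequences ->
        3 predictions + 1 declined task."""
        req = PredictionRequest(
            request_id="r",
            tasks=[
                task(task_id="ok"),
                task(task_id="bad", cell_type="unknown tissue ZZZ"),
            ],
            sequences=[
                SequenceRecord(sequence_id=f"s{i}", sequence="ACGTACGT")
                for i in range(3)
            ],
        )
        resp = handle_request(
            req, lambda s, l: 1.0, oracle_manifest, LocalMatcher(table)
        )
        assert len(resp.predictions) == 3
        assert len(resp.declines) == 1
        assert resp.declines[0].task_id == "bad"
        assert resp.declines[0].reason == "unresolved cell_type"
        assert set(resp.resolved_tasks) == {"ok"}

    def test_empty_task_list_is_valid(self, oracle_manifest):
        req = PredictionRequest(
            request_id="r", tasks=[],
            sequences=[SequenceRecord(sequence_id="s", sequence="ACGT")],
        )
        resp = handle_request(req, lambda s, l: 1.0, oracle_manifest)
        assert resp.predictions == [] and resp.declines == []

    def test_determinism_byte_identical(self, oracle_manifest):
        req = PredictionRequest(
            request_id="r", tasks=[task()],
            sequences=[SequenceRecord(sequence_id="s", sequence="ACGTACGT")],
        )
        model = lambda s, l: sum(b in "GC" for b in s) / len(s)  # noqa: E731
        a = handle_request(req, model, oracle_manifest)
        b = handle_request(req, model, oracle_manifest)
        assert encode_message(a, "json") == encode_message(b, "json")

    def test_track_readout_from_point_model_declines(self, oracle_manifest):
        req = PredictionRequest(
            request_id="r", tasks=[task(readout="track")],
            sequences=[SequenceRecord(sequence_id="s", sequence="ACGTACGT")],
        )
        resp = handle_request(req, lambda s, l: 1.0, oracle_manifest)
        assert resp.declines[0].reason == "track readout unsupported"

    def test_point_from_track_model_aggregates_over_window(self):
        manifest = manifest_for_conditions(
            ["K562"], phenomenon="accessibility", molecule="",
            native_output="track",
        )
        # track model: position index as value; window mean is known exactly
        model = lambda s, l: np.arange(len(s), dtype=float)  # noqa: E731
        req = PredictionRequest(
            request_id="r",
            tasks=[task(phenomenon="accessibility", molecule="",
                        prediction_window=(2, 6))],
            sequences=[SequenceRecord(sequence_id="s", sequence="ACGTACGT")],
        )
        resp = handle_request(req, model, manifest)
        assert resp.predictions[0].value == pytest.approx(np.mean([2, 3, 4, 5]))

    def test_protocol_version_mismatch_declines_all(self, oracle_manifest):
        req = PredictionRequest(
            request_id="r", protocol_version="2.0.0", tasks=[task()],
            sequences=[SequenceRecord(sequence_id="s", sequence="ACGT")],
        )
        resp = handle_request(req, lambda s, l: 1.0, oracle_manifest)
        assert [d.reason for d in resp.declines] == ["protocol version mismatch"]

    def test_randomized_manifest_partition_property(self, rng, table):
        """predictions + declines exactly cover the request for random
        manifests and random task label draws."""
        labels = ["K562", "HepG2", "GM12878", "A549", "unknownZZZ", "cml cell line"]
        for _ in range(15):
            supported = list(rng.choice(labels[:4], size=2, replace=False))
            manifest = manifest_for_conditions(supported)
            tasks = [
                task(task_id=f"t{i}", cell_type=str(rng.choice(labels)))
                for i in range(int(rng.integers(1, 4)))
            ]
            seqs = [
                SequenceRecord(sequence_id=f"s{i}", sequence="ACGTACGTAC")
                for i in range(int(rng.integers(1, 4)))
            ]
            req = PredictionRequest(request_id="r", tasks=tasks, sequences=seqs)
            resp = handle_request(req, lambda s, l: 0.5, manifest, LocalMatcher(table))
            declined = {d.task_id for d in resp.declines}
            expected = {
                (t.task_id, s.sequence_id)
                for t in tasks if t.task_id not in declined for s in seqs
            }
            assert set(resp.prediction_map()) == expected
            assert declined | set(resp.resolved_tasks) == {t.task_id for t in tasks}


class TestManifest:
    def test_json_round_trip(self, oracle_manifest, tmp_path):
        path = tmp_path / "manifest.json"
        oracle_manifest.to_json(path)
        assert CapabilityManifest.from_json(path) == oracle_manifest

    def test_empty_label_list_rejected(self):
        with pytest.raises(ValueError, match="empty label list"):
            CapabilityManifest(phenomena={"expression": []})

    def test_label_choices_ordered_unique(self, oracle_manifest):
        assert oracle_manifest.label_choices("expression", "cell_type") == [
            "K562", "HepG2", "GM12878",
        ]
        assert oracle_manifest.label_choices("expression", "species") == [
            "Homo sapiens"
        ]
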