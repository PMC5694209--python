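import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtfscan.adapters import PosteriorTrack
from mtfscan.classify import ClassifyParams, LocationClass
from mtfscan.consensus import (
    consensus_topology,
    filter_tmhmm,
    merge_branches,
    topologies_agree,
)
from mtfscan.fixtures import plant_tm_protein, soluble_decoy
from mtfscan.model import (
    MtfscanError,
    ProteinRecord,
    TmSpan,
    TopologyPrediction,
)
from conftest import alternating_topologies


def pred_from_spans(spans, length=100, predictor="generic", first="i"):
    return TopologyPrediction.from_spans("P", length, [TmSpan(s, e) for s, e in spans],
                                         predictor=predictor, first_loop=first)


class TestAgreement:
    def test_identical_predictions_agree(self):
        a = pred_from_spans([(10, 30)])
        assert topologies_agree(a, a)

    def test_overlap_boundary(self):
        a = pred_from_spans([(10, 30)])
        assert topologies_agree(a, pred_from_spans([(26, 46)]))   # overlap 5
        assert not topologies_agree(a, pred_from_spans([(27, 47)]))  # overlap 4

    def test_span_count_mismatch(self):
        assert not topologies_agree(pred_from_spans([(10, 30)]),
                                    pred_from_spans([(10, 30), (50, 70)]))

    def test_orientation_mismatch_disagrees(self):
        a = pred_from_spans([(10, 30)], first="i")
        b = pred_from_spans([(10, 30)], first="o")
        assert not topologies_agree(a, b)

    def test_soluble_predictions_agree_regardless_of_loop_label(self):
        a = pred_from_spans([], first="i")
        b = pred_from_spans([], first="o")
        assert topologies_agree(a, b)

    def test_length_mismatch_rejected(self):
        with pytest.raises(MtfscanError):
            topologies_agree(pred_from_spans([], length=10),
                             pred_from_spans([], length=11))

    @settings(max_examples=100, deadline=None)
    @given(alternating_topologies(min_len=20, max_len=60),
           alternating_topologies(min_len=20, max_len=60),
           st.integers(1, 8))
    def test_reflexive_and_symmetric(self, sa, sb, min_overlap):
        n = min(len(sa), len(sb))
        a = TopologyPrediction.from_states("P", sa[:n] if sa[:n][0] != "M" else "i" + sa[1:n])
        b = TopologyPrediction.from_states("P", sb[:n] if sb[:n][0] != "M" else "i" + sb[1:n])
        assert topologies_agree(a, a, min_overlap)
        assert topologies_agree(b, b, min_overlap)
        assert topologies_agree(a, b, min_overlap) == topologies_agree(b, a, min_overlap)


class TestConsensus:
    def test_unanimous_support_six(self):
        preds = [pred_from_spans([(10, 30)], predictor=f"p{i}") for i in range(6)]
        res = consensus_topology(preds)
        assert res.support == 6
        assert [(s.start, s.end) for s in res.winner.spans] == [(10, 30)]

    def test_majority_over_soluble(self):
        preds = [pred_from_spans([(10, 30)], predictor=f"m{i}") for i in range(4)]
        preds += [pred_from_spans([], predictor=f"s{i}") for i in range(2)]
        res = consensus_topology(preds)
        assert res.support == 4 and res.winner.n_spans == 1
        assert sorted(len(c) for c in res.classes) == [2, 4]

    def test_tie_breaks_by_priority_of_representative(self):
        membrane = [pred_from_spans([(10, 30)], predictor=p)
                    for p in ("HMMTOP", "PHOBIUS", "S-TMHMM")]
        soluble = [pred_from_spans([], predictor=p)
                   for p in ("TOPPRED", "SCAMPI", "MEMSAT")]
        res = consensus_topology(membrane + soluble)
        assert res.support == 3 and res.winner.n_spans == 1  # HMMTOP founded first
        res2 = consensus_topology(membrane + soluble,
                                  priority=("TOPPRED", "SCAMPI", "MEMSAT",
                                            "HMMTOP", "PHOBIUS", "S-TMHMM"))
        assert res2.winner.n_spans == 0

    @pytest.mark.parametrize("n", [1, 2, 5])
    def test_n_copies_support_n(self, n):
        preds = [pred_from_spans([(10, 30)], predictor=f"p{i}") for i in range(n)]
        assert consensus_topology(preds).support == n

    def test_empty_input_rejected(self):
        with pytest.raises(MtfscanError):
            consensus_topology([])

    def test_recovers_planted_label_with_one_wrong_predictor(self):
        # 5 of 6 simulated predictors correct (span jitter <= 3), 1 inverted
        rng = np.random.default_rng(42)
        correct = 0
        n = 200
        for k in range(n):
            is_mtf = k % 2 == 0
            length = 150
            truth = [(60, 80)] if is_mtf else []
            preds = []
            wrong_j = int(rng.integers(0, 6))
            for j in range(6):
                wrong = j == wrong_j
                spans = truth if not wrong else ([] if is_mtf else [(60, 80)])
                jittered = [
                    (s + int(rng.integers(-3, 4)), e + int(rng.integers(-3, 4)))
                    for s, e in spans
                ]
                preds.append(pred_from_spans(jittered, length=length,
                                             predictor=f"p{j}"))
            res = consensus_topology(preds)
            if (res.winner.n_spans > 0) == is_mtf:
                correct += 1
        assert correct / n >= 0.98


class TestTmhmmFilter:
    def test_high_posterior_kept(self):
        p = pred_from_spans([(10, 30)])
        track = PosteriorTrack("P", tuple([0.95] * 100))
        assert filter_tmhmm(p, track).n_spans == 1

    def test_boundary_is_strict(self):
        p = pred_from_spans([(10, 30)])
        track = PosteriorTrack("P", tuple([0.90] * 100))
        assert filter_tmhmm(p, track).n_spans == 0

    def test_mixed_posterior_mean_below(self):
        # 0.99 over 11 residues, 0.50 over 10 -> mean 0.7567 < 0.90
        vals = [0.0] * 9 + [0.99] * 11 + [0.50] * 10 + [0.0] * 70
        p = pred_from_spans([(10, 30)])
        assert filter_tmhmm(p, PosteriorTrack("P", tuple(vals))).n_spans == 0

    def test_min_statistic_stricter_than_mean(self):
        vals = [0.0] * 9 + [0.99] * 20 + [0.89] + [0.0] * 70
        p = pred_from_spans([(10, 30)])
        assert filter_tmhmm(p, PosteriorTrack("P", tuple(vals)),
                            statistic="mean").n_spans == 1
        assert filter_tmhmm(p, PosteriorTrack("P", tuple(vals)),
                            statistic="min").n_spans == 0

    def test_missing_track_passes_unfiltered(self):
        p = pred_from_spans([(10, 30)])
        assert filter_tmhmm(p, None).n_spans == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(MtfscanError):
            filter_tmhmm(pred_from_spans([(10, 30)]), PosteriorTrack("P", (0.9,)))


def _cons(pred):
    return consensus_topology([pred])


class TestMerge:
    def setup_method(self):
        self.proteins = {
            "A": ProteinRecord("A", "S" * 100, species="sp1"),
            "B": ProteinRecord("B", "S" * 100, species="sp1"),
            "C": ProteinRecord("C", "S" * 100, species="sp1"),
        }

    def test_both_branches_consensus_spans_win(self):
        cons = {"A": _cons(TopologyPrediction.from_spans("A", 100, [TmSpan(10, 30)]))}
        tm = {"A": TopologyPrediction.from_spans("A", 100, [TmSpan(12, 33)],
                                                 predictor="TMHMM")}
        (rec,) = merge_branches(self.proteins, cons, tm)
        assert rec.provenance == {"consensus", "tmhmm"}
        assert [(s.start, s.end) for s in rec.spans] == [(10, 30)]

    def test_tmhmm_only(self):
        cons = {"B": _cons(TopologyPrediction.from_spans("B", 100, []))}
        tm = {"B": TopologyPrediction.from_spans("B", 100, [TmSpan(50, 70)],
                                                 predictor="TMHMM")}
        (rec,) = merge_branches(self.proteins, cons, tm)
        assert rec.provenance == {"tmhmm"}
        assert [(s.start, s.end) for s in rec.spans] == [(50, 70)]

    def test_neither_branch_absent(self):
        cons = {"C": _cons(TopologyPrediction.from_spans("C", 100, []))}
        tm = {"C": TopologyPrediction.from_spans("C", 100, [], predictor="TMHMM")}
        assert merge_branches(self.proteins, cons, tm) == []

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=12))
    def test_merged_set_is_union_of_branch_calls(self, flags):
        proteins, cons, tm = {}, {}, {}
        for i, (c_hit, t_hit) in enumerate(flags):
            pid = f"P{i}"
            proteins[pid] = ProteinRecord(pid, "S" * 60)
            cons[pid] = _cons(TopologyPrediction.from_spans(
                pid, 60, [TmSpan(20, 40)] if c_hit else []))
            tm[pid] = TopologyPrediction.from_spans(
                pid, 60, [TmSpan(20, 40)] if t_hit else [], predictor="TMHMM")
        merged = merge_branches(proteins, cons, tm)
        called = {m.protein.id for m in merged}
        c_calls = {p for p, r in cons.items() if r.winner.n_spans}
        t_calls = {p for p, r in tm.items() if r.n_spans}
        assert called == c_calls | t_calls
        assert len(called) >= max(len(c_calls), len(t_calls))
        for m in merged:
            assert m.provenance
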