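import numpy as np
import pytest

from mtfscan.classify import LocationClass
from mtfscan.fixtures import plant_tm_protein, soluble_decoy
from mtfscan.hydropathy import (
    HydroParams,
    HydroProfile,
    find_tm_segments,
    hydropathy_profile,
    load_scale,
    orient_topology,
    predict_topology_hydro,
)
from mtfscan.model import Certainty, ProteinRecord, SequenceError, TmSpan
from conftest import random_protein_seq
from oracles import bruteforce_profile

KD = HydroParams(scale="KD")


class TestProfile:
    def test_homopolymer_constant(self):
        prof = hydropathy_profile("L" * 30, KD)
        assert all(abs(v - 3.8) < 1e-12 for v in prof.values)

    def test_single_residue_degenerate_window(self):
        assert hydropathy_profile("M", KD).values == (1.9,)

    @pytest.mark.parametrize("seed,length", [(3, 50), (4, 10), (5, 200)])
    def test_matches_bruteforce_oracle(self, seed, length):
        rng = np.random.default_rng(seed)
        seq = random_protein_seq(rng, length)
        for params in (KD, HydroParams()):
            got = hydropathy_profile(seq, params).values
            want = bruteforce_profile(seq, load_scale(params.scale),
                                      params.core_len, params.wedge_len)
            assert np.allclose(got, want, atol=1e-9)

    def test_monotone_in_residue_hydrophobicity(self):
        # replacing any residue by a more hydrophobic one never lowers the profile
        rng = np.random.default_rng(8)
        seq = list(random_protein_seq(rng, 60))
        base = hydropathy_profile("".join(seq), KD).values
        pos = 25
        seq[pos] = "I"  # most hydrophobic on KD
        bumped = hydropathy_profile("".join(seq), KD).values
        assert all(b >= a - 1e-12 for a, b in zip(base, bumped))

    def test_unknown_scale_rejected(self):
        with pytest.raises(ValueError):
            hydropathy_profile("MKT", HydroParams(scale="nope"))


class TestSegments:
    def test_homopolymer_one_certain_span(self):
        params = HydroParams(scale="KD", lower_cutoff=0.6, upper_cutoff=1.0)
        prof = hydropathy_profile("L" * 25, params)
        spans = find_tm_segments(prof, params)
        assert len(spans) == 1
        assert (spans[0].start, spans[0].end) == (1, 25)
        assert spans[0].certainty is Certainty.CERTAIN

    def test_all_below_cutoff_empty(self):
        prof = hydropathy_profile("S" * 30, KD)  # KD(S) = -0.8
        assert find_tm_segments(prof, KD) == []

    def test_short_gap_merged_before_length_test(self):
        # two above-cutoff runs separated by one residue; min_loop_len=2 merges
        vals = [0.0] * 5 + [2.0] * 8 + [0.0] + [2.0] * 8 + [0.0] * 5
        params = HydroParams(min_loop_len=2, min_helix_len=11)
        spans = find_tm_segments(HydroProfile(tuple(vals)), params)
        assert [(s.start, s.end) for s in spans] == [(6, 22)]

    def test_putative_below_upper_cutoff(self):
        vals = [0.0] * 5 + [0.8] * 12 + [0.0] * 5
        spans = find_tm_segments(HydroProfile(tuple(vals)), HydroParams())
        assert spans[0].certainty is Certainty.PUTATIVE

    def test_min_helix_len_filters(self):
        vals = [0.0] * 5 + [2.0] * 8 + [0.0] * 5
        assert find_tm_segments(HydroProfile(tuple(vals)),
                                HydroParams(min_helix_len=11)) == []


class TestOrientation:
    def test_soluble_default_all_inside(self):
        pred = orient_topology("MKTLIV", [], protein_id="P")
        assert pred.states == "i" * 6 and pred.n_spans == 0

    def test_charge_forces_first_loop_inside(self):
        seq = "KKKSSSSS" + "L" * 21 + "SSSSSSSS"
        pred = orient_topology(seq, [TmSpan(9, 29)], protein_id="P")
        assert pred.first_loop == "i"
        assert pred.states == "i" * 8 + "M" * 21 + "o" * 8

    def test_charge_after_span_flips_orientation(self):
        seq = "SSSSSSSS" + "L" * 21 + "KKKKSSSS"
        pred = orient_topology(seq, [TmSpan(9, 29)], protein_id="P")
        assert pred.first_loop == "o"

    def test_tie_breaks_to_first_loop_inside(self):
        seq = "KKSSSSSS" + "L" * 21 + "SSSSSSKK"
        pred = orient_topology(seq, [TmSpan(9, 29)], protein_id="P")
        assert pred.first_loop == "i"

    def test_charge_window_limits_distal_residues(self):
        # K's far from the span (beyond the 15-residue window) do not count
        seq = "KKKK" + "S" * 40 + "L" * 21 + "SSSSKKKK"
        pred = orient_topology(seq, [TmSpan(45, 65)], loop_charge_window=15,
                               protein_id="P")
        assert pred.first_loop == "o"

    def test_span_out_of_range_rejected(self):
        with pytest.raises(SequenceError):
            orient_topology("MKT", [TmSpan(2, 10)], protein_id="P")

    def test_adding_kkkk_to_n_loop_flips_inside(self):
        # C-loop holds 3 basic residues, so alone it wins ...
        core = "L" * 21 + "KKKSSSSS"
        assert orient_topology("SSSSSSSS" + core, [TmSpan(9, 29)],
                               protein_id="P").first_loop == "o"
        # ... until 4 K's appear in the N-loop within the charge window
        assert orient_topology("SSSSKKKK" + core, [TmSpan(9, 29)],
                               protein_id="P").first_loop == "i"


class TestEndToEnd:
    def test_soluble_decoy_no_spans(self):
        rec = soluble_decoy(200, 1)
        assert predict_topology_hydro(rec).n_spans == 0

    def test_planted_helix_recovered_near_midpoint(self):
        rec, truth = plant_tm_protein(1, [LocationClass.CENTRAL], 120, 7, "P")
        pred = predict_topology_hydro(rec)
        assert pred.n_spans == 1
        assert abs(pred.spans[0].midpoint - truth[0].midpoint) <= 3

    def test_two_planted_helices_in_order(self):
        rec, truth = plant_tm_protein(
            2, [LocationClass.N_TERMINAL, LocationClass.C_TERMINAL], 300, 9, "P")
        pred = predict_topology_hydro(rec)
        assert pred.n_spans == 2
        assert pred.spans[0].start < pred.spans[1].start
        for got, want in zip(pred.spans, truth):
            assert abs(got.midpoint - want.midpoint) <= 3

    def test_predictor_name(self):
        rec = ProteinRecord("P", "S" * 40)
        assert predict_topology_hydro(rec).predictor == "hydro-builtin"
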