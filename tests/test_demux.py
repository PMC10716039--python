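"""Alignment scoring, threshold cascade, demultiplexing and its evaluation."""

import itertools

import numpy as np
import pytest

import probepanel as pp
from probepanel.demux import (
    CRITERION_NAMES,
    AlignmentResult,
    CascadeThresholds,
    assignments_to_frame,
    cascade_fpr,
)
from probepanel.simulate import parse_read_id, read_id_for

from oracles import brute_force_free_end_gaps

# printed reference sequences for the mismatch-discrimination experiment
SEQ_0MM = "GGGTGCACGAGTGCGTGT"
SEQ_1MM = "GGGTACACGAGTGCGTGT"
SEQ_2MM = "GGGTACATGAGTGCGTGT"


class TestCountMismatches:
    def test_printed_one_and_two_mismatch_variants(self):
        assert pp.count_mismatches(SEQ_0MM, SEQ_1MM) == 1
        assert pp.count_mismatches(SEQ_0MM, SEQ_2MM) == 2

    def test_identity_is_zero(self):
        assert pp.count_mismatches(SEQ_0MM, SEQ_0MM) == 0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            pp.count_mismatches("ACGT", "ACG")


class TestAlignRead:
    def test_identity_alignment_counts(self):
        res = pp.align_read(SEQ_0MM, SEQ_0MM)
        assert res.raw_score == 18
        assert res.mismatches_total == 0
        assert res.aligned_bases == 18
        assert res.norm_score == 1.0

    def test_single_substitution_counted(self):
        res = pp.align_read(SEQ_1MM, SEQ_0MM)
        assert res.mismatches_total == 1
        assert res.mismatches_first10 == 1  # the substitution sits at barcode position 5

    def test_score_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(17)
        bases = "ACGT"
        for _ in range(200):
            la, lb = rng.integers(1, 9, size=2)
            a = "".join(bases[i] for i in rng.integers(0, 4, la))
            b = "".join(bases[i] for i in rng.integers(0, 4, lb))
            assert pp.align_read(a, b).raw_score == brute_force_free_end_gaps(a, b), (a, b)

    def test_score_symmetric_under_symmetric_scoring(self):
        rng = np.random.default_rng(5)
        bases = "ACGT"
        for _ in range(50):
            a = "".join(bases[i] for i in rng.integers(0, 4, rng.integers(5, 30)))
            b = "".join(bases[i] for i in rng.integers(0, 4, rng.integers(5, 30)))
            assert pp.align_read(a, b).raw_score == pp.align_read(b, a).raw_score

    def test_read_overhang_is_free(self):
        # barcode embedded in a longer read: no penalty for the flanks
        read = "TTTTT" + SEQ_0MM + "AAAAA"
        res = pp.align_read(read, SEQ_0MM)
        assert res.raw_score == 18
        assert res.aligned_bases == 18
        assert not res.starts_with_GGG  # prefix is checked on the read, not the alignment

    def test_n_bases_never_match(self):
        res = pp.align_read("GGGNNNNN", "GGGTGCAC")
        assert res.aligned_bases == 3  # only the GGG leader aligns
        assert pp.align_read("NNNN", "AAAA").raw_score == 0

    def test_invalid_symbol_position_reported(self):
        with pytest.raises(ValueError, match="position 4"):
            pp.align_read("ACGXT", "ACGT")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pp.align_read("", "ACGT")


class TestCascade:
    def test_passing_result(self):
        flags = pp.apply_cascade(_mk(mm=3, mm10=0, aligned=16, prefix="GGG"))
        assert flags.overall

    def test_aligned_bases_boundary_fails_only_that_criterion(self):
        flags = pp.apply_cascade(_mk(mm=0, mm10=0, aligned=14, prefix="GGG"))
        assert not flags.aligned_bases_ok
        assert flags.total_mismatches_ok and flags.first_window_ok and flags.prefix_ok
        assert not flags.overall

    def test_wrong_prefix_fails_only_prefix(self):
        flags = pp.apply_cascade(_mk(mm=0, mm10=0, aligned=20, prefix="TGG"))
        assert not flags.prefix_ok
        assert flags.total_mismatches_ok and flags.first_window_ok and flags.aligned_bases_ok

    def test_boundary_values_pass(self):
        # thresholds are inclusive: 5 total, 1 in first 10, 15 aligned
        flags = pp.apply_cascade(_mk(mm=5, mm10=1, aligned=15, prefix="GGG"))
        assert flags.overall

    def test_adding_criteria_never_raises_fpr(self, lib40):
        params = pp.SimulationParams(seed=41, spurious_short_event_rate=1.0)
        _, truth = pp.simulate_trace(lib40, {}, params, n_events=400, trace_id="fpr")
        reads = pp.simulate_basecalls(truth, lib40, params)
        by_id = truth.by_id()
        thresholds = CascadeThresholds()
        flagged = []
        for asn in pp.demux(reads, lib40, thresholds):
            is_real = not by_id[parse_read_id(asn.read_id)[1]].is_spurious
            flagged.append((asn.result.flags, is_real))
        for r in range(len(CRITERION_NAMES)):
            for subset in itertools.combinations(CRITERION_NAMES, r):
                base = cascade_fpr(flagged, subset)
                for extra in set(CRITERION_NAMES) - set(subset):
                    assert cascade_fpr(flagged, subset + (extra,)) <= base + 1e-12


def _mk(mm, mm10, aligned, prefix):
    return AlignmentResult(
        read_id="r", probe_id="p", raw_score=aligned - 2 * mm,
        norm_score=0.5, aligned_bases=aligned, mismatches_total=mm,
        mismatches_first10=mm10, first_y_bases=10,
        starts_with_GGG=prefix == "GGG", read_prefix=prefix,
    )


class TestDemux:
    def test_error_free_reads_all_assigned_correctly(self, lib40, clean_params):
        _, truth = pp.simulate_trace(lib40, {}, clean_params, n_events=400, trace_id="cl")
        reads = pp.simulate_basecalls(truth, lib40, clean_params)
        by_id = truth.by_id()
        for asn in pp.demux(reads, lib40):
            assert asn.passes
            assert asn.probe_id == by_id[parse_read_id(asn.read_id)[1]].probe_id

    def test_default_error_model_accuracy_above_95(self, lib40, sim_params):
        _, truth = pp.simulate_trace(lib40, {}, sim_params, n_events=2000, trace_id="er")
        reads = pp.simulate_basecalls(truth, lib40, sim_params)
        by_id = truth.by_id()
        assigned = correct = 0
        for asn in pp.demux(reads, lib40):
            if asn.probe_id is None:
                continue
            ev = by_id[parse_read_id(asn.read_id)[1]]
            if ev.is_spurious:
                continue
            assigned += 1
            correct += asn.probe_id == ev.probe_id
        assert assigned > 1000
        assert correct / assigned > 0.95

    def test_failed_cascade_leaves_read_unassigned(self, lib40):
        asn = pp.demux([("junk", "TTTTTTTTTTTTTTTTTTTT")], lib40)[0]
        assert asn.probe_id is None
        assert not asn.passes

    def test_tie_resolves_to_lexicographically_smallest_and_flags_ambiguous(self):
        seq = "GGG" + "ACGTACGTACGTACGT"
        lib = pp.BarcodeLibrary([
            pp.BarcodeRecord("p_b", seq), pp.BarcodeRecord("p_a", seq),
        ])
        asn = pp.demux([("r1", seq)], lib)[0]
        assert asn.best_probe_id == "p_a"
        assert asn.ambiguous

    def test_margin_nonnegative_and_order_invariant(self, lib40, sim_params):
        _, truth = pp.simulate_trace(lib40, {}, sim_params, n_events=50, trace_id="mi")
        reads = pp.simulate_basecalls(truth, lib40, sim_params)
        a1 = pp.demux(reads, lib40)
        shuffled = pp.BarcodeLibrary(list(reversed(lib40.records)))
        a2 = pp.demux(reads, shuffled)
        for x, y in zip(a1, a2):
            assert x.margin >= 0
            assert (x.best_probe_id, x.passes) == (y.best_probe_id, y.passes)

    def test_assignment_frame_has_expected_columns(self, lib5, clean_params):
        _, truth = pp.simulate_trace(lib5, {}, clean_params, n_events=10, trace_id="df")
        reads = pp.simulate_basecalls(truth, lib5, clean_params)
        df = assignments_to_frame(pp.demux(reads, lib5))
        assert {"read_id", "probe_id", "norm_score", "mismatches_total", "pass",
                "margin"} <= set(df.columns)


class TestROC:
    def test_perfect_separation_gives_auc_one(self):
        scored = [(_score(s), s > 0.5) for s in [0.1, 0.2, 0.3, 0.8, 0.9, 0.95]]
        _, auc = pp.roc_for_thresholds(scored)
        assert auc == pytest.approx(1.0)

    def test_random_labels_give_auc_half(self):
        rng = np.random.default_rng(8)
        scored = [(_score(float(s)), bool(l))
                  for s, l in zip(rng.random(10000), rng.random(10000) < 0.5)]
        _, auc = pp.roc_for_thresholds(scored)
        assert abs(auc - 0.5) < 0.02

    def test_hand_placed_points_auc(self):
        assert pp.auc_from_points([0.0, 0.5, 1.0], [0.0, 1.0, 1.0]) == pytest.approx(0.75)

    def test_matches_sklearn_on_random_scores(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        scores = np.concatenate([rng.normal(0.6, 0.2, 300), rng.normal(0.4, 0.2, 300)])
        labels = np.array([True] * 300 + [False] * 300)
        scored = [(_score(float(s)), bool(l)) for s, l in zip(scores, labels)]
        _, auc = pp.roc_for_thresholds(scored)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pp.roc_for_thresholds([(_score(0.5), True), (_score(0.6), True)])


def _score(s):
    return AlignmentResult(
        read_id="r", probe_id="p", raw_score=0, norm_score=s, aligned_bases=0,
        mismatches_total=0, mismatches_first10=0, first_y_bases=10,
        starts_with_GGG=True, read_prefix="GGG",
    )


class TestConfusion:
    def test_noiseless_reads_give_identity_matrix(self, lib5, clean_params):
        _, truth = pp.simulate_trace(lib5, {}, clean_params, n_events=100, trace_id="id")
        reads = pp.simulate_basecalls(truth, lib5, clean_params)
        assignments = pp.demux(reads, lib5)
        truth_map = {read_id_for("id", e.event_id): e.probe_id
                     for e in truth.events if not e.is_spurious}
        mat = pp.demux_confusion(assignments, truth_map, lib5)
        assert np.allclose(mat.to_numpy(), np.eye(len(lib5)))

    def test_rows_sum_to_one_with_default_errors(self, lib40, sim_params):
        _, truth = pp.simulate_trace(lib40, {}, sim_params, n_events=2000, trace_id="cf")
        reads = pp.simulate_basecalls(truth, lib40, sim_params)
        assignments = pp.demux(reads, lib40)
        truth_map = {read_id_for("cf", e.event_id): e.probe_id
                     for e in truth.events if not e.is_spurious}
        mat = pp.demux_confusion(assignments, truth_map, lib40)
        sums = mat.sum(axis=1).to_numpy()
        assert np.allclose(sums[sums > 0], 1.0)
        diag = np.diag(mat.to_numpy())
        assert diag.min() > 0.95
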