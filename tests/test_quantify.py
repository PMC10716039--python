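"""Hill curves, inversion, prediction, sequence similarity, selectivity metrics."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

import probepanel as pp
from probepanel.errors import (
    BelowBackgroundWarning,
    FlatCurveWarning,
    SaturatedCurveError,
)
from probepanel.quantify import (
    SelectivityMatrix,
    _global_align_matches,
    read_curves_tsv,
    curves_to_frame,
)

# single-probe reference curve parameters (half-saturation 1.77 nM,
# saturating rise 61.03 percentage points)
REF = pp.StandardCurve("ref", Kd=1.77, Vmax=61.03, B0=0.0)


class TestHillForward:
    def test_zero_concentration_gives_background(self):
        curve = pp.StandardCurve("p", Kd=1.0, Vmax=40.0, B0=12.0)
        assert pp.hill_forward(0.0, curve) == pytest.approx(12.0)

    def test_half_saturation_at_kd(self):
        assert pp.hill_forward(1.77, REF) == pytest.approx(61.03 / 2)

    def test_saturating_limit_is_vmax(self):
        assert pp.hill_forward(1.77e9, REF) == pytest.approx(61.03, abs=1e-6)

    def test_strictly_increasing_in_concentration(self):
        c = np.logspace(-3, 3, 200)
        d = pp.hill_forward(c, REF)
        assert np.all(np.diff(d) > 0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            pp.hill_forward(-0.1, REF)


class TestFitHill:
    CONCS = np.array([0.0, 0.25, 1.0, 4.0, 16.0, 64.0])

    def test_noiseless_recovery_to_1e6_relative(self):
        d = pp.hill_forward(self.CONCS, REF)
        fit = pp.fit_hill(self.CONCS, d)
        assert fit.Kd == pytest.approx(1.77, rel=1e-6)
        assert fit.Vmax == pytest.approx(61.03, rel=1e-6)
        assert fit.B0 == pytest.approx(0.0, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_noiseless_recovery_with_background(self):
        curve = pp.StandardCurve("p", Kd=1.09, Vmax=38.69, B0=12.32)
        d = pp.hill_forward(self.CONCS, curve)
        fit = pp.fit_hill(self.CONCS, d)
        assert fit.Kd == pytest.approx(1.09, rel=1e-6)
        assert fit.Vmax == pytest.approx(38.69, rel=1e-6)
        assert fit.B0 == pytest.approx(12.32, rel=1e-6)

    def test_noisy_kd_recovery_median_under_15pct(self):
        rng = np.random.default_rng(10)
        errs = []
        for _ in range(100):
            d = pp.hill_forward(self.CONCS, REF) + rng.normal(0, 2, self.CONCS.size)
            fit = pp.fit_hill(self.CONCS, np.clip(d, 0, 100))
            errs.append(abs(fit.Kd - 1.77) / 1.77)
        assert np.median(errs) < 0.15

    def test_kd_bias_shrinks_with_noise(self):
        rng = np.random.default_rng(11)
        med = []
        for noise in (2.0, 0.5, 0.05):
            errs = []
            for _ in range(40):
                d = pp.hill_forward(self.CONCS, REF) + rng.normal(0, noise, self.CONCS.size)
                errs.append(abs(pp.fit_hill(self.CONCS, np.clip(d, 0, 100)).Kd - 1.77) / 1.77)
            med.append(np.median(errs))
        assert med[2] < med[1] < med[0]

    def test_flat_data_warns_and_fits_zero_vmax(self):
        with pytest.warns(FlatCurveWarning):
            fit = pp.fit_hill([0.0, 1.0, 10.0], [20.0, 20.0, 20.0])
        assert fit.Vmax == 0.0

    def test_too_few_distinct_concentrations_rejected(self):
        with pytest.raises(ValueError):
            pp.fit_hill([0.0, 1.0, 1.0], [5.0, 10.0, 11.0])

    def test_missing_zero_point_needs_external_background(self):
        with pytest.raises(ValueError, match="B0"):
            pp.fit_hill([1.0, 2.0, 4.0], [10.0, 20.0, 30.0])
        fit = pp.fit_hill([1.0, 2.0, 4.0],
                          pp.hill_forward(np.array([1.0, 2.0, 4.0]), REF), B0=0.0)
        assert fit.Kd == pytest.approx(1.77, rel=1e-4)


class TestInvertHill:
    def test_background_maps_to_zero(self):
        curve = pp.StandardCurve("p", Kd=2.0, Vmax=50.0, B0=10.0)
        assert pp.invert_hill(10.0, curve) == 0.0

    def test_half_rise_maps_to_kd(self):
        curve = pp.StandardCurve("p", Kd=2.0, Vmax=50.0, B0=10.0)
        assert pp.invert_hill(35.0, curve) == pytest.approx(2.0)

    def test_round_trip_over_random_curves(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            curve = pp.StandardCurve(
                "p", Kd=float(10 ** rng.uniform(-2, 2)),
                Vmax=float(rng.uniform(5, 80)), B0=float(rng.uniform(0, 20)),
            )
            c = float(10 ** rng.uniform(-2, 2))
            assert pp.invert_hill(pp.hill_forward(c, curve), curve) == \
                pytest.approx(c, rel=1e-9)

    def test_below_background_clamps_to_zero_with_warning(self):
        curve = pp.StandardCurve("p", Kd=2.0, Vmax=50.0, B0=10.0)
        with pytest.warns(BelowBackgroundWarning):
            assert pp.invert_hill(5.0, curve) == 0.0

    def test_saturation_raises(self):
        curve = pp.StandardCurve("p", Kd=2.0, Vmax=50.0, B0=10.0)
        with pytest.raises(SaturatedCurveError):
            pp.invert_hill(60.0, curve)


class TestPredict:
    def test_on_curve_observations_give_unit_ratios(self):
        curves = {f"p{i}": pp.StandardCurve(f"p{i}", Kd=1.0 + i, Vmax=40.0, B0=10.0)
                  for i in range(5)}
        actual = {pid: 0.5 + i for i, pid in enumerate(sorted(curves))}
        obs = {pid: pp.hill_forward(actual[pid], curves[pid]) for pid in curves}
        preds = pp.predict_concentrations(obs, curves, actual)
        for p in preds:
            assert p.ratio == pytest.approx(1.0, rel=1e-9)

    def test_zero_actual_flagged_not_crashed(self):
        curves = {"p": pp.StandardCurve("p", Kd=1.0, Vmax=40.0, B0=10.0)}
        preds = pp.predict_concentrations({"p": 15.0}, curves, {"p": 0.0})
        assert preds[0].ratio is None
        assert preds[0].flag == "undefined_ratio"

    def test_missing_curve_recorded_and_run_continues(self):
        curves = {"p1": pp.StandardCurve("p1", Kd=1.0, Vmax=40.0, B0=10.0)}
        preds = pp.predict_concentrations({"p1": 20.0, "p2": 20.0}, curves)
        flags = {p.probe_id: p.flag for p in preds}
        assert flags["p2"] == "no_curve"
        assert flags["p1"] == "ok"

    def test_saturated_reading_clamps_to_calibrated_top(self):
        curve = pp.StandardCurve("p", Kd=1.0, Vmax=40.0, B0=10.0,
                                 conc_range=(0.0, 20.0))
        preds = pp.predict_concentrations({"p": 55.0}, {"p": curve})
        assert preds[0].flag == "saturated"
        assert preds[0].predicted_nM == 20.0


def brute_force_global(a: str, b: str):
    """(max score, max matches among optimal) over all global alignments."""
    la, lb = len(a), len(b)
    best = (-(la + lb), 0)
    for k in range(0, min(la, lb) + 1):
        for A in itertools.combinations(range(la), k):
            for B in itertools.combinations(range(lb), k):
                matches = sum(a[i] == b[j] for i, j in zip(A, B))
                score = matches - (k - matches) - (la - k) - (lb - k)
                best = max(best, (score, matches))
    return best


class TestSequenceSimilarity:
    def test_identical_sequences_are_100(self):
        seq = "UGAUUGUCCAAACGCAAUUCUU".replace("U", "T")
        assert pp.sequence_similarity(seq, seq) == 100.0

    def test_disjoint_alphabets_are_0(self):
        assert pp.sequence_similarity("AAAA", "CCCC") == 0.0

    def test_symmetry(self):
        a, b = "ACGTTGCA", "ACTTGG"
        assert pp.sequence_similarity(a, b) == pp.sequence_similarity(b, a)

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(13)
        bases = "ACGT"
        for _ in range(60):
            la, lb = rng.integers(1, 8, size=2)
            a = "".join(bases[i] for i in rng.integers(0, 4, la))
            b = "".join(bases[i] for i in rng.integers(0, 4, lb))
            assert _global_align_matches(a, b) == brute_force_global(a, b), (a, b)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pp.sequence_similarity("", "ACGT")


class TestSelectivity:
    def _matrix(self, n, p_values, expected):
        ids = [f"p{i:02d}" for i in range(n)]
        return SelectivityMatrix(
            p_values=pd.DataFrame(p_values, index=ids, columns=ids),
            expected=pd.DataFrame(expected, index=ids, columns=ids),
        )

    def test_diagonal_only_design_forced_arithmetic(self):
        n = 40
        p = np.ones((n, n))
        np.fill_diagonal(p, 0.001)
        exp = np.eye(n, dtype=bool)
        m = pp.selectivity_classify(self._matrix(n, p, exp))
        assert m.tp == pytest.approx(100 * 40 / 1600)  # 2.5% of all cells
        assert m.fn == 0.0
        assert m.fp == 0.0
        assert m.tn == pytest.approx(97.5)

    def test_all_significant_gives_fp_complement(self):
        n = 10
        p = np.zeros((n, n))
        exp = np.eye(n, dtype=bool)
        m = pp.selectivity_classify(self._matrix(n, p, exp))
        assert m.fp == pytest.approx(100.0 - 10.0)

    def test_proportions_sum_to_100(self):
        rng = np.random.default_rng(14)
        n = 12
        p = rng.random((n, n)) * 0.05
        exp = rng.random((n, n)) < 0.3
        np.fill_diagonal(exp, True)
        m = pp.selectivity_classify(self._matrix(n, p, exp))
        assert m.tp + m.fp + m.fn + m.tn == pytest.approx(100.0, abs=1e-9)

    def test_bh_correction_is_more_conservative(self):
        rng = np.random.default_rng(15)
        n = 10
        p = rng.random((n, n)) * 0.02  # many borderline cells
        exp = np.eye(n, dtype=bool)
        raw = pp.selectivity_classify(self._matrix(n, p, exp))
        bh = pp.selectivity_classify(self._matrix(n, p, exp), p_adjust="bh")
        assert bh.tp + bh.fp <= raw.tp + raw.fp  # fewer or equal positive calls

    def test_similarity_mask_diagonal_always_true(self):
        seqs = {"a": "ACGTACGTAC", "b": "TTTTTTTTTT", "c": "ACGTACGTAA"}
        mask = pp.expected_mask_from_similarity(seqs, threshold=90.0)
        assert all(mask.loc[i, i] for i in seqs)
        assert mask.loc["a", "c"]  # 9 of 10 bases identical = 90%
        assert not mask.loc["a", "b"]


class TestClassificationMetrics:
    def test_reported_platform_proportions(self):
        # printed confusion proportions: TP 2.65, FP 0.95, FN 0, TN 96.40
        m = pp.classification_metrics(2.65, 0.95, 0.0, 96.40)
        assert round(m.accuracy, 2) == 99.05
        assert round(m.specificity, 2) == 99.02
        assert round(m.sensitivity, 2) == 100.0

    def test_perfect_classifier(self):
        m = pp.classification_metrics(50, 0, 0, 50)
        assert m.accuracy == m.sensitivity == m.specificity == 100.0

    def test_degenerate_all_negative_flags_sensitivity(self):
        m = pp.classification_metrics(0, 0, 0, 100)
        assert m.accuracy == 100.0
        assert m.sensitivity is None
        assert m.summary()["sensitivity_pct"] is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            pp.classification_metrics(-1, 0, 0, 1)


class TestCurveIO:
    def test_curves_tsv_round_trip(self, tmp_path):
        curves = {
            "p1": pp.StandardCurve("p1", Kd=1.77, Vmax=61.03, B0=0.0, r2=0.9625,
                                   conc_range=(0.0, 50.0)),
            "p2": pp.StandardCurve("p2", Kd=1.09, Vmax=38.69, B0=12.32,
                                   conc_range=(0.0, 20.0)),
        }
        path = tmp_path / "curves.tsv"
        curves_to_frame(curves).to_csv(path, sep="\t", index=False)
        back = read_curves_tsv(path)
        for pid, cv in curves.items():
            assert back[pid].Kd == pytest.approx(cv.Kd, rel=1e-5)
            assert back[pid].conc_range == cv.conc_range
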