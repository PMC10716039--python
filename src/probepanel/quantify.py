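"""Hill-curve quantification and selectivity evaluation.

The percentage of delayed events for a probe follows saturation binding of
its analyte. The standard curve is a Hill equation with coefficient 1,

    D(C) = B0 + Vmax * C / (Kd + C),

with B0 the zero-analyte background (percentage delay at 0 nM), Vmax the
saturating rise and Kd the half-saturation concentration. Inverting the
fitted curve turns an observed percentage delay into a concentration
estimate; predictions are compared to known truth as predicted/actual
ratios. Selectivity is judged per probe-analyte pair: a significant rise in
percentage delay (p <= 0.01) is expected exactly where target sequence
similarity is at least 90%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    BelowBackgroundWarning,
    FitFailureError,
    FlatCurveWarning,
    SaturatedCurveError,
)


@dataclass
class StandardCurve:
    """Fitted Hill parameters for one probe. R2 is on the [0, 1] scale."""

    probe_id: str
    Kd: float  # nM
    Vmax: float  # percentage points
    B0: float  # background percentage at 0 nM
    n_H: float = 1.0
    r2: float = float("nan")
    conc_range: tuple[float, float] = (0.0, float("inf"))

    def __post_init__(self):
        if self.Kd <= 0:
            raise ValueError("Kd must be > 0")
        if not (0 <= self.Vmax <= 100) or not (0 <= self.B0 <= 100):
            raise ValueError("Vmax and B0 must be in [0, 100]")


@dataclass
class Prediction:
    probe_id: str
    observed_percent_delay: float
    predicted_nM: float
    actual_nM: float | None = None
    ratio: float | None = None  # predicted / actual, when actual > 0
    flag: str = "ok"  # ok | below_background | saturated | no_curve | undefined_ratio


def hill_forward(C, curve: StandardCurve):
    """Percent delay expected at concentration C (scalar or array)."""
    c = np.asarray(C, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    cn = c**curve.n_H
    out = curve.B0 + curve.Vmax * cn / (curve.Kd**curve.n_H + cn)
    return float(out) if np.isscalar(C) else out


def fit_hill(
    concentrations: Sequence[float],
    percent_delays: Sequence[float],
    fix_nH_to_1: bool = True,
    probe_id: str = "",
    B0: float | None = None,
) -> StandardCurve:
    """Least-squares Hill fit of percent delay against concentration.

    Needs at least 3 distinct concentrations, and either a 0 nM point (B0
    fitted freely) or an externally supplied ``B0``. The initializer is
    Vmax0 = max(D) - min(D), Kd0 = concentration nearest the half-rise,
    B00 = min(D); parameters are bounded (Kd > 0; Vmax, B0 in [0, 100]).
    """
    c = np.asarray(concentrations, dtype=float)
    d = np.asarray(percent_delays, dtype=float)
    if c.shape != d.shape or c.ndim != 1:
        raise ValueError("concentrations and percent_delays must be equal-length 1-D")
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    if len(np.unique(c)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    has_zero = bool(np.any(c == 0))
    if not has_zero and B0 is None:
        raise ValueError("no 0 nM point: supply B0 externally")

    span = float(d.max() - d.min())
    if span == 0:
        warnings.warn(
            f"percent delay is flat across concentrations (probe {probe_id or '?'}); "
            "Vmax is indeterminate and fitted as 0",
            FlatCurveWarning,
            stacklevel=2,
        )
        b0 = float(d[0]) if B0 is None else float(B0)
        return StandardCurve(probe_id=probe_id, Kd=float(np.median(c[c > 0]) or 1.0),
                             Vmax=0.0, B0=min(b0, 100.0), r2=float("nan"),
                             conc_range=(float(c.min()), float(c.max())))

    b0_init = float(d.min()) if B0 is None else float(B0)
    half_rise = b0_init + span / 2.0
    pos = c[c > 0]
    kd_init = float(pos[np.argmin(np.abs(d[c > 0] - half_rise))]) if pos.size else 1.0
    kd_init = max(kd_init, 1e-6)

    if fix_nH_to_1:
        if B0 is None:
            def model(x, kd, vmax, b0):
                return b0 + vmax * x / (kd + x)
            p0 = [kd_init, min(span, 100.0), min(b0_init, 100.0)]
            lb, ub = [1e-12, 0.0, 0.0], [np.inf, 100.0, 100.0]
        else:
            def model(x, kd, vmax):
                return B0 + vmax * x / (kd + x)
            p0 = [kd_init, min(span, 100.0)]
            lb, ub = [1e-12, 0.0], [np.inf, 100.0]
    else:
        if B0 is None:
            def model(x, kd, vmax, b0, nh):
                return b0 + vmax * x**nh / (kd**nh + x**nh)
            p0 = [kd_init, min(span, 100.0), min(b0_init, 100.0), 1.0]
            lb, ub = [1e-12, 0.0, 0.0, 0.1], [np.inf, 100.0, 100.0, 10.0]
        else:
            def model(x, kd, vmax, nh):
                return B0 + vmax * x**nh / (kd**nh + x**nh)
            p0 = [kd_init, min(span, 100.0), 1.0]
            lb, ub = [1e-12, 0.0, 0.1], [np.inf, 100.0, 10.0]

    try:
        popt, _ = curve_fit(model, c, d, p0=p0, bounds=(lb, ub),
                            maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    except RuntimeError as exc:
        resid = d - model(c, *p0)
        raise FitFailureError(
            f"Hill fit failed to converge for probe {probe_id or '?'}: {exc}",
            details={"initial_residual_ss": float(np.sum(resid**2)), "p0": p0},
        ) from exc

    pred = model(c, *popt)
    ss_res = float(np.sum((d - pred) ** 2))
    ss_tot = float(np.sum((d - d.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    kd = float(popt[0])
    vmax = float(popt[1])
    if B0 is None:
        b0 = float(popt[2])
        nh = float(popt[3]) if not fix_nH_to_1 else 1.0
    else:
        b0 = float(B0)
        nh = float(popt[2]) if not fix_nH_to_1 else 1.0
    return StandardCurve(
        probe_id=probe_id, Kd=kd, Vmax=min(vmax, 100.0), B0=min(b0, 100.0),
        n_H=nh, r2=r2, conc_range=(float(c.min()), float(c.max())),
    )


def invert_hill(D: float, curve: StandardCurve) -> float:
    """Concentration at which the curve predicts percent delay D.

    Readings below B0 clamp to 0 nM with a warning (a blinded sample may
    contain none of the analyte); readings at or above B0 + Vmax raise
    :class:`SaturatedCurveError` since concentration is unbounded there.
    """
    rise = D - curve.B0
    if rise < 0:
        warnings.warn(
            f"percent delay {D:.3g} is below background {curve.B0:.3g}; clamping to 0 nM",
            BelowBackgroundWarning,
            stacklevel=2,
        )
        return 0.0
    if rise >= curve.Vmax:
        raise SaturatedCurveError(
            f"percent delay {D:.3g} is at or above saturation "
            f"(B0 + Vmax = {curve.B0 + curve.Vmax:.3g}); concentration is unbounded"
        )
    return float(curve.Kd * (rise / (curve.Vmax - rise)) ** (1.0 / curve.n_H))


def predict_concentrations(
    percent_delays: Mapping[str, float],
    curves: Mapping[str, StandardCurve],
    actual: Mapping[str, float] | None = None,
) -> list[Prediction]:
    """Invert each probe's standard curve at its observed percent delay.

    The curve is treated as calibrated only within its fitted concentration
    range: readings at/above saturation, or inverting beyond the top
    standard, report the top of the range (flags ``saturated`` /
    ``above_range``) rather than extrapolating — near saturation the
    inverse is numerically explosive and a small noise excursion would
    otherwise produce an arbitrarily large estimate. Probes without a curve
    are flagged and skipped, not fatal. Ratios are predicted/actual where
    actual > 0.
    """
    out: list[Prediction] = []
    for probe_id in sorted(percent_delays):
        obs = float(percent_delays[probe_id])
        act = None if actual is None else actual.get(probe_id)
        curve = curves.get(probe_id)
        if curve is None:
            out.append(Prediction(probe_id, obs, float("nan"), act, None, "no_curve"))
            continue
        flag = "ok"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", BelowBackgroundWarning)
            top = curve.conc_range[1]
            try:
                pred = invert_hill(obs, curve)
                if obs < curve.B0:
                    flag = "below_background"
                elif np.isfinite(top) and pred > top:
                    pred = top
                    flag = "above_range"
            except SaturatedCurveError:
                pred = top if np.isfinite(top) else float("nan")
                flag = "saturated"
        ratio = None
        if act is not None:
            if act > 0 and np.isfinite(pred):
                ratio = pred / act
            else:
                flag = flag if flag != "ok" else "undefined_ratio"
        out.append(Prediction(probe_id, obs, pred, act, ratio, flag))
    return out


# ---------------------------------------------------------------------------
# Sequence similarity and selectivity


def _global_align_matches(a: str, b: str) -> tuple[int, int]:
    """(best score, max matches among optimal alignments) of a global alignment.

    Unit scoring: match +1, mismatch -1, gap -1, end gaps penalized. The DP
    carries (score, matches) lexicographically, which is exact because both
    objectives are additive over alignment columns.
    """
    n, m = len(a), len(b)
    NEG = -(10**9)
    score = np.empty((n + 1, m + 1), dtype=np.int64)
    matches = np.zeros((n + 1, m + 1), dtype=np.int64)
    score[0, :] = -np.arange(m + 1)
    score[:, 0] = -np.arange(n + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            is_match = a[i - 1] == b[j - 1]
            s = 1 if is_match else -1
            cand = (
                (score[i - 1, j - 1] + s, matches[i - 1, j - 1] + (1 if is_match else 0)),
                (score[i - 1, j] - 1, matches[i - 1, j]),
                (score[i, j - 1] - 1, matches[i, j - 1]),
            )
            score[i, j], matches[i, j] = max(cand)
    return int(score[n, m]), int(matches[n, m])


def sequence_similarity(seq_a: str, seq_b: str) -> float:
    """Percent identity: matches in the optimal global alignment over the longer length."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be nonempty")
    _, m = _global_align_matches(seq_a.upper(), seq_b.upper())
    return 100.0 * m / max(len(seq_a), len(seq_b))


@dataclass
class SelectivityMatrix:
    """Probe-by-analyte p-values with the similarity-derived expectation mask."""

    p_values: pd.DataFrame  # rows = probes, columns = analytes
    expected: pd.DataFrame  # bool mask, same shape; diagonal always True
    alpha: float = 0.01
    similarity_threshold: float = 90.0

    def __post_init__(self):
        if self.p_values.shape != self.expected.shape:
            raise ValueError("p_values and expected mask must have the same shape")
        if list(self.p_values.index) != list(self.expected.index) or list(
            self.p_values.columns
        ) != list(self.expected.columns):
            raise ValueError("p_values and expected mask must share labels")
        if self.p_values.shape[0] == self.p_values.shape[1]:
            diag = np.diag(self.expected.to_numpy())
            if not diag.all():
                raise ValueError("each probe must be expected to bind its own target")


def expected_mask_from_similarity(
    target_seqs: Mapping[str, str],
    threshold: float = 90.0,
) -> pd.DataFrame:
    """Expectation mask: probe row x analyte column, True where target similarity >= threshold."""
    ids = sorted(target_seqs)
    mask = pd.DataFrame(False, index=ids, columns=ids)
    for i in ids:
        for j in ids:
            mask.loc[i, j] = (
                i == j or sequence_similarity(target_seqs[i], target_seqs[j]) >= threshold
            )
    return mask


@dataclass
class ConfusionMetrics:
    """Counts or proportions plus derived rates (percent, undefined -> None)."""

    tp: float
    fp: float
    fn: float
    tn: float
    accuracy: float = field(init=False)
    sensitivity: float | None = field(init=False)
    specificity: float | None = field(init=False)

    def __post_init__(self):
        total = self.tp + self.fp + self.fn + self.tn
        if min(self.tp, self.fp, self.fn, self.tn) < 0 or total == 0:
            raise ValueError("counts must be >= 0 and not all zero")
        self.accuracy = 100.0 * (self.tp + self.tn) / total
        self.sensitivity = (
            100.0 * self.tp / (self.tp + self.fn) if (self.tp + self.fn) > 0 else None
        )
        self.specificity = (
            100.0 * self.tn / (self.tn + self.fp) if (self.tn + self.fp) > 0 else None
        )

    def summary(self) -> dict:
        fmt = lambda v: None if v is None else round(v, 2)
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "accuracy_pct": fmt(self.accuracy),
            "sensitivity_pct": fmt(self.sensitivity),
            "specificity_pct": fmt(self.specificity),
        }


def classification_metrics(tp: float, fp: float, fn: float, tn: float) -> ConfusionMetrics:
    """Accuracy, sensitivity and specificity from confusion counts or proportions."""
    return ConfusionMetrics(tp=tp, fp=fp, fn=fn, tn=tn)


def selectivity_classify(
    matrix: SelectivityMatrix, p_adjust: str | None = None
) -> ConfusionMetrics:
    """Tally probe-analyte cells into TP/FP/FN/TN percentages of all cells.

    A cell is called positive when its p-value is <= alpha; it is expected
    positive per the similarity mask. By default raw p-values are
    thresholded (single-readout convention); ``p_adjust="bh"`` applies a
    Benjamini-Hochberg correction across all n^2 cells first.
    """
    p = matrix.p_values.to_numpy(dtype=float)
    if p_adjust is not None:
        if p_adjust != "bh":
            raise ValueError("p_adjust must be None or 'bh'")
        from scipy.stats import false_discovery_control

        p = false_discovery_control(p.ravel(), method="bh").reshape(p.shape)
    exp = matrix.expected.to_numpy(dtype=bool)
    pos = p <= matrix.alpha
    total = p.size
    tp = int(np.sum(pos & exp))
    fp = int(np.sum(pos & ~exp))
    fn = int(np.sum(~pos & exp))
    tn = int(np.sum(~pos & ~exp))
    return ConfusionMetrics(
        tp=100.0 * tp / total, fp=100.0 * fp / total,
        fn=100.0 * fn / total, tn=100.0 * tn / total,
    )


def curves_to_frame(curves: Mapping[str, StandardCurve]) -> pd.DataFrame:
    rows = []
    for pid in sorted(curves):
        cv = curves[pid]
        rows.append(
            {
                "probe_id": pid,
                "Kd_nM": round(cv.Kd, 6),
                "Vmax_pct": round(cv.Vmax, 6),
                "B0_pct": round(cv.B0, 6),
                "n_H": cv.n_H,
                "R2": round(cv.r2, 6) if np.isfinite(cv.r2) else "",
                "conc_min_nM": cv.conc_range[0],
                "conc_max_nM": cv.conc_range[1] if np.isfinite(cv.conc_range[1]) else "",
            }
        )
    return pd.DataFrame(rows)


def read_curves_tsv(path) -> dict[str, StandardCurve]:
    """Load standard curves written by :func:`curves_to_frame`."""
    df = pd.read_csv(path, sep="\t")
    curves = {}
    for _, r in df.iterrows():
        cmax = r.get("conc_max_nM", float("inf"))
        curves[str(r["probe_id"])] = StandardCurve(
            probe_id=str(r["probe_id"]),
            Kd=float(r["Kd_nM"]),
            Vmax=float(r["Vmax_pct"]),
            B0=float(r["B0_pct"]),
            n_H=float(r.get("n_H", 1.0)),
            r2=float(r["R2"]) if pd.notna(r.get("R2")) and r.get("R2") != "" else float("nan"),
            conc_range=(
                float(r.get("conc_min_nM", 0.0) or 0.0),
                float(cmax) if pd.notna(cmax) and cmax != "" else float("inf"),
            ),
        )
    return curves


def predictions_to_frame(predictions: Sequence[Prediction]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probe_id": [p.probe_id for p in predictions],
            "percent_delay": [round(p.observed_percent_delay, 6) for p in predictions],
            "predicted_nM": [round(p.predicted_nM, 6) if np.isfinite(p.predicted_nM) else ""
                             for p in predictions],
            "actual_nM": ["" if p.actual_nM is None else p.actual_nM for p in predictions],
            "ratio": ["" if p.ratio is None else round(p.ratio, 6) for p in predictions],
            "flag": [p.flag for p in predictions],
        }
    )
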