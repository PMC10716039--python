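"""Delay classification of translocation events.

A bound analyte stalls the probe in the pore and produces a low-variance
"quiet" sojourn in the event signal. Each event's normalized samples are
split into 75 contiguous bins; an event is delayed when the per-bin standard
deviation stays below 0.003 (on fraction-of-open-pore current) for a run of
strictly more than 10 consecutive bins. Group comparisons of
percent-delayed values use Welch's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndersampledEventError


@dataclass
class DelayParams:
    """Binning and thresholding knobs for the delay rule.

    ``sd_threshold`` applies to open-pore-normalized current. ``mode`` is
    "binned" (disjoint bins, runs counted over consecutive bins — the
    default) or "sliding" (moving SD over a bin-width window, quiet span
    measured in bin widths).
    """

    n_bins: int = 75
    sd_threshold: float = 0.003
    min_run_bins: int = 10  # strict: delayed requires run > min_run_bins
    mode: str = "binned"

    def __post_init__(self):
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be > 0")
        if self.n_bins < self.min_run_bins + 1:
            raise ValueError("n_bins must be >= min_run_bins + 1")
        if self.mode not in ("binned", "sliding"):
            raise ValueError("mode must be 'binned' or 'sliding'")


@dataclass
class DelayCall:
    event_id: str | int
    bin_sds: np.ndarray
    longest_quiet_run: int
    delayed: bool


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    values_a: list[float]
    values_b: list[float]
    t: float
    p: float
    tail: str  # "one" or "two"


def bin_event(norm_samples: np.ndarray, params: DelayParams | None = None) -> np.ndarray:
    """Per-bin sample standard deviations of an event's normalized signal.

    Samples are partitioned into ``n_bins`` contiguous segments whose lengths
    differ by at most one. SDs use ddof=1; a single-sample bin has no defined
    variability and yields NaN (which the classifier treats as not quiet).
    """
    params = params or DelayParams()
    x = np.asarray(norm_samples, dtype=float)
    if x.size < params.n_bins:
        raise UndersampledEventError(
            f"event has {x.size} samples, fewer than n_bins={params.n_bins}"
        )
    nb = params.n_bins
    base, rem = divmod(x.size, nb)
    lengths = np.full(nb, base)
    lengths[:rem] += 1  # longer bins first, lengths differ by at most one
    bounds = np.concatenate(([0], np.cumsum(lengths)))[:-1]
    sums = np.add.reduceat(x, bounds)
    sumsq = np.add.reduceat(x * x, bounds)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (sumsq - sums**2 / lengths) / (lengths - 1)
        out = np.sqrt(np.maximum(var, 0.0))
    out[lengths < 2] = np.nan  # a single sample has no defined variability
    return out


def _longest_true_run(mask: np.ndarray) -> int:
    best = run = 0
    for q in mask:
        run = run + 1 if q else 0
        if run > best:
            best = run
    return best


def classify_delay(bin_sds: np.ndarray, params: DelayParams | None = None,
                   event_id: str | int = "") -> DelayCall:
    """Apply the quiet-run rule: delayed iff SD < threshold for > min_run_bins bins.

    Both comparisons are strict; NaN bin SDs never count as quiet.
    """
    params = params or DelayParams()
    sds = np.asarray(bin_sds, dtype=float)
    quiet = sds < params.sd_threshold  # NaN compares False
    run = _longest_true_run(quiet)
    return DelayCall(
        event_id=event_id,
        bin_sds=sds,
        longest_quiet_run=int(run),
        delayed=run > params.min_run_bins,
    )


def _sliding_call(norm_samples: np.ndarray, params: DelayParams, event_id) -> DelayCall:
    x = np.asarray(norm_samples, dtype=float)
    if x.size < params.n_bins:
        raise UndersampledEventError(
            f"event has {x.size} samples, fewer than n_bins={params.n_bins}"
        )
    w = max(2, x.size // params.n_bins)
    sds = pd.Series(x).rolling(w).std(ddof=1).to_numpy()[w - 1:]
    quiet = sds < params.sd_threshold
    run_samples = _longest_true_run(quiet)
    run_bins = int(run_samples / w) if run_samples else 0
    # report bin-scale SDs for inspection: stride the moving SD at bin width
    return DelayCall(
        event_id=event_id,
        bin_sds=sds[::w][: params.n_bins],
        longest_quiet_run=run_bins,
        delayed=run_bins > params.min_run_bins,
    )


def call_event(norm_samples: np.ndarray, params: DelayParams | None = None,
               event_id: str | int = "") -> DelayCall:
    """Bin (or slide) and classify one event in a single call."""
    params = params or DelayParams()
    if params.mode == "sliding":
        return _sliding_call(norm_samples, params, event_id)
    return classify_delay(bin_event(norm_samples, params), params, event_id)


def percent_delayed(calls: Sequence[DelayCall]) -> float:
    """Percentage of events classified as delayed."""
    if not calls:
        raise ValueError("percent_delayed of an empty call list is undefined")
    return 100.0 * sum(c.delayed for c in calls) / len(calls)


def welch_t_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    tail: str = "two",
    group_a: str = "a",
    group_b: str = "b",
) -> GroupComparison:
    """Welch's unequal-variance t-test between two replicate sets.

    ``tail="one"`` tests for an increase in ``sample_b`` over ``sample_a``;
    ``tail="two"`` is two-sided.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("both samples have zero variance; t is undefined")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    alternative = "less" if tail == "one" else "two-sided"
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return GroupComparison(
        group_a=group_a, group_b=group_b,
        values_a=list(a), values_b=list(b),
        t=float(res.statistic), p=float(res.pvalue), tail=tail,
    )


def calls_to_frame(calls: Sequence[DelayCall], probe_ids: Sequence[str] | None = None) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": [c.event_id for c in calls],
            "probe_id": probe_ids if probe_ids is not None else [""] * len(calls),
            "longest_quiet_run": [c.longest_quiet_run for c in calls],
            "delayed": [int(c.delayed) for c in calls],
        }
    )


def write_delay_calls_tsv(calls: Sequence[DelayCall], path: str | Path,
                          probe_ids: Sequence[str] | None = None) -> None:
    calls_to_frame(calls, probe_ids).to_csv(path, sep="\t", index=False)


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group_a": [c.group_a for c in comparisons],
            "group_b": [c.group_b for c in comparisons],
            "t": [round(c.t, 6) for c in comparisons],
            "p": [c.p for c in comparisons],
            "tail": [c.tail for c in comparisons],
        }
    )


def write_comparisons_tsv(comparisons: Sequence[GroupComparison], path: str | Path) -> None:
    comparisons_to_frame(comparisons).to_csv(path, sep="\t", index=False)
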