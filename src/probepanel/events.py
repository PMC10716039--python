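"""Event identification in raw current traces.

A translocation event is a maximal run of samples deviating below the
tracked open-pore baseline by more than ``k_sigma`` noise standard
deviations. The baseline is a windowed median interpolated across the trace
and re-estimated once with detected events masked, so blockades occupying a
minority of the trace do not drag it down; the noise scale is a scaled
median absolute deviation for the same reason. Runs closer than
``min_event_separation_s`` are merged, and merged runs shorter than
``min_duration_s`` (default 100 ms) are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterRangeWarning

_MAD_TO_SD = 1.4826  # consistency factor for Gaussian noise


@dataclass
class RawTrace:
    """A sampled current trace in pA with acquisition metadata."""

    samples: np.ndarray
    sample_rate: float
    trace_id: str = "trace"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass
class Event:
    """One detected blockade event with raw and open-pore-normalized samples."""

    trace_id: str
    event_id: int
    start_sample: int
    end_sample: int  # half-open
    sample_rate: float
    raw_samples: np.ndarray
    norm_samples: np.ndarray
    mean_blockade_frac: float  # mean residual current as a fraction of open pore

    @property
    def duration_s(self) -> float:
        return (self.end_sample - self.start_sample) / self.sample_rate


@dataclass
class DetectionParams:
    """Event-detection knobs.

    ``k_sigma`` is the cutoff in noise standard deviations below baseline;
    values outside the recommended 30-40 band warn but are honoured.
    """

    k_sigma: float = 35.0
    baseline_window_s: float = 1.0
    min_duration_s: float = 0.1
    min_event_separation_s: float = 0.001

    def __post_init__(self):
        if self.min_duration_s <= 0:
            raise ValueError("min_duration_s must be > 0")
        if self.baseline_window_s <= 0 or self.min_event_separation_s < 0:
            raise ValueError("baseline_window_s must be > 0 and separation >= 0")
        if not (30 <= self.k_sigma <= 40):
            warnings.warn(
                f"k_sigma={self.k_sigma} is outside the recommended 30-40 range",
                ParameterRangeWarning,
                stacklevel=2,
            )


def track_baseline(
    trace: RawTrace,
    params: DetectionParams | None = None,
    exclude_mask: np.ndarray | None = None,
    upper_percentile: float | None = None,
    reference_level: float | None = None,
    reference_tol_frac: float = 0.1,
) -> tuple[np.ndarray, float]:
    """Track the open-pore baseline and estimate the noise SD.

    The trace is cut into windows of ``baseline_window_s``; each window
    contributes its median (of non-excluded samples), and the per-sample
    baseline is the linear interpolation through the window centres. The
    noise SD is ``1.4826 * MAD`` of the baseline-subtracted, non-excluded
    samples. ``upper_percentile`` replaces the per-window median with a
    higher quantile — since blockades only lower the current, this stays on
    the open-pore level even when events occupy much of a window, and is
    used for the first pass before events are masked. ``reference_level``
    guards against windows so occupied by blockades that even a high
    quantile lands mid-event: window estimates deviating from it by more
    than ``reference_tol_frac`` (relative) are discarded and interpolated
    from their neighbours. By default the reference is the trace-wide 97th
    percentile, which sits on the open-pore level because blockades only
    lower the current; pass ``reference_level=0`` to disable gating (e.g.
    for traces with more than ~10% slow drift).
    Returns ``(baseline, noise_sd)``.
    """
    params = params or DetectionParams()
    x = trace.samples
    n = len(x)
    w = int(round(params.baseline_window_s * trace.sample_rate))
    if n < w:
        raise ValueError(
            f"trace ({n} samples) is shorter than the baseline window ({w} samples)"
        )
    masked = x.astype(float).copy()
    if exclude_mask is not None:
        masked[np.asarray(exclude_mask, dtype=bool)] = np.nan
    q = 50.0 if upper_percentile is None else float(upper_percentile)

    n_win = n // w
    core = masked[: n_win * w].reshape(n_win, w)
    med = _window_percentile(core, q)
    tail = masked[n_win * w:]
    centers = (np.arange(n_win) + 0.5) * w
    if tail.size:
        med = np.append(med, _window_percentile(tail.reshape(1, -1), q))
        centers = np.append(centers, n_win * w + tail.size / 2.0)
    if reference_level is None:
        reference_level = float(np.percentile(x, 97.0))
    if reference_level:
        tol = reference_tol_frac * abs(reference_level)
        med[np.abs(med - reference_level) > tol] = np.nan
    good = np.isfinite(med)
    if not good.any():
        raise ValueError("no usable samples to estimate a baseline")
    baseline = np.interp(np.arange(n), centers[good], med[good])

    resid = masked - baseline
    resid = resid[np.isfinite(resid)]
    if resid.size > 400_000:  # MAD converges long before this; subsample
        resid = resid[:: resid.size // 200_000]
    noise_sd = float(_MAD_TO_SD * np.median(np.abs(resid))) if resid.size else 0.0
    return baseline, noise_sd


def _window_percentile(rows: np.ndarray, q: float) -> np.ndarray:
    """Per-row percentile ignoring NaNs (sort-based; NaN rows give NaN).

    Rank-order statistic (no interpolation between order statistics), which
    is all baseline tracking needs and is much faster than nanpercentile.
    """
    n_valid = np.isfinite(rows).sum(axis=1)
    srt = np.sort(np.where(np.isfinite(rows), rows, np.inf), axis=1)
    idx = np.clip((q / 100.0 * (n_valid - 1)).round().astype(int), 0, rows.shape[1] - 1)
    out = srt[np.arange(rows.shape[0]), idx]
    out[n_valid == 0] = np.nan
    return out


def _runs_below(deviation_ok: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, end) intervals."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], deviation_ok, [False])).astype(int)))
    return list(zip(idx[::2], idx[1::2]))


def _merge_runs(runs: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    if not runs:
        return []
    arr = np.asarray(runs)
    s, e = arr[:, 0], arr[:, 1]
    new_run = np.concatenate(([True], (s[1:] - e[:-1]) >= max_gap))
    starts = s[new_run]
    ends = e[np.concatenate((new_run[1:], [True]))]
    return list(zip(starts.tolist(), ends.tolist()))


def _threshold_runs(
    trace: RawTrace, params: DetectionParams, baseline: np.ndarray, noise_sd: float
) -> list[tuple[int, int]]:
    cutoff = params.k_sigma * max(noise_sd, 1e-12)
    below = (baseline - trace.samples) > cutoff  # one-sided: blockades drop the current
    runs = _runs_below(below)
    max_gap = max(1, int(round(params.min_event_separation_s * trace.sample_rate)))
    return _merge_runs(runs, max_gap)


def detect_events_full(
    trace: RawTrace, params: DetectionParams | None = None
) -> tuple[list[Event], list[tuple[int, int]]]:
    """Detect events; also return sub-threshold-duration runs that were excluded.

    Two-pass baseline: a first estimate locates candidate blockades, which are
    masked before the final baseline/noise estimate, keeping both robust even
    when events occupy a sizeable share of the trace.
    """
    params = params or DetectionParams()
    # Iterated estimation: a high-percentile first pass stays on the open-pore
    # level even in heavily blocked windows; subsequent passes mask detected
    # blockades (union over passes) and use the masked median.
    mask = np.zeros(len(trace.samples), dtype=bool)
    # Global open-pore reference: blockades only lower the current, so a high
    # trace-wide quantile sits on the open-pore level; it gates out baseline
    # windows that are almost entirely blocked by an event cluster.
    ref = float(np.percentile(trace.samples, 97.0))
    baseline, noise_sd = track_baseline(
        trace, params, upper_percentile=90.0, reference_level=ref
    )
    pad = max(2, int(round(0.005 * trace.sample_rate)))
    bridge = max(1, int(round(params.min_duration_s * trace.sample_rate)))
    n_masked = 0
    for _ in range(2):
        runs = _threshold_runs(trace, params, baseline, noise_sd)
        # For baseline estimation only: bridge fragmented in-event runs and pad
        # their edges, so partially sub-threshold blockades are fully masked.
        for s, e in _merge_runs(runs, bridge):
            mask[max(0, s - pad): e + pad] = True
        new_masked = int(mask.sum())
        if new_masked == 0 or new_masked == n_masked:  # converged
            break
        n_masked = new_masked
        baseline, noise_sd = track_baseline(
            trace, params, exclude_mask=mask, reference_level=ref
        )
    runs = _threshold_runs(trace, params, baseline, noise_sd)

    min_samples = params.min_duration_s * trace.sample_rate
    events: list[Event] = []
    excluded: list[tuple[int, int]] = []
    for s, e in runs:
        if e - s < min_samples:  # strictly shorter than the floor is dropped
            excluded.append((s, e))
            continue
        raw = trace.samples[s:e]
        open_pore_est = float(np.mean(baseline[s:e]))
        norm = normalize_event(raw, open_pore_est)
        events.append(
            Event(
                trace_id=trace.trace_id,
                event_id=len(events),
                start_sample=int(s),
                end_sample=int(e),
                sample_rate=trace.sample_rate,
                raw_samples=raw,
                norm_samples=norm,
                mean_blockade_frac=float(np.mean(norm)),
            )
        )
    return events, excluded


def detect_events(trace: RawTrace, params: DetectionParams | None = None) -> list[Event]:
    """Detected events, sorted by start and non-overlapping (see detect_events_full)."""
    return detect_events_full(trace, params)[0]


def normalize_event(event_raw: np.ndarray, open_pore_est: float) -> np.ndarray:
    """Express event samples as a fraction of the open-pore current."""
    if open_pore_est <= 0:
        raise ValueError("open_pore_est must be > 0")
    return np.asarray(event_raw, dtype=float) / float(open_pore_est)


# ---------------------------------------------------------------------------
# Plain-text signal container and event tables

def write_trace(trace: RawTrace, path: str | Path) -> None:
    """Write the plain-text signal container: '#key=value' header, one pA sample per line."""
    with open(path, "w") as fh:
        meta = dict(trace.metadata)
        meta.setdefault("sample_rate_hz", trace.sample_rate)
        meta.setdefault("trace_id", trace.trace_id)
        for k, v in meta.items():
            fh.write(f"#{k}={v}\n")
        np.savetxt(fh, trace.samples, fmt="%.4f")


def read_trace(path: str | Path) -> RawTrace:
    meta: dict = {}
    samples: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                k, _, v = line[1:].partition("=")
                meta[k.strip()] = v.strip()
            else:
                samples.append(float(line))
    sr = float(meta.get("sample_rate_hz", 0) or 0)
    if sr <= 0:
        raise ValueError(f"{path}: missing or invalid sample_rate_hz header")
    trace_id = meta.get("trace_id") or Path(path).stem
    return RawTrace(samples=np.array(samples), sample_rate=sr, trace_id=trace_id, metadata=meta)


def events_to_frame(events: list[Event]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trace_id": [e.trace_id for e in events],
            "event_id": [e.event_id for e in events],
            "start_sample": [e.start_sample for e in events],
            "end_sample": [e.end_sample for e in events],
            "duration_s": [round(e.duration_s, 6) for e in events],
            "mean_blockade_frac": [round(e.mean_blockade_frac, 6) for e in events],
        }
    )


def write_events_tsv(events: list[Event], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, sep="\t", index=False)
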