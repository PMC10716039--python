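"""Self-contained evaluation studies on synthetic data.

Each study generates its own labeled data with the simulator, runs the
relevant pipeline stages, and measures performance against ground truth.
They are the package's reproducible benchmarks: the delay-classifier
operating characteristics, the event filter's recall and short-event
rejection, and the full blinded quantification exercise (simulate ->
detect -> demux -> delay -> fit -> predict).

Problem sizes default to what gives stable statistics on a single CPU in a
few minutes; every study is deterministic in its seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import derive_rng
from .delay import DelayParams, call_event
from .demux import CascadeThresholds
from .events import DetectionParams, detect_events
from .library import generate_barcode_library
from .pipeline import analyze_trace, percent_delay_table
from .quantify import fit_hill, predict_concentrations
from .simulate import SimulationParams, simulate_basecalls, simulate_events, simulate_trace


def delay_classifier_study(
    seed: int,
    n_events: int = 10_000,
    p_delayed: float = 0.5,
    params: SimulationParams | None = None,
    delay_params: DelayParams | None = None,
) -> dict:
    """Sensitivity/specificity of the quiet-run rule on labeled synthetic events."""
    params = params or SimulationParams(seed=seed)
    events = simulate_events(n_events, p_delayed, params, seed_tokens=("delay-study",))
    tp = fp = fn = tn = 0
    for norm, is_delayed, _ in events:
        call = call_event(norm, delay_params)
        if call.delayed and is_delayed:
            tp += 1
        elif call.delayed:
            fp += 1
        elif is_delayed:
            fn += 1
        else:
            tn += 1
    return {
        "n_events": n_events,
        "sensitivity_pct": 100.0 * tp / (tp + fn) if tp + fn else float("nan"),
        "specificity_pct": 100.0 * tn / (tn + fp) if tn + fp else float("nan"),
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
    }


def event_filter_study(
    seed: int,
    n_probes: int = 5,
    n_events_per_trace: int = 600,
    n_traces: int = 3,
) -> dict:
    """Recall of long events and rejection of sub-100 ms blockades."""
    library = generate_barcode_library(n_probes, seed=seed)
    det = DetectionParams()
    long_truth = long_found = 0
    short_retained = 0
    n_detected = 0
    for t in range(n_traces):
        params = SimulationParams(seed=seed + 1000 * t, spurious_short_event_rate=0.3)
        trace, truth = simulate_trace(
            library, {}, params, n_events=n_events_per_trace, trace_id=f"filter{t}"
        )
        events = detect_events(trace, det)
        n_detected += len(events)
        short_retained += sum(e.duration_s < 0.1 for e in events)
        det_iv = [(e.start_sample, e.end_sample) for e in events]
        for te in truth.events:
            if te.duration_s(trace.sample_rate) < 0.15:
                continue
            long_truth += 1
            ov = max(
                (min(e, te.end_sample) - max(s, te.start_sample) for s, e in det_iv),
                default=0,
            )
            if ov >= 0.9 * (te.end_sample - te.start_sample):
                long_found += 1
    return {
        "n_truth_long": long_truth,
        "n_detected": n_detected,
        "recall_long_pct": 100.0 * long_found / long_truth,
        "short_events_retained": short_retained,
    }


def blinded_quantification_study(
    seed: int,
    n_probes: int = 40,
    calibration_concs: tuple[float, ...] = (0.0, 0.25, 1.0, 3.0, 10.0, 20.0),
    events_per_probe_calibration: int = 300,
    events_per_probe_blinded: int = 700,
    conc_range: tuple[float, float] = (0.25, 20.0),
) -> pd.DataFrame:
    """The blinded multiplexed quantification exercise, end to end.

    Standard curves are built per probe from multiplexed runs at the
    calibration concentrations (every probe's analyte at the same level per
    run); a final blinded run draws each analyte's concentration
    log-uniformly from ``conc_range`` and predicts it from the observed
    percent delay. Returns one row per probe with predicted, actual and
    their ratio.
    """
    library = generate_barcode_library(n_probes, seed=seed)
    params = SimulationParams(seed=seed)
    det, casc, dly = DetectionParams(), CascadeThresholds(), DelayParams()

    def run_sample(sample_id: str, mix: dict) -> pd.DataFrame:
        trace, truth = simulate_trace(
            library, mix, params, n_events=n_probes * _events_for(sample_id),
            trace_id=sample_id,
        )
        reads = simulate_basecalls(truth, library, params)
        per_event, _, _, _ = analyze_trace(trace, reads, truth, library, det, casc, dly)
        return percent_delay_table(per_event, sample_id)

    def _events_for(sample_id: str) -> int:
        return (events_per_probe_blinded if sample_id == "blinded"
                else events_per_probe_calibration)

    pct_frames = []
    for i, conc in enumerate(calibration_concs):
        sample_id = f"cal{i:02d}"
        mix = {p: conc for p in library.probe_ids}
        df = run_sample(sample_id, mix)
        df["concentration_nM"] = conc
        pct_frames.append(df)
    calibration = pd.concat(pct_frames, ignore_index=True)

    curves = {}
    for probe_id, grp in calibration.groupby("probe_id"):
        curves[probe_id] = fit_hill(
            grp["concentration_nM"].to_numpy(),
            grp["percent_delayed"].to_numpy(),
            probe_id=str(probe_id),
        )

    rng = derive_rng(seed, "blinded-truth")
    lo, hi = np.log10(conc_range[0]), np.log10(conc_range[1])
    actual = {p: float(10 ** rng.uniform(lo, hi)) for p in library.probe_ids}
    blinded_pct = run_sample("blinded", actual)
    obs = blinded_pct.set_index("probe_id")["percent_delayed"].to_dict()
    preds = predict_concentrations(obs, curves, actual)

    rows = []
    for p in preds:
        rows.append(
            {
                "probe_id": p.probe_id,
                "percent_delay": p.observed_percent_delay,
                "predicted_nM": p.predicted_nM,
                "actual_nM": p.actual_nM,
                "ratio": p.ratio,
                "flag": p.flag,
                "n_events": int(
                    blinded_pct.set_index("probe_id").loc[p.probe_id, "n_events"]
                ),
                "Kd_fit": curves[p.probe_id].Kd,
                "R2_fit": curves[p.probe_id].r2,
            }
        )
    return pd.DataFrame(rows)
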