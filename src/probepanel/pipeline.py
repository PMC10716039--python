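"""End-to-end pipeline: detect -> demux -> delay -> quantify.

Two entry points. :func:`analyze_trace` is the in-memory workhorse joining
one trace's detected events to their base-called reads (via ground-truth
intervals, the simulator's stand-in for per-event base calling) and
producing per-event probe assignments and delay calls. :func:`run_pipeline`
is the file-based run driven by a :class:`RunConfig`: it processes every
sample in the design table, writes the stage TSVs, fits standard curves from
samples with known concentrations, predicts the unknowns, and emits a
machine-readable report. Outputs are byte-reproducible for a fixed config.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .delay import DelayParams, call_event, percent_delayed
from .demux import CascadeThresholds, demux, write_demux_tsv
from .errors import ConfigError, FitFailureError, UndersampledEventError
from .events import DetectionParams, detect_events_full, read_trace, write_events_tsv
from .library import read_library
from .quantify import (
    curves_to_frame,
    fit_hill,
    predict_concentrations,
    predictions_to_frame,
)
from .simulate import match_events_to_truth, read_fastq, read_id_for, read_truth


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run (round-trips through YAML)."""

    library_fasta: str
    probes_tsv: str
    signal_dir: str
    reads_dir: str
    truth_dir: str
    design_tsv: str
    out_dir: str
    seed: int = 0
    detection: DetectionParams = field(default_factory=DetectionParams)
    cascade: CascadeThresholds = field(default_factory=CascadeThresholds)
    delay: DelayParams = field(default_factory=DelayParams)
    fix_nH_to_1: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        for key, typ in (("detection", DetectionParams), ("cascade", CascadeThresholds),
                         ("delay", DelayParams)):
            if key in d and isinstance(d[key], Mapping):
                d[key] = typ(**d[key])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class RunReport:
    """Per-stage record counts, parameter echo and wall-clock times."""

    version: str = _pkg_version
    counts: dict = field(default_factory=dict)
    per_probe_delayed: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    wall_clock_s: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


_REQUIRED_PATHS = ("library_fasta", "probes_tsv", "signal_dir", "reads_dir",
                   "truth_dir", "design_tsv")


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config.

    Missing keys take the documented defaults. Raises :class:`ConfigError`
    whose ``errors`` attribute lists every violation found, not just the
    first; unparseable files report the line number from the YAML parser.
    """
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError([f"config syntax error{line}: {exc}"]) from exc
    except OSError as exc:
        raise ConfigError([f"cannot read config: {exc}"]) from exc
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a mapping of keys to values"])

    errors: list[str] = []
    for key in _REQUIRED_PATHS + ("out_dir",):
        if key not in raw:
            errors.append(f"missing required field: {key}")
    base = Path(path).parent
    for key in _REQUIRED_PATHS:
        if key in raw:
            p = base / str(raw[key])
            if not p.exists():
                errors.append(f"{key}: path does not exist: {p}")
            else:
                raw[key] = str(p)
    if "out_dir" in raw:
        raw["out_dir"] = str(base / str(raw["out_dir"]))

    cfg = None
    if not errors:
        try:
            cfg = RunConfig.from_dict(raw)
        except (TypeError, ValueError) as exc:
            errors.append(str(exc))
    if cfg is not None:
        try:
            design = pd.read_csv(cfg.design_tsv, sep="\t")
        except Exception as exc:  # pragma: no cover - malformed design
            errors.append(f"design_tsv unreadable: {exc}")
        else:
            need = {"sample_id", "probe_id", "concentration_nM"}
            if not need.issubset(design.columns):
                errors.append(f"design_tsv must have columns {sorted(need)}")
            elif (pd.to_numeric(design["concentration_nM"], errors="coerce") < 0).any():
                errors.append("design_tsv contains a negative concentration")
    if errors:
        raise ConfigError(errors)
    return cfg


def analyze_trace(
    trace,
    reads,
    truth,
    library,
    detection: DetectionParams | None = None,
    cascade: CascadeThresholds | None = None,
    delay: DelayParams | None = None,
):
    """Detect, demultiplex and delay-classify one trace.

    ``reads`` are the base-called reads for the trace's ground-truth events
    (read ids encode truth event ids). Returns ``(per_event DataFrame,
    exclusions list)`` where each exclusion is ``(record_id, stage, reason)``.
    """
    detection = detection or DetectionParams()
    cascade = cascade or CascadeThresholds()
    delay = delay or DelayParams()

    events, short_runs = detect_events_full(trace, detection)
    exclusions = [
        (f"{trace.trace_id}:run@{s}", "event_detection", "shorter_than_min_duration")
        for s, e in short_runs
    ]
    matching = match_events_to_truth(events, truth)
    reads_by_id = {r.id: r for r in reads}

    matched_events, matched_reads = [], []
    for ev in events:
        tid = matching.get(ev.event_id)
        rid = None if tid is None else read_id_for(truth.trace_id, tid)
        if rid is None or rid not in reads_by_id:
            exclusions.append((f"{trace.trace_id}:event{ev.event_id}", "demux", "no_read"))
            continue
        matched_events.append(ev)
        matched_reads.append(reads_by_id[rid])

    assignments = demux(matched_reads, library, cascade)

    rows = []
    for ev, asn in zip(matched_events, assignments):
        if asn.probe_id is None:
            exclusions.append((asn.read_id, "demux", "cascade_fail"))
            continue
        try:
            call = call_event(ev.norm_samples, delay, event_id=ev.event_id)
        except UndersampledEventError:
            exclusions.append((asn.read_id, "delay", "undersampled_event"))
            continue
        rows.append(
            {
                "trace_id": trace.trace_id,
                "event_id": ev.event_id,
                "read_id": asn.read_id,
                "probe_id": asn.probe_id,
                "duration_s": round(ev.duration_s, 6),
                "longest_quiet_run": call.longest_quiet_run,
                "delayed": int(call.delayed),
            }
        )
    cols = ["trace_id", "event_id", "read_id", "probe_id", "duration_s",
            "longest_quiet_run", "delayed"]
    return pd.DataFrame(rows, columns=cols), exclusions, events, assignments


def percent_delay_table(per_event: pd.DataFrame, sample_id: str) -> pd.DataFrame:
    """Per-probe percent-delayed summary of one sample's event table."""
    if per_event.empty:
        return pd.DataFrame(columns=["probe_id", "replicate", "percent_delayed", "n_events"])
    g = per_event.groupby("probe_id")["delayed"]
    out = pd.DataFrame(
        {
            "probe_id": g.mean().index,
            "replicate": sample_id,
            "percent_delayed": (100.0 * g.mean()).round(6).to_numpy(),
            "n_events": g.size().to_numpy(),
        }
    )
    return out.reset_index(drop=True)


def run_pipeline(config: RunConfig, force: bool = False) -> RunReport:
    """Execute the full pipeline described by ``config``.

    Samples come from the design table; per sample the pipeline expects
    ``<signal_dir>/<sample_id>.trace.txt``, ``<reads_dir>/<sample_id>.fastq``
    and ``<truth_dir>/<sample_id>.truth.tsv``. Samples with known
    concentrations feed the per-probe standard-curve fits; samples with a
    blank concentration are treated as blinded and predicted. Refuses to
    overwrite an existing output directory unless ``force`` is set.
    """
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise ConfigError(
            [f"output directory {out} is not empty; pass force=True (--force) to overwrite"]
        )
    out.mkdir(parents=True, exist_ok=True)

    report = RunReport(parameters={
        "detection": asdict(config.detection),
        "cascade": asdict(config.cascade),
        "delay": asdict(config.delay),
        "seed": config.seed,
        "fix_nH_to_1": config.fix_nH_to_1,
    })
    t_start = time.perf_counter()

    library = read_library(config.library_fasta, config.probes_tsv)
    design = pd.read_csv(config.design_tsv, sep="\t")
    sample_ids = sorted(design["sample_id"].astype(str).unique())

    all_events, all_demux, per_event_frames, pd_frames, exclusions = [], [], [], [], []
    for sample_id in sample_ids:
        trace = read_trace(Path(config.signal_dir) / f"{sample_id}.trace.txt")
        reads = read_fastq(Path(config.reads_dir) / f"{sample_id}.fastq")
        truth = read_truth(Path(config.truth_dir) / f"{sample_id}.truth.tsv")
        per_event, excl, events, assignments = analyze_trace(
            trace, reads, truth, library, config.detection, config.cascade, config.delay
        )
        per_event_frames.append(per_event)
        pd_frames.append(percent_delay_table(per_event, sample_id))
        exclusions.extend(excl)
        all_events.extend(events)
        all_demux.extend(assignments)
        report.counts.setdefault("events_kept", 0)
        report.counts["events_kept"] += len(events)
        report.counts.setdefault("reads", 0)
        report.counts["reads"] += len(reads)
    report.wall_clock_s["detect_demux_delay"] = round(time.perf_counter() - t_start, 3)

    write_events_tsv(all_events, out / "events.tsv")
    write_demux_tsv(all_demux, out / "demux.tsv")
    per_event_all = pd.concat(per_event_frames, ignore_index=True)
    per_event_all.to_csv(out / "delay_calls.tsv", sep="\t", index=False)
    pct = pd.concat(pd_frames, ignore_index=True)
    pct.to_csv(out / "percent_delay.tsv", sep="\t", index=False)
    pd.DataFrame(exclusions, columns=["record_id", "stage", "reason"]).to_csv(
        out / "exclusions.tsv", sep="\t", index=False
    )
    report.counts["assigned_events"] = int(len(per_event_all))
    report.counts["unassigned_or_excluded"] = len(exclusions)
    report.counts["delayed_events"] = int(per_event_all["delayed"].sum())
    report.per_probe_delayed = {
        pid: int(n) for pid, n in
        per_event_all.groupby("probe_id")["delayed"].sum().items()
    }

    # quantification: calibration samples -> curves; blinded samples -> predictions
    t_q = time.perf_counter()
    design["concentration_nM"] = pd.to_numeric(design["concentration_nM"], errors="coerce")
    known = design.dropna(subset=["concentration_nM"])
    merged = pct.merge(known, left_on=["probe_id", "replicate"],
                       right_on=["probe_id", "sample_id"], how="inner")
    curves = {}
    for probe_id, grp in merged.groupby("probe_id"):
        if grp["concentration_nM"].nunique() < 3:
            continue
        try:
            curves[probe_id] = fit_hill(
                grp["concentration_nM"].to_numpy(),
                grp["percent_delayed"].to_numpy(),
                fix_nH_to_1=config.fix_nH_to_1,
                probe_id=str(probe_id),
            )
        except (FitFailureError, ValueError) as exc:
            exclusions.append((str(probe_id), "quantify", f"fit_failed:{exc}"))
    if curves:
        curves_to_frame(curves).to_csv(out / "curves.tsv", sep="\t", index=False)

    blinded_samples = design[design["concentration_nM"].isna()]["sample_id"].astype(str).unique()
    pred_frames = []
    for sample_id in blinded_samples:
        obs = pct[pct["replicate"] == sample_id].set_index("probe_id")["percent_delayed"]
        preds = predict_concentrations(obs.to_dict(), curves)
        df = predictions_to_frame(preds)
        df.insert(0, "sample_id", sample_id)
        pred_frames.append(df)
    if pred_frames:
        pd.concat(pred_frames, ignore_index=True).to_csv(
            out / "predictions.tsv", sep="\t", index=False
        )
    report.counts["curves_fitted"] = len(curves)
    report.counts["blinded_samples"] = int(len(blinded_samples))
    report.wall_clock_s["quantify"] = round(time.perf_counter() - t_q, 3)
    report.wall_clock_s["total"] = round(time.perf_counter() - t_start, 3)

    with open(out / "report.json", "w") as fh:
        fh.write(report.to_json())
    return report
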