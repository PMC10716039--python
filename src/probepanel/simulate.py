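"""Synthetic nanopore data with ground truth.

Emulates the measurement chain of the barcoded-probe platform well enough to
test every downstream stage: an open-pore baseline with Gaussian noise,
square blockade events at Poisson-spaced arrivals, low-variance "delay"
sojourns inside a fraction of the events (the signature of a bound analyte
stalling translocation), sub-100 ms spurious blockades, and base-called
reads whose substitution rate grows from the 5' to the 3' end of the
barcode.

The probability that an event is delayed follows first-order binding
occupancy (a Hill curve with coefficient 1): for a probe whose analyte is at
concentration C,

    p_delay = (B0 + Vmax * C / (Kd + C)) / 100.

Every draw derives from one master seed via stable per-trace / per-read
substreams, so outputs are bit-reproducible and insensitive to the presence
of unrelated traces or probes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._rng import derive_rng
from .library import BarcodeLibrary
from .errors import ProbePanelError

_DNA = "ACGT"


@dataclass
class SimulationParams:
    """Tunable knobs of the synthetic signal, occupancy and basecall models.

    Current levels are in pA, durations in ms, rates per second of open-pore
    time, concentrations in nM. ``delay_sd_frac`` is the standard deviation
    of the normalized (fraction-of-open-pore) signal inside a delay sojourn
    and must stay below the 0.003 classification threshold for simulated
    delays to be detectable.
    """

    open_pore_pA: float = 220.0
    noise_sd_pA: float = 1.5
    sample_rate_Hz: int = 1000
    event_rate_per_s: float = 2.0
    mean_event_ms: float = 300.0
    sd_event_ms: float = 60.0
    min_event_ms: float = 160.0
    blockade_frac: float = 0.30
    blockade_frac_sd: float = 0.02
    delay_sd_frac: float = 0.001
    delay_min_frac: float = 0.20
    delay_max_frac: float = 0.60
    spurious_short_event_rate: float = 0.1
    Kd_nM: float = 1.09
    Vmax_pct: float = 38.69
    B0_pct: float = 12.32
    per_probe: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    basecall_sub_rate_5p: float = 0.01
    basecall_sub_rate_3p: float = 0.15
    indel_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.open_pore_pA <= 0 or self.noise_sd_pA < 0:
            raise ValueError("open_pore_pA must be > 0 and noise_sd_pA >= 0")
        if int(self.sample_rate_Hz) <= 0:
            raise ValueError("sample_rate_Hz must be a positive integer")
        for name in ("event_rate_per_s", "spurious_short_event_rate", "indel_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mean_event_ms <= 0 or self.sd_event_ms < 0 or self.min_event_ms <= 0:
            raise ValueError("event duration parameters must be positive")
        if not (0 < self.blockade_frac < 1):
            raise ValueError("blockade_frac must be in (0, 1)")
        if not (0 <= self.delay_sd_frac < 0.003):
            raise ValueError(
                "delay_sd_frac must be in [0, 0.003): simulated sojourns must sit "
                "below the delay-classification threshold"
            )
        if not (0 < self.delay_min_frac <= self.delay_max_frac <= 0.8):
            raise ValueError("delay sojourn fractions must satisfy 0 < min <= max <= 0.8")
        for probe_id, (kd, vmax, b0) in self._occupancy_items():
            if kd <= 0:
                raise ValueError(f"Kd_nM must be > 0 (probe {probe_id})")
            if not (0 <= vmax + b0 <= 100) or vmax < 0 or b0 < 0:
                raise ValueError(
                    f"occupancy must satisfy 0 <= Vmax_pct + B0_pct <= 100 (probe {probe_id})"
                )
        for name in ("basecall_sub_rate_5p", "basecall_sub_rate_3p"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")

    def _occupancy_items(self):
        yield "<default>", (self.Kd_nM, self.Vmax_pct, self.B0_pct)
        for pid, triple in self.per_probe.items():
            yield pid, triple

    def occupancy(self, probe_id: str) -> tuple[float, float, float]:
        """(Kd_nM, Vmax_pct, B0_pct) for a probe, falling back to the defaults."""
        return self.per_probe.get(probe_id, (self.Kd_nM, self.Vmax_pct, self.B0_pct))


def delay_probability(conc_nM: float, Kd_nM: float, Vmax_pct: float, B0_pct: float) -> float:
    """Per-event probability of a delay under first-order binding occupancy."""
    if conc_nM < 0:
        raise ValueError("concentration must be >= 0")
    return (B0_pct + Vmax_pct * conc_nM / (Kd_nM + conc_nM)) / 100.0


@dataclass
class TruthEvent:
    """Ground truth for one injected blockade event."""

    event_id: int
    probe_id: str  # "" for spurious (non-probe) blockades
    start_sample: int
    end_sample: int  # half-open
    is_delayed: bool
    delay_start_sample: int | None = None
    delay_end_sample: int | None = None

    def duration_s(self, sample_rate: float) -> float:
        return (self.end_sample - self.start_sample) / sample_rate

    @property
    def is_spurious(self) -> bool:
        return self.probe_id == ""

    def delay_bins(self, n_bins: int = 75) -> tuple[int, int] | None:
        """Bin-index interval of the sojourn when the event is split into n_bins."""
        if not self.is_delayed:
            return None
        n = self.end_sample - self.start_sample
        b0 = int((self.delay_start_sample - self.start_sample) / n * n_bins)
        b1 = int(math.ceil((self.delay_end_sample - self.start_sample) / n * n_bins))
        return b0, min(b1, n_bins)


@dataclass
class GroundTruth:
    trace_id: str
    events: list[TruthEvent] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def n_delayed(self) -> int:
        return sum(e.is_delayed for e in self.events)

    def by_id(self) -> dict[int, TruthEvent]:
        return {e.event_id: e for e in self.events}


def read_id_for(trace_id: str, event_id: int) -> str:
    return f"{trace_id}:ev{event_id:06d}"


def parse_read_id(read_id: str) -> tuple[str, int]:
    trace_id, _, ev = read_id.rpartition(":ev")
    return trace_id, int(ev)


# ---------------------------------------------------------------------------
# Signal synthesis


def _event_samples(
    n: int,
    level_pA: float,
    noise_sd_pA: float,
    delay: tuple[int, int] | None,
    delay_sd_pA: float,
    rng: np.random.Generator,
) -> np.ndarray:
    x = rng.normal(level_pA, noise_sd_pA, size=n)
    if delay is not None:
        d0, d1 = delay
        x[d0:d1] = rng.normal(level_pA, delay_sd_pA, size=d1 - d0)
    return x


def _draw_duration_samples(params: SimulationParams, rng: np.random.Generator) -> int:
    ms = max(params.min_event_ms, rng.normal(params.mean_event_ms, params.sd_event_ms))
    return max(2, int(round(ms / 1000.0 * params.sample_rate_Hz)))


def _draw_delay_window(n: int, params: SimulationParams, rng: np.random.Generator):
    frac = rng.uniform(params.delay_min_frac, params.delay_max_frac)
    start_frac = rng.uniform(0.1, max(0.1, 0.9 - frac))
    d0 = int(start_frac * n)
    d1 = min(n, d0 + max(1, int(frac * n)))
    return d0, d1


def simulate_events(
    n_events: int,
    p_delayed: float,
    params: SimulationParams,
    seed_tokens: Sequence[str] = ("events",),
) -> list[tuple[np.ndarray, bool, tuple[int, int] | None]]:
    """Standalone normalized event signals with truth labels.

    Returns ``(norm_samples, is_delayed, delay_window)`` triples; useful for
    exercising the delay classifier without synthesizing whole traces.
    """
    if not (0 <= p_delayed <= 1):
        raise ValueError("p_delayed must be in [0, 1]")
    rng = derive_rng(params.seed, *seed_tokens)
    out = []
    for _ in range(n_events):
        n = _draw_duration_samples(params, rng)
        level = params.open_pore_pA * float(
            np.clip(rng.normal(params.blockade_frac, params.blockade_frac_sd), 0.05, 0.8)
        )
        delayed = bool(rng.random() < p_delayed)
        window = _draw_delay_window(n, params, rng) if delayed else None
        raw = _event_samples(
            n, level, params.noise_sd_pA, window,
            params.delay_sd_frac * params.open_pore_pA, rng,
        )
        out.append((raw / params.open_pore_pA, delayed, window))
    return out


def simulate_trace(
    library: BarcodeLibrary,
    mix: Mapping[str, float],
    params: SimulationParams,
    n_events: int | None = None,
    duration_s: float | None = None,
    trace_id: str = "trace",
):
    """Synthesize one raw current trace plus its ground truth.

    Blockade events arrive as a Poisson process during open-pore time; each
    non-spurious event carries a probe drawn uniformly from the library and
    is delayed with the occupancy probability for that probe's analyte
    concentration in ``mix`` (absent probes are at 0 nM). Spurious sub-100 ms
    blockades are superposed at ``spurious_short_event_rate`` and carry no
    probe. Exactly one of ``n_events`` (count of non-spurious events) or
    ``duration_s`` must be given.

    Returns ``(RawTrace, GroundTruth)``.
    """
    from .events import RawTrace  # local import to avoid a cycle

    if len(library) == 0:
        raise ValueError("library must be nonempty")
    unknown = set(mix) - set(library.probe_ids)
    if unknown:
        raise ValueError(f"mix contains unknown probe ids: {sorted(unknown)}")
    for pid, c in mix.items():
        if c < 0:
            raise ValueError(f"negative concentration for {pid}")
    if (n_events is None) == (duration_s is None):
        raise ValueError("give exactly one of n_events or duration_s")

    rng = derive_rng(params.seed, "trace", trace_id)
    sr = int(params.sample_rate_Hz)
    rate_real = params.event_rate_per_s
    rate_sp = params.spurious_short_event_rate
    rate_tot = rate_real + rate_sp
    if rate_tot <= 0:
        raise ValueError("total event rate must be > 0")
    probe_ids = list(library.probe_ids)
    p_delay = {
        pid: delay_probability(float(mix.get(pid, 0.0)), *params.occupancy(pid))
        for pid in probe_ids
    }

    segments: list[np.ndarray] = []
    truth = GroundTruth(trace_id=trace_id)
    cursor = 0
    n_real = 0
    target_samples = None if duration_s is None else int(round(duration_s * sr))

    def gap(n: int) -> None:
        nonlocal cursor
        if n > 0:
            segments.append(rng.normal(params.open_pore_pA, params.noise_sd_pA, size=n))
            cursor += n

    while True:
        gap_n = max(1, int(round(rng.exponential(1.0 / rate_tot) * sr)))
        if target_samples is not None and cursor + gap_n >= target_samples:
            gap(target_samples - cursor)
            break
        gap(gap_n)
        spurious = rng.random() < rate_sp / rate_tot
        if spurious:
            dur_ms = rng.uniform(50.0, 99.0)
            n = max(2, int(round(dur_ms / 1000.0 * sr)))
            delayed, window, probe_id = False, None, ""
        else:
            n = _draw_duration_samples(params, rng)
            probe_id = probe_ids[int(rng.integers(len(probe_ids)))]
            delayed = bool(rng.random() < p_delay[probe_id])
            window = _draw_delay_window(n, params, rng) if delayed else None
        if target_samples is not None and cursor + n + 1 > target_samples:
            gap(target_samples - cursor)
            break
        level = params.open_pore_pA * float(
            np.clip(rng.normal(params.blockade_frac, params.blockade_frac_sd), 0.05, 0.8)
        )
        seg = _event_samples(
            n, level, params.noise_sd_pA, window,
            params.delay_sd_frac * params.open_pore_pA, rng,
        )
        truth.events.append(
            TruthEvent(
                event_id=len(truth.events),
                probe_id=probe_id,
                start_sample=cursor,
                end_sample=cursor + n,
                is_delayed=delayed,
                delay_start_sample=None if window is None else cursor + window[0],
                delay_end_sample=None if window is None else cursor + window[1],
            )
        )
        segments.append(seg)
        cursor += n
        if not spurious:
            n_real += 1
            if n_events is not None and n_real >= n_events:
                gap(max(1, int(round(rng.exponential(1.0 / rate_tot) * sr))))
                break

    samples = np.concatenate(segments) if segments else np.empty(0)
    trace = RawTrace(
        samples=samples,
        sample_rate=sr,
        trace_id=trace_id,
        metadata={
            "sample_rate_hz": sr,
            "open_pore_pa": params.open_pore_pA,
            "seed": params.seed,
        },
    )
    return trace, truth


# ---------------------------------------------------------------------------
# Base-called reads


def _sub_rates(length: int, r5: float, r3: float) -> np.ndarray:
    if length == 1:
        return np.array([r5])
    pos = np.arange(length) / (length - 1)
    return r5 + (r3 - r5) * pos


def _quality(rate: float) -> int:
    return int(np.clip(round(-10 * math.log10(max(rate, 1e-4))), 2, 40))


def simulate_basecalls(
    truth: GroundTruth,
    library: BarcodeLibrary,
    params: SimulationParams,
) -> list[SeqRecord]:
    """One base-called read per ground-truth event (FASTQ-ready records).

    Probe events yield the probe's barcode passed through a position-dependent
    substitution channel — the rate interpolates linearly from
    ``basecall_sub_rate_5p`` at the first base to ``basecall_sub_rate_3p`` at
    the last — plus symmetric insertions/deletions at ``indel_rate``.
    Spurious blockades yield uniform-random sequence of barcode length.
    Read ids encode the trace and event id for truth joining.
    """
    if len(truth) == 0:
        raise ValueError("truth must contain at least one event")
    barcode_len = len(library.records[0].barcode_seq) if len(library) else 35
    half_indel = params.indel_rate / 2.0
    # per-probe/-length caches: encoded templates, error profiles, qualities
    codes_cache = {
        r.probe_id: np.frombuffer(r.barcode_seq.encode(), dtype=np.uint8)
        for r in library
    }
    base_for = {ord(b): b for b in _DNA}
    sub_map = {ord(b): _DNA.replace(b, "") for b in _DNA}
    rates_cache: dict[int, np.ndarray] = {}
    quals_cache: dict[int, list[int]] = {}

    def profile(length: int):
        if length not in rates_cache:
            rates_cache[length] = _sub_rates(
                length, params.basecall_sub_rate_5p, params.basecall_sub_rate_3p
            )
            quals_cache[length] = [_quality(r) for r in rates_cache[length]]
        return rates_cache[length], quals_cache[length]

    reads: list[SeqRecord] = []
    for ev in truth.events:
        rng = derive_rng(params.seed, "read", truth.trace_id, str(ev.event_id))
        if ev.is_spurious:
            seq = "".join(_DNA[i] for i in rng.integers(0, 4, size=barcode_len))
            quals = [_quality(0.25)] * len(seq)
        else:
            codes = codes_cache[ev.probe_id]
            L = len(codes)
            rates, base_quals = profile(L)
            sub_here = rng.random(L) < rates
            sub_pick = rng.integers(0, 3, size=L)
            if half_indel > 0:
                ins_here = rng.random(L) < half_indel
                del_here = rng.random(L) < half_indel
                any_indel = bool(ins_here.any() or del_here.any())
            else:
                any_indel = False
            if not any_indel:
                bases = [
                    sub_map[c][p] if s else base_for[c]
                    for c, s, p in zip(codes.tolist(), sub_here.tolist(), sub_pick.tolist())
                ]
                quals = list(base_quals)
            else:
                ins_base = rng.integers(0, 4, size=L)
                bases, quals = [], []
                for i, c in enumerate(codes.tolist()):
                    if ins_here[i]:
                        bases.append(_DNA[ins_base[i]])
                        quals.append(7)
                    if del_here[i]:
                        continue
                    bases.append(sub_map[c][sub_pick[i]] if sub_here[i] else base_for[c])
                    quals.append(base_quals[i])
                if not bases:  # pathological all-deleted read; keep conservation
                    bases, quals = ["N"], [2]
            seq = "".join(bases)
        rec = SeqRecord(Seq(seq), id=read_id_for(truth.trace_id, ev.event_id), description="")
        rec.letter_annotations["phred_quality"] = quals
        reads.append(rec)
    return reads


def write_fastq(reads: Sequence[SeqRecord], path: str | Path) -> None:
    SeqIO.write(list(reads), str(path), "fastq")


def read_fastq(path: str | Path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fastq"))


# ---------------------------------------------------------------------------
# Ground-truth TSV round-trip (plumbing for the file-based pipeline)

_TRUTH_COLS = [
    "event_id", "probe_id", "start_sample", "end_sample",
    "is_delayed", "delay_start_sample", "delay_end_sample",
]


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    rows = []
    for e in truth.events:
        rows.append(
            {
                "event_id": e.event_id,
                "probe_id": e.probe_id,
                "start_sample": e.start_sample,
                "end_sample": e.end_sample,
                "is_delayed": int(e.is_delayed),
                "delay_start_sample": "" if e.delay_start_sample is None else e.delay_start_sample,
                "delay_end_sample": "" if e.delay_end_sample is None else e.delay_end_sample,
            }
        )
    df = pd.DataFrame(rows, columns=_TRUTH_COLS)
    with open(path, "w") as fh:
        fh.write(f"# trace_id={truth.trace_id}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        first = fh.readline().strip()
        trace_id = first.split("trace_id=", 1)[1] if "trace_id=" in first else "trace"
        df = pd.read_csv(fh, sep="\t")
    events = []
    for _, r in df.iterrows():
        d0 = r["delay_start_sample"]
        d1 = r["delay_end_sample"]
        events.append(
            TruthEvent(
                event_id=int(r["event_id"]),
                probe_id="" if pd.isna(r["probe_id"]) else str(r["probe_id"]),
                start_sample=int(r["start_sample"]),
                end_sample=int(r["end_sample"]),
                is_delayed=bool(int(r["is_delayed"])),
                delay_start_sample=None if pd.isna(d0) or d0 == "" else int(d0),
                delay_end_sample=None if pd.isna(d1) or d1 == "" else int(d1),
            )
        )
    return GroundTruth(trace_id=trace_id, events=events)


def match_events_to_truth(events, truth: GroundTruth, min_overlap: float = 0.5):
    """Map detected events to ground-truth events by interval overlap.

    Returns ``{detected_event_id: truth_event_id}``; a detected event matches
    the truth event with the largest overlap, kept only if that overlap
    covers at least ``min_overlap`` of the truth interval.
    """
    tsorted = sorted(truth.events, key=lambda t: t.start_sample)
    dsorted = sorted(events, key=lambda d: d.start_sample)
    mapping: dict = {}
    j = 0
    for det in dsorted:
        while j < len(tsorted) and tsorted[j].end_sample <= det.start_sample:
            j += 1
        best, best_ov = None, 0
        k = j
        while k < len(tsorted) and tsorted[k].start_sample < det.end_sample:
            te = tsorted[k]
            ov = min(det.end_sample, te.end_sample) - max(det.start_sample, te.start_sample)
            if ov > best_ov:
                best, best_ov = te, ov
            k += 1
        if best is not None and best_ov >= min_overlap * (best.end_sample - best.start_sample):
            mapping[det.event_id] = best.event_id
    return mapping
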