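"""Barcode demultiplexing: alignment scoring, threshold cascade, evaluation.

Each base-called read is aligned with free end gaps against every barcode in
the library; the best-scoring barcode is kept only if the alignment clears four
conjunctive criteria (the threshold cascade): at most 5 mismatched bases in
total, at most 1 mismatch in the first 10 barcode bases, at least 15 aligned
bases, and the read starting with the shared ``GGG`` leader. Raw scores use
unit costs (match +1, mismatch -1, gap -1) and are normalized by barcode
length. ROC/AUC and confusion-matrix helpers evaluate the demultiplexer
against known truth labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import _align
from .library import BarcodeLibrary

DEFAULT_SCORING = (1, -1, -1)  # match, mismatch, gap


@dataclass
class CascadeThresholds:
    """The four read-acceptance criteria applied after alignment."""

    max_mismatches_total: int = 5
    max_mismatches_first_y: int = 1
    first_y_bases: int = 10
    min_aligned_bases: int = 15
    required_prefix: str = "GGG"

    def __post_init__(self):
        for name in ("max_mismatches_total", "max_mismatches_first_y",
                     "first_y_bases", "min_aligned_bases"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.required_prefix:
            raise ValueError("required_prefix must be nonempty")


@dataclass
class CascadeFlags:
    total_mismatches_ok: bool
    first_window_ok: bool
    aligned_bases_ok: bool
    prefix_ok: bool

    @property
    def overall(self) -> bool:
        return (self.total_mismatches_ok and self.first_window_ok
                and self.aligned_bases_ok and self.prefix_ok)

    def passes_subset(self, criteria: Iterable[str]) -> bool:
        """Conjunction over a subset of criterion names (for threshold studies)."""
        return all(getattr(self, name) for name in criteria)


CRITERION_NAMES = ("total_mismatches_ok", "first_window_ok", "aligned_bases_ok", "prefix_ok")


@dataclass
class AlignmentResult:
    """Scores and counts of one read-vs-barcode semi-global alignment."""

    read_id: str
    probe_id: str
    raw_score: int
    norm_score: float  # raw_score / barcode length, in [-1, 1]
    aligned_bases: int
    mismatches_total: int
    mismatches_first10: int
    first_y_bases: int
    starts_with_GGG: bool
    read_prefix: str
    flags: CascadeFlags | None = None


@dataclass
class DemuxAssignment:
    read_id: str
    probe_id: str | None  # None when unassigned
    best_probe_id: str
    best_norm_score: float
    margin: float  # best minus runner-up normalized score, >= 0
    passes: bool
    ambiguous: bool = False
    result: AlignmentResult | None = None


def count_mismatches(seq_a: str, seq_b: str) -> int:
    """Hamming distance between equal-length sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError(f"sequences differ in length ({len(seq_a)} vs {len(seq_b)})")
    return sum(a != b for a, b in zip(seq_a, seq_b))


def align_read(
    read: str,
    barcode: str,
    scoring: tuple[int, int, int] = DEFAULT_SCORING,
    read_id: str = "",
    probe_id: str = "",
    first_y_bases: int = 10,
    prefix: str = "GGG",
) -> AlignmentResult:
    """Align a read against one barcode with free end gaps.

    Unaligned ends of either sequence cost nothing (under unit scoring this
    is the zero-floored local-alignment recurrence, so the raw score is
    symmetric in its arguments); gaps inside the aligned span are penalized.
    Counts come from the optimal path with deterministic tie-breaking
    (diagonal over vertical over horizontal moves; among equally scoring end
    cells, the first in row-major order). Substitutions and in-span gap
    columns both count toward ``mismatches_total``; the first-10-bases
    window is measured in barcode coordinates. The prefix check is made on
    the read's first called bases, not on the alignment. 'N' never matches
    and breaks the prefix.
    """
    match, mismatch, gap = (int(s) for s in scoring)
    r = _align.encode_seq(read, "read")
    b = _align.encode_seq(barcode, "barcode")
    H = _align.fill_matrix(r, b, match, mismatch, gap)
    raw, ei, ej = _align.best_end(H)
    aligned, mm_total, mm_first, _, _ = _align.traceback_counts(
        H, r, b, match, mismatch, gap, ei, ej, first_y_bases
    )
    return AlignmentResult(
        read_id=read_id,
        probe_id=probe_id,
        raw_score=int(raw),
        norm_score=float(raw) / len(barcode),
        aligned_bases=int(aligned),
        mismatches_total=int(mm_total),
        mismatches_first10=int(mm_first),
        first_y_bases=first_y_bases,
        starts_with_GGG=read.startswith(prefix),
        read_prefix=read[: len(prefix)],
    )


def apply_cascade(result: AlignmentResult, thresholds: CascadeThresholds | None = None) -> CascadeFlags:
    """Evaluate the four criteria independently and attach the flags to the result."""
    thresholds = thresholds or CascadeThresholds()
    if thresholds.first_y_bases != result.first_y_bases:
        raise ValueError(
            f"alignment counted mismatches over the first {result.first_y_bases} "
            f"bases but the cascade asks for {thresholds.first_y_bases}"
        )
    flags = CascadeFlags(
        total_mismatches_ok=result.mismatches_total <= thresholds.max_mismatches_total,
        first_window_ok=result.mismatches_first10 <= thresholds.max_mismatches_first_y,
        aligned_bases_ok=result.aligned_bases >= thresholds.min_aligned_bases,
        prefix_ok=result.read_prefix == thresholds.required_prefix,
    )
    result.flags = flags
    return flags


def _as_read_tuples(reads) -> list[tuple[str, str]]:
    out = []
    for r in reads:
        if isinstance(r, tuple):
            out.append((str(r[0]), str(r[1]).upper()))
        else:  # SeqRecord-like
            out.append((r.id, str(r.seq).upper()))
    return out


def demux(
    reads,
    library: BarcodeLibrary,
    thresholds: CascadeThresholds | None = None,
    scoring: tuple[int, int, int] = DEFAULT_SCORING,
) -> list[DemuxAssignment]:
    """Assign each read to its best-scoring barcode, gated by the cascade.

    Barcodes are considered in probe-id order, so an exact score tie resolves
    to the lexicographically smallest probe id and the read is flagged
    ambiguous. Reads whose best alignment fails any cascade criterion are
    returned unassigned.
    """
    if len(library) == 0:
        raise ValueError("library must be nonempty")
    thresholds = thresholds or CascadeThresholds()
    lib = library.sorted_by_id()
    codes = [_align.encode_seq(r.barcode_seq, f"barcode {r.probe_id}") for r in lib]
    lengths = np.array([len(c) for c in codes])
    same_len = bool((lengths == lengths[0]).all())
    lib2d = np.stack(codes) if same_len else None
    match, mismatch, gap = (int(s) for s in scoring)

    out: list[DemuxAssignment] = []
    for read_id, seq in _as_read_tuples(reads):
        r = _align.encode_seq(seq, f"read {read_id}")
        if same_len:
            raw = _align.score_library(r, lib2d, match, mismatch, gap)
        else:
            raw = np.array([_align.score_pair(r, c, match, mismatch, gap) for c in codes])
        norm = raw / lengths
        best_k = int(np.argmax(norm))
        best = float(norm[best_k])
        ambiguous = int(np.sum(norm == norm[best_k])) > 1
        if len(norm) > 1:
            margin = float(best - np.partition(norm, -2)[-2])
        else:
            margin = 0.0
        rec = lib.records[best_k]
        result = align_read(
            seq, rec.barcode_seq, scoring,
            read_id=read_id, probe_id=rec.probe_id,
            first_y_bases=thresholds.first_y_bases, prefix=thresholds.required_prefix,
        )
        flags = apply_cascade(result, thresholds)
        out.append(
            DemuxAssignment(
                read_id=read_id,
                probe_id=rec.probe_id if flags.overall else None,
                best_probe_id=rec.probe_id,
                best_norm_score=best,
                margin=margin,
                passes=flags.overall,
                ambiguous=ambiguous,
                result=result,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Evaluation


def auc_from_points(fpr: Sequence[float], tpr: Sequence[float]) -> float:
    """Trapezoidal AUC over ROC points, with (0,0) and (1,1) anchors appended."""
    f = np.concatenate(([0.0], np.asarray(fpr, dtype=float), [1.0]))
    t = np.concatenate(([0.0], np.asarray(tpr, dtype=float), [1.0]))
    order = np.lexsort((t, f))
    return float(np.trapezoid(t[order], f[order]))


def roc_for_thresholds(
    scored: Sequence[tuple[AlignmentResult, bool]],
    threshold_grid: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, float]:
    """ROC of the normalized alignment score against truth labels.

    At each grid threshold t a read is called positive iff norm_score >= t.
    Returns the (threshold, fpr, tpr) table and the trapezoidal AUC.
    """
    if not scored:
        raise ValueError("scored must be nonempty")
    scores = np.array([r.norm_score for r, _ in scored], dtype=float)
    labels = np.array([bool(l) for _, l in scored])
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one true and one false label")
    grid = (np.unique(scores)[::-1] if threshold_grid is None
            else np.asarray(threshold_grid, dtype=float))
    rows = []
    for t in grid:
        pred = scores >= t
        tpr = float(np.sum(pred & labels)) / n_pos
        fpr = float(np.sum(pred & ~labels)) / n_neg
        rows.append((float(t), fpr, tpr))
    df = pd.DataFrame(rows, columns=["threshold", "fpr", "tpr"])
    return df, auc_from_points(df["fpr"], df["tpr"])


def cascade_fpr(
    flagged: Sequence[tuple[CascadeFlags, bool]],
    criteria: Iterable[str] = CRITERION_NAMES,
) -> float:
    """False-positive rate of a criterion subset: truth-negative reads that pass."""
    criteria = tuple(criteria)
    negatives = [f for f, label in flagged if not label]
    if not negatives:
        raise ValueError("no truth-negative reads")
    return sum(f.passes_subset(criteria) for f in negatives) / len(negatives)


def demux_confusion(
    assignments: Sequence[DemuxAssignment],
    truth: Mapping[str, str],
    library: BarcodeLibrary,
) -> pd.DataFrame:
    """Row-normalized confusion matrix over assigned reads (rows = true probe)."""
    ids = sorted(library.probe_ids)
    counts = pd.DataFrame(0.0, index=ids, columns=ids)
    for a in assignments:
        if a.probe_id is None:
            continue
        true_id = truth.get(a.read_id)
        if true_id in counts.index:
            counts.loc[true_id, a.probe_id] += 1
    row_sums = counts.sum(axis=1)
    norm = counts.div(row_sums.where(row_sums > 0, 1.0), axis=0)
    return norm


def assignments_to_frame(assignments: Sequence[DemuxAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        r = a.result
        rows.append(
            {
                "read_id": a.read_id,
                "probe_id": a.probe_id if a.probe_id is not None else "",
                "best_probe_id": a.best_probe_id,
                "norm_score": round(a.best_norm_score, 6),
                "aligned_bases": r.aligned_bases if r else "",
                "mismatches_total": r.mismatches_total if r else "",
                "mismatches_first10": r.mismatches_first10 if r else "",
                "pass": int(a.passes),
                "ambiguous": int(a.ambiguous),
                "margin": round(a.margin, 6),
            }
        )
    return pd.DataFrame(rows)


def write_demux_tsv(assignments: Sequence[DemuxAssignment], path: str | Path) -> None:
    assignments_to_frame(assignments).to_csv(path, sep="\t", index=False)
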