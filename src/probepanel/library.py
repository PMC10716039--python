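"""Barcoded-probe libraries.

A probe couples a DNA barcode (read through the pore and base-called) to a
target-binding region (a complementary sequence for miRNA/DNA, or an aptamer
for proteins and small molecules). All barcodes share a leading ``GGG`` so a
prefix check can reject poorly resolved reads during demultiplexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._rng import derive_rng
from .errors import InfeasibleLibraryError

BARCODE_PREFIX = "GGG"
TARGET_CLASSES = ("miRNA", "protein", "small_molecule")
_DNA = "ACGT"


@dataclass(frozen=True)
class BarcodeRecord:
    """One barcoded probe: identity, barcode sequence and target metadata."""

    probe_id: str
    barcode_seq: str
    binding_seq: str = ""
    target_name: str = ""
    target_class: str = "miRNA"

    def __post_init__(self):
        if not self.probe_id:
            raise ValueError("probe_id must be nonempty")
        if set(self.barcode_seq) - set(_DNA):
            raise ValueError(f"barcode_seq of {self.probe_id!r} must be over ACGT")
        if not self.barcode_seq.startswith(BARCODE_PREFIX):
            raise ValueError(
                f"barcode_seq of {self.probe_id!r} must start with {BARCODE_PREFIX!r}"
            )
        if self.target_class not in TARGET_CLASSES:
            raise ValueError(
                f"target_class must be one of {TARGET_CLASSES}, got {self.target_class!r}"
            )


@dataclass
class BarcodeLibrary:
    """An ordered collection of :class:`BarcodeRecord` with unique probe ids."""

    records: list[BarcodeRecord] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.probe_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate probe ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[BarcodeRecord]:
        return iter(self.records)

    def __getitem__(self, probe_id: str) -> BarcodeRecord:
        for r in self.records:
            if r.probe_id == probe_id:
                return r
        raise KeyError(probe_id)

    @property
    def probe_ids(self) -> list[str]:
        return [r.probe_id for r in self.records]

    def sorted_by_id(self) -> "BarcodeLibrary":
        return BarcodeLibrary(sorted(self.records, key=lambda r: r.probe_id))


def barcode_space_size(barcode_len: int) -> int:
    """Number of distinct DNA barcodes of the given length, exactly (4**L).

    For the 35-base barcodes used by the platform this is
    1,180,591,620,717,411,303,424 (about 1.18e21).
    """
    barcode_len = int(barcode_len)
    if barcode_len < 0:
        raise ValueError("barcode_len must be >= 0")
    return 4**barcode_len


def hamming_distance(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"sequences differ in length ({len(a)} vs {len(b)})")
    return sum(x != y for x, y in zip(a, b))


def generate_barcode_library(
    n_barcodes: int,
    barcode_len: int = 35,
    min_pairwise_mismatches: int = 5,
    seed: int = 0,
    target_class: str = "miRNA",
    max_attempts_per_barcode: int = 2000,
) -> BarcodeLibrary:
    """Draw a library of barcodes with a guaranteed pairwise Hamming separation.

    Each barcode begins with the shared ``GGG`` leader; the remaining
    (variable) region is drawn uniformly and accepted only if its Hamming
    distance to the variable region of every accepted barcode is at least
    ``min_pairwise_mismatches``. Deterministic for a fixed seed.

    Raises
    ------
    InfeasibleLibraryError
        If the request provably cannot be met, or rejection sampling exceeds
        ``max_attempts_per_barcode`` tries for one slot.
    """
    if n_barcodes < 1:
        raise ValueError("n_barcodes must be >= 1")
    if barcode_len < len(BARCODE_PREFIX) + 1:
        raise ValueError(f"barcode_len must be >= {len(BARCODE_PREFIX) + 1}")
    if min_pairwise_mismatches < 0:
        raise ValueError("min_pairwise_mismatches must be >= 0")
    var_len = barcode_len - len(BARCODE_PREFIX)
    if n_barcodes > 1 and min_pairwise_mismatches > var_len:
        raise InfeasibleLibraryError(
            f"min_pairwise_mismatches={min_pairwise_mismatches} exceeds the "
            f"{var_len}-base variable region"
        )
    rng = derive_rng(seed, "barcode-library")
    width = max(2, len(str(n_barcodes)))
    accepted: list[np.ndarray] = []
    records: list[BarcodeRecord] = []
    for k in range(n_barcodes):
        for _ in range(max_attempts_per_barcode):
            cand = rng.integers(0, 4, size=var_len)
            if all(int(np.sum(cand != prev)) >= min_pairwise_mismatches for prev in accepted):
                break
        else:
            raise InfeasibleLibraryError(
                f"could not place barcode {k + 1} of {n_barcodes} at length "
                f"{barcode_len} with min pairwise mismatches "
                f"{min_pairwise_mismatches} after {max_attempts_per_barcode} attempts"
            )
        accepted.append(cand)
        seq = BARCODE_PREFIX + "".join(_DNA[i] for i in cand)
        probe_id = f"probe_{k + 1:0{width}d}"
        records.append(
            BarcodeRecord(
                probe_id=probe_id,
                barcode_seq=seq,
                binding_seq=str(Seq(seq).reverse_complement()),
                target_name=f"target_{k + 1:0{width}d}",
                target_class=target_class,
            )
        )
    return BarcodeLibrary(records)


# ---------------------------------------------------------------------------
# FASTA + TSV sidecar round-trip


def write_library(library: BarcodeLibrary, fasta_path: str | Path, tsv_path: str | Path) -> None:
    """Write barcodes as FASTA and probe metadata as a TSV sidecar."""
    seqs = [
        SeqRecord(Seq(r.barcode_seq), id=r.probe_id, description="") for r in library
    ]
    SeqIO.write(seqs, str(fasta_path), "fasta")
    pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in library],
            "binding_seq": [r.binding_seq for r in library],
            "target_name": [r.target_name for r in library],
            "target_class": [r.target_class for r in library],
        }
    ).to_csv(tsv_path, sep="\t", index=False)


def read_library(fasta_path: str | Path, tsv_path: str | Path | None = None) -> BarcodeLibrary:
    """Load a library from FASTA (barcodes) and an optional metadata sidecar."""
    meta: dict[str, dict] = {}
    if tsv_path is not None:
        df = pd.read_csv(tsv_path, sep="\t", dtype=str).fillna("")
        meta = {row["probe_id"]: row for _, row in df.iterrows()}
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        m = meta.get(rec.id, {})
        records.append(
            BarcodeRecord(
                probe_id=rec.id,
                barcode_seq=str(rec.seq).upper(),
                binding_seq=m.get("binding_seq", ""),
                target_name=m.get("target_name", ""),
                target_class=m.get("target_class", "miRNA"),
            )
        )
    return BarcodeLibrary(records)
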