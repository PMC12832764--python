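"""Spatial-barcode extraction, whitelist correction and UMI deduplication.

Read 1 carries a 30-nt spatial barcode (SBC) at positions 1-30 and a 10-nt
UMI at positions 88-97 (1-based).  SBCs are matched against the chip
whitelist exactly, then with a single-base fallback: a barcode with exactly
one whitelist entry at Hamming distance 1 is corrected to it, while barcodes
that are ambiguous at distance 1 are dropped.  Reads sharing the same
(barcode, gene, splice class) are collapsed to the number of distinct UMIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .spatial_core import GridSpec, SpotTable, SPOT_COLUMNS

__all__ = [
    "ReadRecord",
    "BarcodeWhitelist",
    "ShortReadError",
    "DemuxStats",
    "SBC_LENGTH",
    "UMI_LENGTH",
    "MIN_READ_LENGTH",
    "extract_sbc_umi",
    "correct_barcode",
    "dedup_umis",
    "demultiplex",
    "sequencing_saturation",
    "read_fastq",
    "read_gene_assignments",
]

SBC_LENGTH = 30
UMI_LENGTH = 10
_UMI_START = 87  # 0-based; 1-based position 88
MIN_READ_LENGTH = _UMI_START + UMI_LENGTH  # 97

_BASES = ("A", "C", "G", "T")


class ShortReadError(ValueError):
    """Read 1 too short to contain both the barcode and the UMI."""


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    seq1: str
    gene: str | None = None
    splice_class: str = "spliced"


@dataclass
class BarcodeWhitelist:
    """Chip barcode -> coordinate lookup.

    All barcodes must be unique 30-mers; when a grid is supplied the
    coordinates are validated against it.
    """

    entries: Mapping[str, tuple[int, int]]
    grid: GridSpec | None = None

    def __post_init__(self) -> None:
        entries = dict(self.entries)
        for bc, (x, y) in entries.items():
            if len(bc) != SBC_LENGTH:
                raise ValueError(f"barcode {bc!r} is not {SBC_LENGTH} nt")
            if self.grid is not None and not bool(self.grid.contains(x, y)):
                raise ValueError(f"barcode {bc!r} coordinate ({x}, {y}) outside grid")
        self.entries = entries

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path, grid: GridSpec | None = None) -> "BarcodeWhitelist":
        df = pd.read_csv(path, sep="\t", dtype={"barcode": str})
        entries = {
            str(r.barcode): (int(r.x_bin), int(r.y_bin)) for r in df.itertuples(index=False)
        }
        if len(entries) != len(df):
            raise ValueError("whitelist barcodes are not unique")
        return cls(entries, grid)


def extract_sbc_umi(read: ReadRecord) -> tuple[str, str]:
    """Slice the spatial barcode and UMI out of read 1.

    Raises :class:`ShortReadError` when the read is shorter than 97 nt.
    """
    if len(read.seq1) < MIN_READ_LENGTH:
        raise ShortReadError(
            f"read {read.read_id}: length {len(read.seq1)} < {MIN_READ_LENGTH}"
        )
    seq = read.seq1
    return seq[:SBC_LENGTH], seq[_UMI_START : _UMI_START + UMI_LENGTH]


def correct_barcode(
    sbc: str, whitelist: BarcodeWhitelist
) -> tuple[int, int, str] | None:
    """Resolve a barcode to chip coordinates, tolerating one substitution.

    Returns ``(x_bin, y_bin, whitelist_barcode)`` or ``None`` when there is no
    hit or the distance-1 hit is ambiguous.  An exact hit always wins.
    """
    entries = whitelist.entries
    hit = entries.get(sbc)
    if hit is not None:
        return hit[0], hit[1], sbc
    # enumerate the 90 single-substitution neighbours instead of scanning the
    # whitelist; equivalent to an exhaustive Hamming-1 search
    candidates: list[str] = []
    for i, orig in enumerate(sbc):
        prefix, suffix = sbc[:i], sbc[i + 1 :]
        for base in _BASES:
            if base == orig:
                continue
            variant = prefix + base + suffix
            if variant in entries:
                candidates.append(variant)
    if len(candidates) == 1:
        bc = candidates[0]
        x, y = entries[bc]
        return x, y, bc
    return None


def dedup_umis(assigned: pd.DataFrame, grid: GridSpec) -> SpotTable:
    """Collapse corrected reads into a SpotTable of distinct-UMI counts.

    ``assigned`` needs columns ``barcode, x_bin, y_bin, gene, splice_class,
    umi`` (one row per read).  ``umi_count`` is the number of distinct UMIs
    per (barcode, gene, splice_class); PCR duplicates collapse to one.
    """
    if len(assigned) == 0:
        empty = pd.DataFrame({c: [] for c in SPOT_COLUMNS})
        return SpotTable(empty, grid)
    grouped = (
        assigned.groupby(["barcode", "x_bin", "y_bin", "gene", "splice_class"], sort=True)["umi"]
        .nunique()
        .reset_index(name="umi_count")
    )
    return SpotTable(grouped, grid)


@dataclass
class DemuxStats:
    n_reads: int = 0
    n_short: int = 0
    n_unassigned_gene: int = 0
    n_no_barcode_match: int = 0
    n_assigned: int = 0
    n_unique_umis: int = 0

    @property
    def saturation(self) -> float:
        return sequencing_saturation(self.n_assigned, self.n_unique_umis)


def demultiplex(
    reads: Iterable[ReadRecord], whitelist: BarcodeWhitelist, grid: GridSpec
) -> tuple[SpotTable, DemuxStats]:
    """Full read-1 processing: extract, correct, deduplicate.

    Reads without a gene assignment or without a barcode match are discarded
    and counted in the returned :class:`DemuxStats`.
    """
    stats = DemuxStats()
    rows: list[tuple[str, int, int, str, str, str]] = []
    for read in reads:
        stats.n_reads += 1
        try:
            sbc, umi = extract_sbc_umi(read)
        except ShortReadError:
            stats.n_short += 1
            continue
        if read.gene is None:
            stats.n_unassigned_gene += 1
            continue
        hit = correct_barcode(sbc, whitelist)
        if hit is None:
            stats.n_no_barcode_match += 1
            continue
        x, y, bc = hit
        rows.append((bc, x, y, read.gene, read.splice_class, umi))
        stats.n_assigned += 1
    assigned = pd.DataFrame(
        rows, columns=["barcode", "x_bin", "y_bin", "gene", "splice_class", "umi"]
    )
    table = dedup_umis(assigned, grid)
    stats.n_unique_umis = int(table.data["umi_count"].sum())
    return table, stats


def sequencing_saturation(n_reads_assigned: int, n_unique_umis: int) -> float:
    """``1 - unique UMIs / assigned reads``, in [0, 1]."""
    if n_reads_assigned <= 0:
        raise ValueError("saturation undefined for zero assigned reads")
    if not 0 < n_unique_umis <= n_reads_assigned:
        raise ValueError(
            f"need 0 < n_unique_umis <= n_reads_assigned, got "
            f"({n_reads_assigned}, {n_unique_umis})"
        )
    return 1.0 - n_unique_umis / n_reads_assigned


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Yield read-1 records from a FASTQ file (sequence uppercased)."""
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fastq"):
        yield ReadRecord(read_id=rec.id, seq1=str(rec.seq).upper())


def read_gene_assignments(path: str | Path) -> dict[str, tuple[str, str]]:
    """Load per-read gene assignments from upstream alignment.

    TSV with columns ``read_id, gene`` and optional ``splice_class``
    (default ``spliced``).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "splice_class" not in df.columns:
        df["splice_class"] = "spliced"
    return {
        r.read_id: (r.gene, r.splice_class) for r in df.itertuples(index=False)
    }


def annotate_reads(
    reads: Iterable[ReadRecord], assignments: Mapping[str, tuple[str, str]]
) -> Iterator[ReadRecord]:
    for read in reads:
        hit = assignments.get(read.read_id)
        if hit is None:
            yield read
        else:
            gene, splice_class = hit
            yield ReadRecord(read.read_id, read.seq1, gene, splice_class)
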