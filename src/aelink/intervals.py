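"""Genomic interval primitives and plain-text region I/O.

All coordinates are 0-based half-open (BED convention). 1-based positions
appear only in human-readable reports, never in data structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "merge_intervals",
    "intervals_overlap",
    "overlap_bp",
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
]

PROMOTER_UPSTREAM = 1500
PROMOTER_DOWNSTREAM = 500


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: start must be < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


def intervals_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.overlaps(b)


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    return a.overlap_bp(b)


@dataclass(frozen=True)
class GeneModel:
    """A gene with a strand-aware TSS and promoter.

    The promoter spans 1,500 bp upstream to 500 bp downstream of the TSS,
    oriented by strand, and is clipped at zero.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"gene {self.gene_id}: tx_start must be < tx_end")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.tx_start, self.tx_end)

    @property
    def promoter(self) -> GenomicInterval:
        if self.strand == "+":
            start = self.tss - PROMOTER_UPSTREAM
            end = self.tss + PROMOTER_DOWNSTREAM
        else:
            start = self.tss - PROMOTER_DOWNSTREAM + 1
            end = self.tss + PROMOTER_UPSTREAM + 1
        return GenomicInterval(self.chrom, max(0, start), end)


def merge_intervals(
    intervals: Iterable[GenomicInterval], merge_bookended: bool = True
) -> list[GenomicInterval]:
    """Union-merge intervals; book-ended intervals (end == next start) coalesce
    by default, matching standard merge semantics."""
    per_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        per_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(per_chrom):
        ivs = sorted(per_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            joins = iv.start <= cur_end if merge_bookended else iv.start < cur_end
            if joins:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


# ---------------------------------------------------------------------------
# Plain-text I/O


def read_bed(path, min_fields: int = 3) -> pd.DataFrame:
    """Read a BED3+ file into a DataFrame (chrom, start, end [, extra...]).

    Raises ValueError naming the offending line on malformed input.
    """
    rows = []
    n_extra = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < min_fields:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= {min_fields} fields, got {len(parts)}"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise ValueError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            rows.append([parts[0], start, end] + parts[3:])
            n_extra = max(n_extra, len(parts) - 3)
    cols = ["chrom", "start", "end"] + [f"field{i+4}" for i in range(n_extra)]
    df = pd.DataFrame(rows, columns=cols[: 3 + n_extra] if rows else cols)
    if df.empty:
        df = pd.DataFrame(columns=["chrom", "start", "end"])
    return df


def write_bed(df: pd.DataFrame, path, extra_cols: Sequence[str] = ()) -> None:
    cols = ["chrom", "start", "end", *extra_cols]
    df.to_csv(path, sep="\t", header=False, index=False, columns=list(cols))


def read_bedpe(path) -> pd.DataFrame:
    """Read 6-column BEDPE (two paired anchors) into a DataFrame."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 BEDPE fields")
            rows.append(
                [
                    parts[0],
                    int(parts[1]),
                    int(parts[2]),
                    parts[3],
                    int(parts[4]),
                    int(parts[5]),
                ]
            )
    return pd.DataFrame(
        rows, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    )


def write_bedpe(df: pd.DataFrame, path) -> None:
    df.to_csv(
        path,
        sep="\t",
        header=False,
        index=False,
        columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"],
    )


def read_genes(path) -> list[GeneModel]:
    """Read a genes.tsv (gene_id, chrom, strand, tx_start, tx_end; headered)."""
    df = pd.read_csv(path, sep="\t")
    return [
        GeneModel(
            gene_id=str(r.gene_id),
            chrom=str(r.chrom),
            strand=str(r.strand),
            tx_start=int(r.tx_start),
            tx_end=int(r.tx_end),
        )
        for r in df.itertuples()
    ]


def write_genes(genes: Sequence[GeneModel], path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "tx_start": g.tx_start,
                "tx_end": g.tx_end,
            }
            for g in genes
        ],
        columns=["gene_id", "chrom", "strand", "tx_start", "tx_end"],
    ).to_csv(path, sep="\t", index=False)
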