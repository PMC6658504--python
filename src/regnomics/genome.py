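"""Shared genomic coordinate types and operations.

All coordinates are 0-based half-open throughout the package, matching the
native convention of the BED and refFlat formats this package consumes.
Any 1-based representation is a display concern only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import pandas as pd

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "BinGrid",
    "make_bins",
    "overlaps",
    "read_refflat",
    "write_refflat",
    "promoter_of",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of '+', '-', '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class GeneModel:
    """A transcript model; the TSS is strand-dependent (tx_start on '+',
    tx_end on '-')."""

    symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be '+' or '-', got {self.strand!r}")
        if self.tx_start >= self.tx_end:
            raise ValueError("tx_start must be < tx_end")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def footprint(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.tx_start, self.tx_end, self.strand)


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width tiling of one chromosome.

    Bins tile [0, chrom_length) without gaps or overlaps; every bin has
    width ``bin_size`` except possibly the last, which is truncated.
    """

    chrom: str
    bin_size: int
    chrom_length: int
    bins: tuple[GenomicInterval, ...] = field(default=())

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def bin_range_overlapping(self, start: int, end: int) -> range:
        """Indices of bins overlapping [start, end), clipped to the grid."""
        if end <= 0 or start >= self.chrom_length:
            return range(0)
        lo = max(start, 0) // self.bin_size
        hi = (min(end, self.chrom_length) - 1) // self.bin_size
        return range(lo, hi + 1)


def make_bins(chrom_length: int, bin_size: int, chrom: str = "chr") -> BinGrid:
    """Tile a chromosome with fixed-width bins (last bin truncated)."""
    if chrom_length <= 0:
        raise ValueError(f"chrom_length must be positive, got {chrom_length}")
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    bins = []
    for start in range(0, chrom_length, bin_size):
        bins.append(GenomicInterval(chrom, start, min(start + bin_size, chrom_length)))
    return BinGrid(chrom=chrom, bin_size=bin_size, chrom_length=chrom_length,
                   bins=tuple(bins))


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Half-open overlap predicate; intervals on different chromosomes never
    overlap, and abutting intervals share no base."""
    if a.chrom != b.chrom:
        return False
    return max(a.start, b.start) < min(a.end, b.end)


# refFlat columns, UCSC order
_REFFLAT_COLS = (
    "geneName", "name", "chrom", "strand", "txStart", "txEnd",
    "cdsStart", "cdsEnd", "exonCount", "exonStarts", "exonEnds",
)


def read_refflat(source: str | TextIO) -> list[GeneModel]:
    """Parse a refFlat (UCSC Table Browser) file into gene models.

    Accepts a path or an open text stream.  Lines must be tab-delimited with
    at least the first six refFlat columns; coordinates stay 0-based
    half-open as in the format.  Malformed lines raise ``ValueError`` naming
    the offending line number.
    """
    close = False
    if isinstance(source, str):
        handle: TextIO = open(source)
        close = True
    else:
        handle = source
    genes: list[GeneModel] = []
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"refFlat line {lineno}: expected >= 6 tab-delimited fields, "
                    f"got {len(fields)}"
                )
            symbol, _name, chrom, strand, tx_start, tx_end = fields[:6]
            try:
                start_i, end_i = int(tx_start), int(tx_end)
            except ValueError as exc:
                raise ValueError(
                    f"refFlat line {lineno}: non-numeric coordinates "
                    f"({tx_start!r}, {tx_end!r})"
                ) from exc
            genes.append(GeneModel(symbol=symbol, chrom=chrom, strand=strand,
                                   tx_start=start_i, tx_end=end_i))
    finally:
        if close:
            handle.close()
    return genes


def write_refflat(genes: Iterable[GeneModel], dest: str | TextIO) -> None:
    """Write gene models in minimal refFlat layout (transcript name reuses
    the symbol; CDS set to the transcript span; single exon)."""
    close = False
    if isinstance(dest, str):
        handle: TextIO = open(dest, "w")
        close = True
    else:
        handle = dest
    try:
        for g in genes:
            row = (
                g.symbol, g.symbol, g.chrom, g.strand,
                str(g.tx_start), str(g.tx_end), str(g.tx_start), str(g.tx_end),
                "1", f"{g.tx_start},", f"{g.tx_end},",
            )
            handle.write("\t".join(row) + "\n")
    finally:
        if close:
            handle.close()


def promoter_of(gene: GeneModel, flank: int = 1000) -> GenomicInterval:
    """Promoter window [TSS - flank, TSS + flank), clipped at 0."""
    if flank <= 0:
        raise ValueError(f"flank must be positive, got {flank}")
    tss = gene.tss
    return GenomicInterval(gene.chrom, max(tss - flank, 0), tss + flank,
                           gene.strand)


def promoters_of(genes: Iterable[GeneModel], flank: int = 1000
                 ) -> dict[str, list[GenomicInterval]]:
    """Per-symbol promoter windows, deduplicated by identical intervals.

    Multiple transcripts of one symbol keep distinct promoters; transcripts
    sharing a TSS collapse to one window.
    """
    out: dict[str, list[GenomicInterval]] = {}
    for g in genes:
        p = promoter_of(g, flank)
        bucket = out.setdefault(g.symbol, [])
        if p not in bucket:
            bucket.append(p)
    return out


def read_bed(source: str | TextIO) -> pd.DataFrame:
    """Read BED3+ into a DataFrame with at least chrom/start/end columns;
    name/score/strand are kept when present."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(source, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]] + [f"col{i}" for i in range(6, df.shape[1])]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(intervals: Sequence[GenomicInterval], dest: str | TextIO,
              names: Sequence[str] | None = None) -> None:
    """Write intervals as BED3 (or BED4 when names are given)."""
    rows = []
    for i, iv in enumerate(intervals):
        row = [iv.chrom, iv.start, iv.end]
        if names is not None:
            row.append(names[i])
        rows.append(row)
    pd.DataFrame(rows).to_csv(dest, sep="\t", header=False, index=False)


def read_chrom_sizes(source: str | TextIO) -> dict[str, int]:
    """Two-column chromosome sizes file (name, length)."""
    df = pd.read_csv(source, sep="\t", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"], df["length"].astype(int)))


def bed_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    """Convert a BED DataFrame into GenomicInterval records."""
    strand = df["strand"] if "strand" in df else ["."] * len(df)
    return [GenomicInterval(c, int(s), int(e), st if st in "+-" else ".")
            for c, s, e, st in zip(df["chrom"], df["start"], df["end"], strand)]
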