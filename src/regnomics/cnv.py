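"""Cohort copy-number gain analysis.

Implements the binned gain-frequency map over a chromosome (fixed-width
bins, a segment counts toward a bin when a gained interval overlaps it),
per-sample 17q classification into segmental / numerical / no gain, and
gene-level gain calls.  A segment is a gain when its copy number strictly
exceeds the threshold (default 2.5 on a diploid baseline of 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

from .genome import BinGrid, GenomicInterval, overlaps

__all__ = [
    "CnSegment",
    "GainFrequencyTrack",
    "SampleGainSummary",
    "call_gains",
    "gain_frequency_track",
    "gene_gain_status",
    "classify_17q",
    "mean_region_cn",
    "gain_contingency",
    "read_seg_csv",
    "write_bedgraph",
]

GAIN_THRESHOLD = 2.5  # copy number must strictly exceed this to count as a gain


@dataclass(frozen=True)
class CnSegment:
    """One copy-number segment of one sample (diploid baseline 2.0)."""

    sample_id: str
    interval: GenomicInterval
    copy_number: float

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise ValueError(f"copy_number must be >= 0, got {self.copy_number}")


@dataclass(frozen=True)
class GainFrequencyTrack:
    """Per-bin count and frequency of samples carrying a gain in the bin."""

    grid: BinGrid
    counts: np.ndarray
    frequency: np.ndarray
    cohort_size: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": [b.chrom for b in self.grid.bins],
            "start": [b.start for b in self.grid.bins],
            "end": [b.end for b in self.grid.bins],
            "count": self.counts,
            "frequency": self.frequency,
        })


@dataclass(frozen=True)
class SampleGainSummary:
    sample_id: str
    status_17q: str  # segmental | numerical | none
    gene_gained: dict[str, bool]
    mean_17q_cn: float


def call_gains(segments: Sequence[CnSegment],
               threshold: float = GAIN_THRESHOLD) -> list[CnSegment]:
    """Segments whose copy number strictly exceeds the threshold, in order."""
    return [s for s in segments if s.copy_number > threshold]


def gain_frequency_track(cohort: Mapping[str, Sequence[CnSegment]],
                         grid: BinGrid,
                         threshold: float = GAIN_THRESHOLD) -> GainFrequencyTrack:
    """Cross-cohort gain frequency per bin.

    A bin counts a sample when at least one of that sample's gained segments
    overlaps the bin; the denominator is the full cohort, including samples
    with no gains at all.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must contain at least one sample")
    counts = np.zeros(grid.n_bins, dtype=int)
    for segments in cohort.values():
        hit = np.zeros(grid.n_bins, dtype=bool)
        for seg in call_gains(segments, threshold):
            if seg.interval.chrom != grid.chrom:
                continue
            for i in grid.bin_range_overlapping(seg.interval.start, seg.interval.end):
                hit[i] = True
        counts += hit
    return GainFrequencyTrack(grid=grid, counts=counts,
                              frequency=counts / len(cohort),
                              cohort_size=len(cohort))


def gene_gain_status(sample_segments: Sequence[CnSegment],
                     gene_footprint: GenomicInterval,
                     threshold: float = GAIN_THRESHOLD) -> bool:
    """True iff at least one gained segment overlaps the gene footprint."""
    return any(overlaps(s.interval, gene_footprint)
               for s in call_gains(sample_segments, threshold))


def _gained_coverage(gained: Sequence[CnSegment], region: GenomicInterval) -> int:
    """Bases of `region` covered by >= 1 gained segment (union, not sum)."""
    clipped = []
    for s in gained:
        if not overlaps(s.interval, region):
            continue
        clipped.append((max(s.interval.start, region.start),
                        min(s.interval.end, region.end)))
    if not clipped:
        return 0
    clipped.sort()
    total, cur_s, cur_e = 0, *clipped[0]
    for s, e in clipped[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    total += cur_e - cur_s
    return total


def classify_17q(sample_segments: Sequence[CnSegment],
                 arm_model: Mapping[str, GenomicInterval],
                 threshold: float = GAIN_THRESHOLD,
                 whole_chrom_fraction: float = 0.9) -> str:
    """Classify a sample's 17q gain as ``segmental``, ``numerical`` or ``none``.

    ``numerical`` (whole-chromosome) gain requires gained bases to cover at
    least ``whole_chrom_fraction`` of BOTH arms; any q-arm gain short of that
    is ``segmental``; no gained segment overlapping the q arm is ``none``.
    The 90% default tolerates array edge effects at the telomeres and
    centromere.
    """
    if set(arm_model) != {"p_arm", "q_arm"}:
        raise ValueError("arm_model must have exactly 'p_arm' and 'q_arm'")
    p_arm, q_arm = arm_model["p_arm"], arm_model["q_arm"]
    if p_arm.chrom != q_arm.chrom or p_arm.end != q_arm.start:
        raise ValueError("arm intervals must share a chromosome and abut at the centromere")
    gained = call_gains(sample_segments, threshold)
    q_cov = _gained_coverage(gained, q_arm)
    if q_cov == 0:
        return "none"
    p_cov = _gained_coverage(gained, p_arm)
    if (q_cov >= whole_chrom_fraction * len(q_arm)
            and p_cov >= whole_chrom_fraction * len(p_arm)):
        return "numerical"
    return "segmental"


def mean_region_cn(sample_segments: Sequence[CnSegment],
                   region: GenomicInterval,
                   baseline: float = 2.0) -> float:
    """Length-weighted mean copy number over a region.

    Bases not covered by any segment are imputed at the diploid baseline.
    Where segments overlap each other, later segments take precedence over
    earlier ones base-by-base.
    """
    if len(region) == 0:
        raise ValueError("region must have positive length")
    # event-sweep over clipped segments; last-writer-wins on overlap
    boundaries: list[tuple[int, int, float]] = []
    for s in sample_segments:
        if not overlaps(s.interval, region):
            continue
        boundaries.append((max(s.interval.start, region.start),
                           min(s.interval.end, region.end), s.copy_number))
    if not boundaries:
        return baseline
    total = 0.0
    cuts = sorted({region.start, region.end,
                   *(b[0] for b in boundaries), *(b[1] for b in boundaries)})
    for a, b in zip(cuts[:-1], cuts[1:]):
        value = baseline
        for s, e, c in boundaries:
            if s <= a and b <= e:
                value = c
        total += value * (b - a)
    return total / len(region)


def gain_contingency(gained_by_group: Mapping[str, tuple[int, int]]
                     ) -> pd.DataFrame:
    """Per-group and pooled gain counts and percentages.

    ``gained_by_group`` maps group label -> (gained, total).  Percentages are
    rounded to 2 decimal places; the pooled row is computed from the summed
    counts, not from averaging group percentages.
    """
    rows = []
    g_sum = t_sum = 0
    for group, (gained, total) in gained_by_group.items():
        if gained > total:
            raise ValueError(f"group {group!r}: gained ({gained}) > total ({total})")
        pct = round(100.0 * gained / total, 2) if total else float("nan")
        rows.append({"group": group, "gained": gained, "total": total,
                     "percent": pct})
        g_sum += gained
        t_sum += total
    rows.append({"group": "pooled", "gained": g_sum, "total": t_sum,
                 "percent": round(100.0 * g_sum / t_sum, 2) if t_sum else float("nan")})
    return pd.DataFrame(rows)


def read_seg_csv(source: str | TextIO) -> dict[str, list[CnSegment]]:
    """SEG-like CSV (sample_id, chrom, start, end, copy_number; 0-based
    half-open) -> per-sample segment lists."""
    df = pd.read_csv(source)
    required = {"sample_id", "chrom", "start", "end", "copy_number"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"SEG CSV missing columns: {sorted(missing)}")
    cohort: dict[str, list[CnSegment]] = {}
    for row in df.itertuples(index=False):
        seg = CnSegment(str(row.sample_id),
                        GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
                        float(row.copy_number))
        cohort.setdefault(seg.sample_id, []).append(seg)
    return cohort


def write_bedgraph(track: GainFrequencyTrack, dest: str | TextIO) -> None:
    """4-column BEDGRAPH of the per-bin gain frequency."""
    df = track.to_frame()[["chrom", "start", "end", "frequency"]]
    df.to_csv(dest, sep="\t", header=False, index=False)
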