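"""RNA Pol II promoter-occupancy loss analysis.

Per-file depth normalization (f = reads in file / mean reads across files),
normalized reads-per-kilobase over a region
(count / region length in bp / f * 1000), the both-control/neither-treated
peak-loss filter for promoters, and the per-replicate paired t-test on the
normalized densities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from scipy import stats

from .genome import GenomicInterval
from .enhancers import Peak, _interval_trees

__all__ = [
    "ReadSet",
    "RegionDensity",
    "PromoterLossResult",
    "norm_factor",
    "normalized_rpk",
    "count_overlapping_reads",
    "region_densities",
    "lost_promoters",
    "paired_t",
    "promoter_loss_analysis",
]


@dataclass(frozen=True)
class ReadSet:
    """Aligned reads of one sample/replicate as genomic intervals."""

    sample_id: str
    condition: str  # control | treated
    replicate_id: str
    reads: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.condition not in ("control", "treated"):
            raise ValueError(f"condition must be control/treated, got {self.condition!r}")

    @property
    def total_reads(self) -> int:
        return len(self.reads)


@dataclass(frozen=True)
class RegionDensity:
    region: GenomicInterval
    sample_id: str
    rpk: float
    factor: float


@dataclass(frozen=True)
class PromoterLossResult:
    """Genes passing the promoter peak-loss filter, with the per-replicate
    paired t statistics on normalized promoter densities."""

    lost_genes: tuple[str, ...]
    per_replicate_t: dict[str, dict[str, float]]  # replicate -> {t, p, n}
    mean_control_rpk: dict[str, float]
    mean_treated_rpk: dict[str, float]


def norm_factor(file_total: int, all_totals: Sequence[int]) -> float:
    """Depth factor f = reads in this file / mean reads across all files."""
    totals = np.asarray(all_totals, dtype=float)
    if file_total <= 0 or np.any(totals <= 0):
        raise ValueError("all read totals must be positive")
    return float(file_total / totals.mean())


def normalized_rpk(read_count_in_region: int, region_length: int,
                   f: float) -> float:
    """Normalized reads per kilobase: count / length(bp) / f * 1000."""
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    if f <= 0:
        raise ValueError("normalization factor must be positive")
    return read_count_in_region / region_length / f * 1000.0


class _SortedReads:
    """Per-chromosome sorted endpoints for O(log n) overlap counting.

    A read counts toward a region when >= 1 bp overlaps (half-open):
    count = #(start < region.end) - #(end <= region.start).
    """

    def __init__(self, reads: Sequence[GenomicInterval]):
        self.starts: dict[str, np.ndarray] = {}
        self.ends: dict[str, np.ndarray] = {}
        grouped: dict[str, list[GenomicInterval]] = {}
        for r in reads:
            grouped.setdefault(r.chrom, []).append(r)
        for chrom, rs in grouped.items():
            self.starts[chrom] = np.sort(np.array([r.start for r in rs]))
            self.ends[chrom] = np.sort(np.array([r.end for r in rs]))

    def count(self, region: GenomicInterval) -> int:
        starts = self.starts.get(region.chrom)
        if starts is None:
            return 0
        ends = self.ends[region.chrom]
        n_start_before = int(np.searchsorted(starts, region.end, side="left"))
        n_end_before = int(np.searchsorted(ends, region.start, side="right"))
        return n_start_before - n_end_before


def count_overlapping_reads(reads: Sequence[GenomicInterval],
                            region: GenomicInterval) -> int:
    """Number of reads overlapping the region by >= 1 bp (half-open)."""
    return _SortedReads(reads).count(region)


def region_densities(read_set: ReadSet, regions: Sequence[GenomicInterval],
                     all_totals: Sequence[int]) -> list[RegionDensity]:
    """Normalized rpk of every region in one read file."""
    f = norm_factor(read_set.total_reads, all_totals)
    index = _SortedReads(read_set.reads)
    return [RegionDensity(region=r, sample_id=read_set.sample_id,
                          rpk=normalized_rpk(index.count(r), len(r), f),
                          factor=f)
            for r in regions]


def lost_promoters(ctrl_rep_peaks: Sequence[Sequence[Peak]],
                   treated_rep_peaks: Sequence[Sequence[Peak]],
                   promoters: Mapping[str, GenomicInterval]) -> list[str]:
    """Genes whose promoter has a peak in BOTH control replicates and no
    peak in ANY treated replicate.

    ``promoters`` maps gene symbol -> promoter interval.  The replicate
    structure (2 control / 2 treated in the reference design) is whatever
    the caller supplies, but each side must be nonempty.
    """
    if len(ctrl_rep_peaks) == 0 or len(treated_rep_peaks) == 0:
        raise ValueError("need >= 1 control and >= 1 treated replicate peak set")
    ctrl_trees = [_interval_trees(reps) for reps in ctrl_rep_peaks]
    trt_trees = [_interval_trees(reps) for reps in treated_rep_peaks]

    def has_peak(trees, iv: GenomicInterval) -> bool:
        tree = trees.get(iv.chrom)
        return tree is not None and bool(tree.overlap(iv.start, iv.end))

    lost = []
    for gene, promoter in promoters.items():
        if (all(has_peak(t, promoter) for t in ctrl_trees)
                and not any(has_peak(t, promoter) for t in trt_trees)):
            lost.append(gene)
    return lost


def paired_t(ctrl_rpk: Sequence[float], treated_rpk: Sequence[float]
             ) -> dict[str, float]:
    """Paired t-test on control vs treated densities over the same regions:
    t = mean(d) / (sd(d)/sqrt(n)) with d = control - treated, n-1 df,
    two-sided p.  Zero-variance differences report p = 1 with a warning."""
    c = np.asarray(ctrl_rpk, dtype=float)
    t_arr = np.asarray(treated_rpk, dtype=float)
    if c.size != t_arr.size:
        raise ValueError("paired vectors must have equal length")
    if c.size < 2:
        raise ValueError("paired t-test requires n >= 2")
    d = c - t_arr
    if np.allclose(d, d[0]):
        if d[0] == 0:
            warnings.warn("identical vectors; t = 0, p = 1")
            return {"t": 0.0, "p": 1.0, "n": int(c.size)}
        warnings.warn("constant nonzero differences; p reported as 1")
        return {"t": float(np.sign(d[0]) * np.inf), "p": 1.0, "n": int(c.size)}
    res = stats.ttest_rel(c, t_arr)
    return {"t": float(res.statistic), "p": float(res.pvalue), "n": int(c.size)}


def promoter_loss_analysis(ctrl_reads: Sequence[ReadSet],
                           treated_reads: Sequence[ReadSet],
                           ctrl_rep_peaks: Sequence[Sequence[Peak]],
                           treated_rep_peaks: Sequence[Sequence[Peak]],
                           promoters: Mapping[str, GenomicInterval],
                           test_on: str = "filtered") -> PromoterLossResult:
    """Full promoter-loss procedure.

    Applies the peak-loss filter, then for each replicate pair computes
    normalized promoter densities in control and treated and the paired t.
    ``test_on='filtered'`` (default) tests only the lost promoters;
    ``test_on='all'`` tests every promoter.
    """
    if len(ctrl_reads) != len(treated_reads):
        raise ValueError("control and treated read sets must pair one-to-one")
    lost = lost_promoters(ctrl_rep_peaks, treated_rep_peaks, promoters)
    if test_on == "filtered":
        tested = {g: promoters[g] for g in lost}
    elif test_on == "all":
        tested = dict(promoters)
    else:
        raise ValueError("test_on must be 'filtered' or 'all'")
    genes = list(tested)
    regions = [tested[g] for g in genes]
    all_totals = [rs.total_reads for rs in (*ctrl_reads, *treated_reads)]

    per_rep: dict[str, dict[str, float]] = {}
    ctrl_rpk_acc = np.zeros(len(regions))
    trt_rpk_acc = np.zeros(len(regions))
    for c_set, t_set in zip(ctrl_reads, treated_reads):
        c_rpk = np.array([d.rpk for d in region_densities(c_set, regions, all_totals)])
        t_rpk = np.array([d.rpk for d in region_densities(t_set, regions, all_totals)])
        ctrl_rpk_acc += c_rpk
        trt_rpk_acc += t_rpk
        if len(regions) >= 2:
            per_rep[t_set.replicate_id or c_set.replicate_id] = paired_t(c_rpk, t_rpk)
    n_rep = max(len(ctrl_reads), 1)
    return PromoterLossResult(
        lost_genes=tuple(lost),
        per_replicate_t=per_rep,
        mean_control_rpk={g: v / n_rep for g, v in zip(genes, ctrl_rpk_acc)},
        mean_treated_rpk={g: v / n_rep for g, v in zip(genes, trt_rpk_acc)},
    )
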