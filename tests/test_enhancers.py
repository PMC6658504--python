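import io

import numpy as np
import pytest

from regnomics.enhancers import (
    Peak,
    RegulatoryCatalog,
    assign_genes,
    classify_and_venn,
    exclude_tss_peaks,
    read_narrowpeak,
    retain_consistent_peaks,
    se_threshold,
    stitch,
)
from regnomics.genome import GeneModel, GenomicInterval


def peak(start, end, signal=1.0, q=0.01, chrom="chr1", rep=""):
    return Peak(GenomicInterval(chrom, start, end), signal, q, replicate_id=rep)


class TestRetainConsistentPeaks:
    REPS = [
        [peak(100, 600, q=0.01), peak(5_000, 5_500, q=0.01)],
        [peak(150, 650, q=0.01)],
        [peak(90, 580, q=0.01)],
    ]

    def test_peak_in_all_replicates_kept(self):
        kept = retain_consistent_peaks(self.REPS)
        assert [p.interval.start for p in kept] == [100]

    def test_two_of_three_dropped(self):
        # the 5 kb peak has no partner in replicates 2 and 3
        kept = retain_consistent_peaks(self.REPS)
        assert all(p.interval.start != 5_000 for p in kept)

    def test_q_threshold_is_strict(self):
        reps = [[peak(100, 600, q=0.05)], [peak(100, 600, q=0.01)]]
        assert retain_consistent_peaks(reps) == []
        reps = [[peak(100, 600, q=0.01)], [peak(100, 600, q=0.06)]]
        assert retain_consistent_peaks(reps) == []

    def test_empty_replicate_list_rejected(self):
        with pytest.raises(ValueError):
            retain_consistent_peaks([])


class TestExcludeTssPeaks:
    def test_center_within_window_removed(self):
        p = peak(4_250, 4_750)  # center 4500, 500 bp from TSS 5000
        assert exclude_tss_peaks([p], [("chr1", 5_000)]) == []

    def test_center_just_outside_kept(self):
        p = peak(5_751, 6_251)  # center 6001, 1001 bp away
        assert exclude_tss_peaks([p], [("chr1", 5_000)]) == [p]

    def test_matches_brute_force_distance_check(self):
        rng = np.random.default_rng(23)
        tss = [("chr1", int(t)) for t in rng.integers(0, 100_000, 30)]
        peaks = [peak(int(s), int(s) + 400)
                 for s in rng.integers(0, 100_000, 200)]
        kept = exclude_tss_peaks(peaks, tss, window=1_000)
        expected = [p for p in peaks
                    if not any(abs(p.interval.center - t) <= 1_000
                               for _, t in tss)]
        assert kept == expected


class TestStitch:
    def test_gap_at_suture_distance_merges(self):
        regions = stitch([peak(0, 500), peak(12_900, 13_400)])  # gap 12,400
        assert len(regions) == 1
        assert (regions[0].interval.start, regions[0].interval.end) == (0, 13_400)

    def test_gap_beyond_suture_distance_splits(self):
        regions = stitch([peak(0, 500), peak(13_001, 13_501)])  # gap 12,501
        assert len(regions) == 2

    def test_transitive_chain(self):
        chain = [peak(0, 500), peak(10_500, 11_000), peak(21_000, 21_500)]
        regions = stitch(chain)
        assert len(regions) == 1
        assert regions[0].interval.end == 21_500
        assert regions[0].rank_signal == pytest.approx(3.0)

    def test_partition_of_peaks(self):
        rng = np.random.default_rng(29)
        peaks = [peak(int(s), int(s) + 300, signal=float(rng.exponential()))
                 for s in np.cumsum(rng.integers(1_000, 30_000, 50))]
        regions = stitch(peaks)
        assigned = [p for r in regions for p in r.component_peaks]
        assert sorted(assigned, key=lambda p: p.interval.start) == \
            sorted(peaks, key=lambda p: p.interval.start)
        # neighboring regions separated by more than the gap
        for a, b in zip(regions[:-1], regions[1:]):
            assert b.interval.start - a.interval.end > 12_500


class TestSeThreshold:
    def test_constant_signals_no_supers(self):
        regions = stitch([peak(i * 50_000, i * 50_000 + 500, signal=2.0)
                          for i in range(5)])
        with pytest.warns(UserWarning):
            flagged, _ = se_threshold(regions)
        assert not any(r.is_super for r in flagged)

    def test_single_outlier_called(self):
        peaks = [peak(i * 50_000, i * 50_000 + 500, signal=1.0)
                 for i in range(99)]
        peaks.append(peak(99 * 50_000, 99 * 50_000 + 500, signal=100.0))
        flagged, thr = se_threshold(stitch(peaks))
        supers = [r for r in flagged if r.is_super]
        assert len(supers) == 1
        assert supers[0].rank_signal == 100.0

    def test_threshold_is_max_distance_elbow(self):
        rng = np.random.default_rng(37)
        signals = np.concatenate([rng.exponential(1.0, 200),
                                  rng.uniform(30, 200, 10)])
        peaks = [peak(i * 50_000, i * 50_000 + 500, signal=float(s))
                 for i, s in enumerate(signals)]
        regions = stitch(peaks)
        flagged, thr = se_threshold(regions)
        # brute-force elbow: maximize scaled-rank minus scaled-signal
        s = np.sort(np.array([r.rank_signal for r in regions]))
        x = np.arange(len(s)) / (len(s) - 1)
        y = (s - s[0]) / (s[-1] - s[0])
        best = max(range(len(s)), key=lambda i: x[i] - y[i])
        assert thr == s[best]
        assert ({r.rank_signal for r in flagged if r.is_super}
                == set(s[s > s[best]]))

    def test_super_count_monotone_in_outlier_signal(self):
        def n_supers(top):
            peaks = [peak(i * 50_000, i * 50_000 + 500, signal=1.0 + 0.01 * i)
                     for i in range(50)]
            peaks.append(peak(50 * 50_000, 50 * 50_000 + 500, signal=top))
            flagged, _ = se_threshold(stitch(peaks))
            return sum(r.is_super for r in flagged)

        counts = [n_supers(t) for t in (100.0, 20.0, 5.0, 2.0)]
        assert counts == sorted(counts, reverse=True)


class TestAssignGenes:
    def gene(self, symbol, tss, strand="+"):
        return GeneModel(symbol, "chr1", strand, tss, tss + 1_000) \
            if strand == "+" else GeneModel(symbol, "chr1", strand, tss - 1_000, tss)

    def test_single_gene_within_domain(self):
        region = stitch([peak(1_000_000, 1_010_000)])[0]
        genes = [self.gene("NEAR", 1_060_000), self.gene("FAR", 5_000_000)]
        assert assign_genes(region, genes) == (("NEAR", 50_000),)

    def test_two_nearest_sorted_by_distance(self):
        region = stitch([peak(1_000_000, 1_010_000)])[0]
        genes = [self.gene("B", 1_210_000), self.gene("A", 1_020_000),
                 self.gene("C", 1_900_000)]
        result = assign_genes(region, genes)
        assert [g for g, _ in result] == ["A", "B"]

    def test_no_gene_within_domain(self):
        region = stitch([peak(1_000_000, 1_010_000)])[0]
        assert assign_genes(region, [self.gene("FAR", 3_000_000)]) == ()

    def test_tss_inside_region_distance_zero(self):
        region = stitch([peak(1_000_000, 1_010_000)])[0]
        assert assign_genes(region, [self.gene("IN", 1_005_000)]) == (("IN", 0),)


class TestClassifyAndVenn:
    def make_catalog(self):
        proms = (GenomicInterval("chr1", 1_000, 3_000),
                 GenomicInterval("chr1", 50_000, 52_000))
        peaks = [peak(200_000, 200_500, signal=1.0),
                 peak(300_000, 300_500, signal=50.0)]
        flagged, _ = se_threshold(stitch(peaks))
        return RegulatoryCatalog(
            promoters=proms,
            typical_enhancers=tuple(r for r in flagged if not r.is_super),
            super_enhancers=tuple(r for r in flagged if r.is_super))

    def test_both_factors_counted_once(self):
        catalog = self.make_catalog()
        a = [peak(1_500, 1_600)]
        b = [peak(1_550, 1_650)]
        venn = classify_and_venn(a, b, catalog)
        assert venn.counts["promoter"] == {"a_only": 0, "b_only": 0, "both": 1}

    def test_unbound_regions_uncounted(self):
        catalog = self.make_catalog()
        venn = classify_and_venn([], [], catalog)
        assert all(v == 0 for cat in venn.counts.values() for v in cat.values())

    def test_matches_brute_force_and_conserves(self):
        rng = np.random.default_rng(43)
        catalog = self.make_catalog()
        a = [peak(int(s), int(s) + 800) for s in rng.integers(0, 320_000, 25)]
        b = [peak(int(s), int(s) + 800) for s in rng.integers(0, 320_000, 25)]
        venn = classify_and_venn(a, b, catalog)
        from regnomics.genome import overlaps
        cats = {"promoter": list(catalog.promoters),
                "typical_enhancer": [r.interval for r in catalog.typical_enhancers],
                "super_enhancer": [r.interval for r in catalog.super_enhancers]}
        for cat, ivs in cats.items():
            a_only = b_only = both = bound_a = 0
            for iv in ivs:
                hit_a = any(overlaps(p.interval, iv) for p in a)
                hit_b = any(overlaps(p.interval, iv) for p in b)
                bound_a += hit_a
                if hit_a and hit_b:
                    both += 1
                elif hit_a:
                    a_only += 1
                elif hit_b:
                    b_only += 1
            assert venn.counts[cat] == {"a_only": a_only, "b_only": b_only,
                                        "both": both}
            assert venn.counts[cat]["a_only"] + venn.counts[cat]["both"] == bound_a


class TestNarrowPeak:
    def test_q_column_converted_from_neglog10(self):
        line = "chr1\t100\t600\tpeak1\t800\t.\t12.5\t30.0\t2.0\t250\n"
        peaks = read_narrowpeak(io.StringIO(line))
        assert peaks[0].signal == 12.5
        assert peaks[0].q_value == pytest.approx(0.01)
        assert (peaks[0].interval.start, peaks[0].interval.end) == (100, 600)

    def test_too_few_columns_rejected(self):
        with pytest.raises(ValueError):
            read_narrowpeak(io.StringIO("chr1\t100\t600\n"))
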