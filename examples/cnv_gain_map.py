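"""Map cohort copy-number gain frequency along a chromosome 17-like axis.

Generates a 209-sample array-CGH-style cohort, calls gains (copy number
strictly above 2.5), bins the chromosome at 100 kb, and classifies each
sample's 17q status as segmental / numerical / none.
"""

import io
from collections import Counter

from regnomics import GenomicInterval, make_bins
from regnomics.cnv import classify_17q, gain_contingency, gain_frequency_track, read_seg_csv
from regnomics.simulate import GeneratorConfig, gen_cn_cohort

cfg = GeneratorConfig(seed=0)
seg_df, truth = gen_cn_cohort(cfg)
cohort = read_seg_csv(io.StringIO(seg_df.to_csv(index=False)))

grid = make_bins(cfg.cn.chrom_length, 100_000, cfg.cn.chrom)
track = gain_frequency_track(cohort, grid)
q_bins = [i for i, b in enumerate(grid.bins) if b.start >= cfg.cn.centromere]
print(f"cohort: {len(cohort)} samples, {grid.n_bins} bins of 100 kb")
print(f"max gain frequency on the q arm: {track.frequency[q_bins].max():.3f}")

arms = {"p_arm": GenomicInterval(cfg.cn.chrom, 0, cfg.cn.centromere),
        "q_arm": GenomicInterval(cfg.cn.chrom, cfg.cn.centromere,
                                 cfg.cn.chrom_length)}
status = Counter(classify_17q(segs, arms) for segs in cohort.values())
print("17q classification:", dict(status))

gained = sum(1 for s in status.elements() if s != "none")
table = gain_contingency({"cohort": (gained, len(cohort))})
print(table.to_string(index=False))
print("-> the pooled percent is the cohort-wide 17q gain rate; near the "
      "generator's planted 82.3% frequency.")
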