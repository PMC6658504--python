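# regnomics

Analysis toolkit for regulatory-genomics studies of the kind built around a
candidate oncogene on a recurrently gained chromosome arm — the motivating
case is neuroblastoma, where gain of chromosome 17q is the most frequent
genomic lesion and the dosage, expression and downstream regulatory
activity of 17q genes carry prognostic weight. The package covers the
desk-side half of such a study end to end:

- **Copy-number gain mapping** (`regnomics.cnv`): call gains from SEG-like
  segment tables (copy number strictly > 2.5 on a diploid baseline), count
  per-100-kb-bin gain frequencies across a cohort, classify each tumor's
  17q status as segmental / numerical (whole-chromosome) / none, and pool
  subgroup gain counts into exact percentages.
- **Biomarker survival analytics** (`regnomics.survival`): Kaplan–Meier
  curves, two-sided log-rank tests, the Kaplan-scan search for the
  expression cutoff minimizing the log-rank p, median/upper-quartile
  dichotomization, multivariable Cox proportional hazards with
  HR = exp(β) and 95% CI = exp(β ± 1.96·SE), the composite Myc score
  (elementwise max of N-Myc and c-Myc expression), Pearson correlation,
  and the log(−log S(t)) vs log t proportionality diagnostic.
- **Super-enhancer calling** (`regnomics.enhancers`): replicate-consistent
  peak retention at FDR q < 0.05, ±1 kb TSS exclusion, stitching within
  12,500 bp, the geometric-inflection threshold on the min-max-scaled
  ranked-signal curve, ±1 Mb two-nearest-gene assignment, and two-factor
  co-occupancy Venn counts over promoters / typical enhancers /
  super-enhancers.
- **RNA Pol II promoter-loss statistics** (`regnomics.polii`): normalized
  reads per kilobase (count / region length / depth factor × 1000, with
  depth factor = file total / mean total across files), the
  both-control/neither-treated peak-loss filter, and per-replicate paired
  t-tests on the normalized densities.
- **Gene-set enrichment** (`regnomics.enrichment`): preranked running-sum
  enrichment scores with a gene-label permutation null (enriched at
  FDR q < 0.25) and hypergeometric overlap tests (significant at q < 0.05
  and p < 0.05), sharing one Benjamini–Hochberg implementation.
- **Drug-synergy quantification** (`regnomics.synergy`): viability
  normalization, four-parameter logistic fits, closed-form ICx inversion,
  isobolograms at the 85% inhibition level, and the Loewe combination
  index CI = d₁/IC85₁ + d₂/IC85₂ (1 = additive, < 1 = synergistic).
- **Assay calculators** (`regnomics.assays`): ΔΔCt fold change
  (2^(−ΔΔCt) against a housekeeping gene), ChIP-qPCR fold enrichment over
  IgG relative to input, densitometry normalization, and the
  (length × width × height)/2 tumor-volume formula.
- **Synthetic data** (`regnomics.simulate`): seeded generators producing
  cohorts, peak landscapes, read sets and dose-response plates with the
  statistical structure the analyses assume, each with a machine-readable
  truth object — so the entire pipeline is testable without any external
  download.

The public face of the package is its importable API plus the narrative
scripts in `examples/` (one per capability).

## Worked example

```bash
python examples/drug_synergy.py
```

```
additive surface (interaction 1.0):
  IC85 THZ1=23.80, panobinostat=47.61 (closed-form truth 23.80, 47.61)
  8 isobologram points, CI range [0.994, 1.051]
synergistic surface (interaction 0.5):
  IC85 THZ1=23.80, panobinostat=47.61 (closed-form truth 23.80, 47.61)
  7 isobologram points, CI range [0.497, 0.513]
```

The single-agent IC85 values recovered by the 4PL fit match the
closed-form inversion of the generating curves; on the Loewe-additive
surface every combination index sits at 1 (up to dose-grid interpolation),
while the surface generated with interaction parameter 0.5 yields CIs
clustered at 0.5 — the quantitative signature of two-fold synergy on an
isobologram.

Similarly, `examples/survival_biomarker.py` prints a multivariable Cox
table whose biomarker hazard ratio recovers the planted HR of 2.0 with
covariate intervals covering 1, and `examples/super_enhancers.py` shows
all 20 planted high-signal clusters called super among 500 background
regions.

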