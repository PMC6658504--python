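# Methods

This note documents the models and procedures implemented in `regnomics`,
the defaults that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Coordinates and formats

All coordinates are 0-based half-open, the native convention of BED and
refFlat; 1-based display is formatting only. Overlap is the strict
half-open predicate (`max(starts) < min(ends)`), so abutting intervals
share no base. Gene TSS is `txStart` on the + strand and `txEnd` on the −
strand; a promoter is `[TSS − flank, TSS + flank)` with flank 1,000 bp,
clipped at zero. Duplicate gene symbols keep all transcripts; a symbol's
promoter set is the union of its transcripts' windows, deduplicated by
identical intervals. Chromosome binning tiles `[0, chrom_length)` with
fixed-width bins (default 100 kb), the last bin truncated.

## Copy-number gain analysis

A segment is a gain when its copy number **strictly exceeds** 2.5
(diploid baseline 2.0). The cohort gain-frequency track counts, per bin,
the distinct samples with ≥ 1 gained segment overlapping the bin;
the denominator is the whole cohort including samples with no gains.

The segmental/numerical distinction is not standardized; the rule used
here is: *numerical* (whole-chromosome) gain requires the union of gained
bases to cover ≥ 90% of **both** chromosome arms; any q-arm gain short of
that is *segmental*; no q-arm gain is *none*. The 90% fraction is a
parameter (`whole_chrom_fraction`) and tolerates array edge effects at
telomeres and the centromere. This rule is a stand-in for whichever manual
or platform-specific assignment a given study used.

`mean_region_cn` is the length-weighted mean over the region with
uncovered bases imputed at 2.0 (parameter `baseline`); overlapping
segments resolve base-by-base with the later segment taking precedence.
Pooled gain percentages are computed from summed counts, never by
averaging subgroup percentages, and are reported at 2 decimal places.

## Survival analytics

Kaplan–Meier estimation is the standard product-limit estimator; subjects
censored exactly at an event time remain in the risk set for that event
(events processed first). The log-rank statistic is the 1-df chi-square
(via lifelines), two-sided. Cox models are fitted by maximizing the
partial likelihood through statsmodels `PHReg`; the tie correction
defaults to Efron with Breslow available. Hazard ratios are the antilogs
of the coefficients, intervals are Wald `exp(β ± 1.96·SE)` and p-values
two-sided Wald. No formal proportionality test is provided; the
`loglog_diagnostic` returns `(log t, log(−log S(t)))` series for the
visual parallel-curves check, dropping steps at S = 1 or S = 0 where the
transform is undefined.

The Kaplan scan evaluates every observed expression value inside the
10th–90th percentile band (parameters `lower_q`, `upper_q`) as a strict
`value > cutoff` split and returns the cutoff minimizing the two-sided
log-rank p. The restriction bounds the smaller group away from emptiness;
ties on p break toward the smaller high group, then the lower cutoff. The
reported minimum p is **unadjusted** for the multiplicity of the scan and
should be read as a selection criterion, not a calibrated significance
level. Dichotomization quantiles use linear interpolation between order
statistics; "high" is strictly above the cutoff, so constant inputs label
everything low.

The composite Myc score is the elementwise maximum of N-Myc and c-Myc
expression, reflecting their mutually exclusive expression pattern.

## Super-enhancer calling

The workflow consumes called peaks (e.g. MACS2 narrowPeak; the −log10
q-value column is converted to plain q internally) and never recomputes
read-level signal. Steps:

1. **Replicate consistency**: keep peaks with q **strictly** below 0.05
   that overlap a sub-threshold peak in *every* other replicate. The first
   replicate provides the reference coordinates (`reference="first"`);
   `reference="union"` keeps any replicate's consistent peaks.
2. **TSS exclusion**: remove peaks whose **center** lies within ±1,000 bp
   of any TSS (`mode="center"`); `mode="overlap"` removes on any-overlap.
3. **Stitching**: merge same-chromosome peaks transitively when the
   inter-peak gap is ≤ 12,500 bp (inclusive at the boundary). A region's
   ranking signal is the sum of its component peak signals as provided by
   the peak caller (input subtraction is assumed upstream).
4. **Threshold**: regions are ranked ascending by signal; rank and signal
   are each min-max scaled to [0, 1]. The threshold is the signal at the
   point where a line of slope 1 is tangent to the scaled curve —
   computed globally as the maximizer of (scaled rank − scaled signal).
   On the convex ranked curve this is exactly where the tangent slope
   first reaches 1; the global form is used instead of a local
   finite-difference crossing because a single large spacing in the
   heavy-tailed background otherwise produces a spurious early crossing.
   Regions strictly above the threshold are super-enhancers; constant
   signals yield zero super-enhancers with a warning.
5. **Gene assignment**: among genes whose TSS ± 1 Mb window overlaps the
   region, the two with the smallest TSS-to-region distance (0 if the TSS
   is inside) are listed, sorted by distance then symbol.
6. **Co-occupancy**: a catalog region counts as bound by a factor when
   ≥ 1 of that factor's (already replicate-filtered) peaks overlaps it;
   Venn cells count *regions* bound by A only / B only / both, per
   category.

## RNA Pol II promoter loss

Per-file depth normalization uses `f = file total / mean total across all
files`, so the factors average to 1 by construction. Normalized density is
`reads overlapping region / region length (bp) / f × 1000`; a read counts
with ≥ 1 bp of half-open overlap (no fractional weighting). A promoter is
*lost* when a peak is called within it in **both** control replicates and
in **no** treated replicate (replicate counts are configuration; the
reference design is 2 + 2). The paired t-test (`d = control − treated`,
n − 1 df, two-sided) is computed separately per replicate pair, by default
over the filtered promoters (`test_on="filtered"`; `"all"` tests every
promoter). Zero-variance differences report p = 1 with a warning rather
than failing.

## Gene-set enrichment

Preranked mode computes the weighted Kolmogorov–Smirnov running sum: hits
advance by `|metric|^weight` normalized over hits (weight 1 default;
weight 0 reduces to equal steps and makes the ES invariant under monotone
transformations of the metric), misses retreat by `1/(N − N_hits)`; the ES
is the extremum of largest magnitude. Because only a ranked list is
consumed, the null is **gene-label permutation** (seeded), not phenotype
permutation. NES divides the ES by the mean |null ES| of the same sign;
the nominal p is the same-sign permutation tail with the +1 correction;
q is Benjamini–Hochberg across the queried collection with the
conventional 0.25 call threshold. Overlap mode is the hypergeometric upper
tail with BH across sets and a significance flag at q < 0.05 **and**
p < 0.05. BH is implemented once (statsmodels `multipletests`) and shared.

## Drug synergy

The dose-response model is the four-parameter logistic
`v(d) = bottom + (top − bottom)/(1 + (d/ec50)^hill)`, fitted by
least squares with multi-start over the Hill-slope sign; a
bottom-0/top-100 constrained variant can be obtained by fixing those
readings upstream. ICx inverts the fit in closed form and refuses targets
outside the fitted asymptotes. Isobologram points are located per fixed
second-drug dose by monotone linear interpolation **in log-dose** along
the first-drug series; unreachable levels are excluded, never
extrapolated. The combination index is the two-term Loewe index
`d₁/IC_1 + d₂/IC_2` at the fixed effect level (85% inhibition by
default); the Chou–Talalay Dm/m parameterization is deliberately not
used. Tumor volume is the ellipsoid approximation
`length × width × height / 2`.

## Assay calculators

ΔΔCt assumes amplification efficiency 2 (perfect doubling; parameter).
ChIP-qPCR fold enrichment defaults to the input-ΔCt correction
`2^[(Ct_IgG − Ct_input,IgG) − (Ct_Ab − Ct_input,Ab)]`; a percent-input
ratio mode is provided since legends are often ambiguous between the two
(they coincide at shared efficiency).

## Synthetic data: what it emulates, and what it does not

One master seed expands into fixed per-generator substreams
(`SeedSequence(seed, spawn_key=(k,))`), so outputs are byte-identical for
a fixed config and adding a generator never perturbs existing fixtures.
Every generator returns a truth object for downstream recall/precision
scoring.

- **CN cohort** (default n = 209, gain probability 0.823, hg19-like
  chr17 geometry): gained windows carry CN ~ U(2.6, 5); 30% of gains are
  whole-chromosome (numerical), the rest run from a random q-arm
  breakpoint to the telomere; the non-gained genome is diploid with
  Gaussian noise (sd 0.1). Not emulated: probe-level noise, GC waves,
  focal amplifications, subclonality.
- **Survival cohort** (default n = 476, biomarker HR 2.0, censoring 0.3):
  log-normal biomarker, exponential event times with the hazard doubled
  above the biomarker median, uniform censoring on [0, c_max] with c_max
  calibrated by bisection to the requested marginal censoring fraction.
  N-Myc/c-Myc are generated with latent correlation 0.5 to the biomarker,
  which places the Pearson R of the composite (max) score near 0.45. The
  three clinical covariates default to prevalence-only (no independent
  hazard), so a biomarker-only Cox model is correctly specified; per-
  covariate log-HRs are parameters. Not emulated: non-proportional
  hazards, informative censoring, cohort heterogeneity.
- **Peak landscape** (500 background + 20 planted clusters + 30 decoys,
  3 replicates): background regions are isolated peaks with Exp(1)
  signal; planted clusters of 4 peaks (internal gaps 3 kb, well under the
  stitch distance) have stitched signal `20 × (1 + Exp(1) × 4)` — the
  floor of 20 separates them from the background and the heavy tail
  reproduces the hockey-stick shape of real ranked-signal curves, which
  is what makes a geometric-inflection threshold well-posed; with all
  planted signals within a factor of two of the floor, any tangent rule
  would place the cutoff several ranks into an exponential background
  tail. Replicates jitter positions by ≤ 50 bp (peaks are 500 bp, so
  overlap is preserved); decoys carry q ≥ 0.05 everywhere and must
  vanish at retention. Genes are placed between peak slots, ≥ 19 kb from
  any peak. Not emulated: read-level signal, fragment pile-up shapes,
  copy-number-driven signal bias.
- **Pol II reads** (1,000 promoters of 2 kb, control density 40 reads/kb,
  2 + 2 replicates): per-promoter Poisson counts; a planted 5% of
  promoters lose 60% of treated density; reads are 50-mers placed
  uniformly within the promoter. Peak files are derived by thresholding
  per-promoter counts at 60% of the expected control count — midway
  between the control mean and the depleted treated mean, giving
  near-deterministic peak presence/absence on either side. Not emulated:
  background (non-promoter) reads, fragment-length structure, duplicate
  reads.
- **Dose-response plate** (4PL pairs ec50 10/20, hill 2, 8×8 log2 grid,
  3 replicates, noise sd 1): combination viability at (d₁, d₂) solves
  `d₁/D₁(v) + d₂/D₂(v) = ψ` by Brent's method (tolerance 1e−12), where
  `D_i(v)` is the single-agent inverse; ψ = 1 is exact Loewe additivity
  and ψ < 1 synergy. The plate additionally carries three-point series
  bracketing the exact isobole dose pairs at the 85% level (the points an
  isobologram plots); on those the noiseless additive surface returns
  CI = 1 to machine precision, whereas CIs interpolated at off-isobole
  grid points carry a few percent of log-linear interpolation error that
  shrinks with grid resolution. Not emulated: plate-position effects,
  replicate drift.

Because the generators plant exactly the structure the analyses look for,
passing tests demonstrate the correctness and calibration of the
procedures under their stated assumptions — not robustness to the many
real-data violations listed above.

## Problem sizes in the test suite

The suite runs the generators at their reference scales (209-sample CN
cohort, 476/500-sample survival cohorts, 520-region landscapes,
1,000-promoter read sets) and uses 200 replicates of n = 500 for the Cox
coverage calibration — chosen as the smallest design that pins the 95%
interval's coverage to within a few percent.
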