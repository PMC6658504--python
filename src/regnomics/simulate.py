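"""Seeded synthetic-data generators.

Each generator emulates one class of study input at its reference scale —
an array-CGH cohort of 209 tumors with 17q gains, an expression + outcome
cohort with a known biomarker hazard ratio, a three-replicate H3K27ac peak
landscape with planted super-enhancer clusters, paired control/treated RNA
Pol II read sets with a planted promoter-density reduction, and a
dose-response plate following a Loewe interaction model — and every
generator returns a machine-readable truth object so recovery rates can be
scored downstream.

Determinism contract: a fixed :class:`GeneratorConfig` (including the
seed) yields byte-identical outputs.  The global seed expands into
independent per-generator substreams, so adding a generator never perturbs
existing fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GeneModel, GenomicInterval
from .enhancers import Peak
from .polii import ReadSet

__all__ = [
    "GeneratorConfig",
    "CnCohortConfig",
    "SurvivalCohortConfig",
    "PeakscapeConfig",
    "PolIIConfig",
    "PlateConfig",
    "gen_cn_cohort",
    "gen_survival_cohort",
    "gen_peakscape",
    "gen_polii_reads",
    "gen_dose_response",
]

# fixed substream ids: adding a generator appends a new id, never renumbers
_STREAM_CN, _STREAM_SURV, _STREAM_PEAKS, _STREAM_POLII, _STREAM_PLATE = range(5)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class CnCohortConfig:
    """Array-CGH-like cohort: 209 tumors, gains on a 17-like chromosome.

    Chromosome geometry follows hg19 chr17 (81.2 Mb, centromere ~24 Mb);
    gained copy numbers are uniform in [2.6, 5]; non-gained genome is
    diploid with Gaussian noise (sd 0.1)."""

    n_samples: int = 209
    p_gain: float = 0.823          # cohort gain frequency at the reference scale
    numerical_weight: float = 0.3  # fraction of gains that are whole-chromosome
    chrom: str = "chr17"
    chrom_length: int = 81_195_210
    centromere: int = 24_000_000
    cn_noise_sd: float = 0.1


@dataclass(frozen=True)
class SurvivalCohortConfig:
    """Expression + outcome cohort with a planted biomarker hazard ratio.

    The biomarker is log-normal; subjects above its median carry
    ``hazard_ratio`` times the baseline exponential hazard.  Censoring
    times are uniform on [0, c_max] with c_max calibrated to the requested
    censoring fraction.  N-Myc / c-Myc expression are generated correlated
    with the biomarker so the composite Myc score reproduces a positive
    Pearson correlation."""

    n_samples: int = 476
    hazard_ratio: float = 2.0
    baseline_hazard: float = 1.0 / 36.0   # per month; median OS ~ 2 years low-risk
    censor_rate: float = 0.3
    # latent per-gene correlation with the biomarker; 0.5 puts the Pearson R
    # of the composite (max) Myc score near the 0.45 seen in real cohorts
    myc_correlation: float = 0.5
    prev_mycn_amp: float = 0.14
    prev_age_gt_18m: float = 0.5
    prev_stage_unfav: float = 0.45
    covariate_log_hrs: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass(frozen=True)
class PeakscapeConfig:
    """H3K27ac-like landscape: isolated background peaks with Exponential(1)
    signal plus planted multi-peak clusters whose stitched signal exceeds a
    floor, in three replicates with <= 50 bp positional jitter."""

    n_background: int = 500
    n_planted: int = 20
    planted_signal_floor: float = 20.0
    # stitched planted signal = floor * (1 + Exp(1) * tail); the heavy tail
    # reproduces the hockey-stick shape of real ranked-signal curves, where
    # the strongest super-enhancers dominate the scale
    planted_signal_tail: float = 4.0
    n_decoys: int = 30            # q >= 0.05, must disappear at retention
    n_replicates: int = 3
    peak_width: int = 500
    cluster_peaks: int = 4
    cluster_gap: int = 3_000      # internal gaps, well under the stitch distance
    spacing: int = 40_000         # slot spacing keeps distinct regions unstitched
    jitter: int = 50
    n_genes: int = 60
    chrom: str = "chr1"


@dataclass(frozen=True)
class PolIIConfig:
    """Paired Pol II ChIP read sets: Poisson promoter counts at 40 reads/kb
    in control; a planted fraction of promoters loses ``loss_depth`` of its
    treated-condition density.  Peak files are derived by thresholding
    per-promoter counts at ``peak_threshold_frac`` of the expected control
    count."""

    n_promoters: int = 1000
    loss_fraction: float = 0.05
    loss_depth: float = 0.6
    control_rpk: float = 40.0
    promoter_width: int = 2_000
    read_length: int = 50
    n_replicates: int = 2
    peak_threshold_frac: float = 0.6
    chrom: str = "chr2"
    spacing: int = 10_000


@dataclass(frozen=True)
class PlateConfig:
    """Dose-response plate under a Loewe interaction model.

    Single agents follow 4PL curves; the combination viability at (d1, d2)
    is the effect level v solving d1/D1(v) + d2/D2(v) = interaction, so
    interaction 1 is exact Loewe additivity and 0.5 is two-fold synergy."""

    ec50_1: float = 10.0
    ec50_2: float = 20.0
    hill_1: float = 2.0
    hill_2: float = 2.0
    top: float = 100.0
    bottom: float = 0.0
    interaction: float = 1.0
    n_doses: int = 8
    dose_span_log2: tuple[float, float] = (-3.0, 4.0)  # doses = ec50 * 2^span
    noise_sd: float = 1.0
    n_replicates: int = 3
    # extra combination series bracketing the exact dose pairs on the
    # interaction isobole at this level, as an isobologram would plot
    anchor_level: float = 85.0
    anchor_fractions: tuple[float, ...] = (0.25, 0.5, 0.75)


@dataclass(frozen=True)
class GeneratorConfig:
    """Master configuration: one seed, one sub-config per generator."""

    seed: int = 0
    cn: CnCohortConfig = field(default_factory=CnCohortConfig)
    survival: SurvivalCohortConfig = field(default_factory=SurvivalCohortConfig)
    peaks: PeakscapeConfig = field(default_factory=PeakscapeConfig)
    polii: PolIIConfig = field(default_factory=PolIIConfig)
    plate: PlateConfig = field(default_factory=PlateConfig)


# ---------------------------------------------------------------- CN cohort

def gen_cn_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Synthetic array-CGH cohort as a SEG-like table plus truth sidecar.

    Returns (segments DataFrame with sample_id/chrom/start/end/copy_number,
    truth dict per sample: gained flag and geometry).
    """
    c = config.cn
    if not 0 <= c.p_gain <= 1 or not 0 <= c.numerical_weight <= 1:
        raise ValueError("probabilities must lie in [0, 1]")
    rng = _rng(config.seed, _STREAM_CN)
    rows = []
    truth = {}
    q_start, q_end = c.centromere, c.chrom_length
    for i in range(c.n_samples):
        sid = f"S{i:04d}"
        gained = bool(rng.random() < c.p_gain)
        geometry = "none"
        if gained:
            cn = float(rng.uniform(2.6, 5.0))
            if rng.random() < c.numerical_weight:
                geometry = "numerical"
                gain_start, gain_end = 0, c.chrom_length
            else:
                geometry = "segmental"
                # breakpoint in the proximal 80% of the q arm, gain to qter
                gain_start = int(rng.uniform(q_start, q_start + 0.8 * (q_end - q_start)))
                gain_end = q_end
            rows.append((sid, c.chrom, gain_start, gain_end, cn))
            # diploid remainder
            if gain_start > 0:
                rows.append((sid, c.chrom, 0, gain_start,
                             max(float(rng.normal(2.0, c.cn_noise_sd)), 0.0)))
        else:
            rows.append((sid, c.chrom, 0, c.chrom_length,
                         max(float(rng.normal(2.0, c.cn_noise_sd)), 0.0)))
        truth[sid] = {"gained": gained, "geometry": geometry}
    df = pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end",
                                     "copy_number"])
    return df, truth


# ---------------------------------------------------------- survival cohort

def _calibrate_cmax(hazards: np.ndarray, censor_rate: float) -> float:
    """c_max of Uniform(0, c_max) censoring giving the requested marginal
    censoring fraction against exponential event times."""

    def censored_fraction(cmax: float) -> float:
        # P(C < T) with C ~ U(0, cmax), T ~ Exp(lambda): (1 - e^(-l c))/(l c)
        lam = hazards * cmax
        return float(np.mean((1.0 - np.exp(-lam)) / lam))

    lo, hi = 1e-6, 1e6
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if censored_fraction(mid) > censor_rate:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def gen_survival_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Synthetic expression + clinical cohort table plus truth sidecar."""
    s = config.survival
    rng = _rng(config.seed, _STREAM_SURV)
    n = s.n_samples
    z = rng.normal(size=n)
    jmjd6 = np.exp(z)  # log-normal biomarker
    rho = s.myc_correlation
    nmyc = np.exp(rho * z + np.sqrt(1 - rho ** 2) * rng.normal(size=n))
    cmyc = np.exp(rho * z + np.sqrt(1 - rho ** 2) * rng.normal(size=n))

    high = jmjd6 > np.median(jmjd6)
    mycn_amp = rng.random(n) < s.prev_mycn_amp
    age = rng.random(n) < s.prev_age_gt_18m
    stage = rng.random(n) < s.prev_stage_unfav
    log_hr_cov = np.array(s.covariate_log_hrs)
    covariate_term = (mycn_amp * log_hr_cov[0] + age * log_hr_cov[1]
                      + stage * log_hr_cov[2])
    hazards = s.baseline_hazard * (s.hazard_ratio ** high) * np.exp(covariate_term)

    def draw_endpoint() -> tuple[np.ndarray, np.ndarray]:
        t_event = rng.exponential(1.0 / hazards)
        if s.censor_rate <= 0:
            return t_event, np.ones(n, dtype=bool)
        cmax = _calibrate_cmax(hazards, s.censor_rate)
        t_cens = rng.uniform(0, cmax, size=n)
        observed = np.minimum(t_event, t_cens)
        return np.maximum(observed, 1e-6), t_event <= t_cens

    os_t, os_e = draw_endpoint()
    efs_t, efs_e = draw_endpoint()
    df = pd.DataFrame({
        "sample_id": [f"P{i:04d}" for i in range(n)],
        "JMJD6": jmjd6, "NMYC": nmyc, "CMYC": cmyc,
        "mycn_amplified": mycn_amp, "age_gt_18m": age,
        "stage_unfavorable": stage,
        "os_time": os_t, "os_event": os_e,
        "efs_time": efs_t, "efs_event": efs_e,
    })
    truth = {"hazard_ratio": s.hazard_ratio, "high_group": high.tolist(),
             "censor_rate": s.censor_rate}
    return df, truth


# -------------------------------------------------------------- peakscape

def gen_peakscape(config: GeneratorConfig
                  ) -> tuple[list[list[Peak]], list[GeneModel], dict]:
    """Three-replicate peak landscape with planted super-enhancer clusters.

    Returns (per-replicate peak lists, gene models for the TSS/assignment
    steps, truth dict with planted cluster spans and decoy count).
    """
    p = config.peaks
    rng = _rng(config.seed, _STREAM_PEAKS)

    # lay out slots left to right: background singles, planted clusters
    # interleaved, decoys at the far end; slot spacing >> stitch distance
    n_slots = p.n_background + p.n_planted + p.n_decoys
    slot_starts = (1 + np.arange(n_slots)) * p.spacing
    slot_kind = np.array(["bg"] * p.n_background + ["planted"] * p.n_planted
                         + ["decoy"] * p.n_decoys)
    rng.shuffle(slot_kind)

    base_peaks: list[tuple[int, int, float, float, str]] = []  # start,end,sig,q,kind
    planted_spans = []
    for start, kind in zip(slot_starts, slot_kind):
        start = int(start)
        if kind == "planted":
            total = float(p.planted_signal_floor
                          * (1.0 + rng.exponential(p.planted_signal_tail)))
            split = rng.dirichlet(np.ones(p.cluster_peaks)) * total
            pos = start
            for sig in split:
                base_peaks.append((pos, pos + p.peak_width, float(sig),
                                   float(rng.uniform(1e-6, 0.04)), kind))
                pos += p.peak_width + p.cluster_gap
            planted_spans.append((start, pos - p.cluster_gap))
        elif kind == "bg":
            base_peaks.append((start, start + p.peak_width,
                               float(rng.exponential(1.0)),
                               float(rng.uniform(1e-6, 0.04)), kind))
        else:  # decoy: fails the FDR filter in every replicate
            base_peaks.append((start, start + p.peak_width,
                               float(rng.exponential(1.0)),
                               float(rng.uniform(0.05, 0.5)), kind))

    replicates: list[list[Peak]] = []
    for r in range(p.n_replicates):
        peaks = []
        for start, end, sig, q, kind in base_peaks:
            j = int(rng.integers(-p.jitter, p.jitter + 1)) if r > 0 else 0
            peaks.append(Peak(
                interval=GenomicInterval(p.chrom, start + j, end + j),
                signal=sig * float(rng.uniform(0.9, 1.1)) if r > 0 else sig,
                q_value=q, replicate_id=f"rep{r + 1}", mark_or_factor="H3K27ac"))
        replicates.append(peaks)

    # genes placed between slots so no TSS sits within 1 kb of a peak
    genome_end = int(slot_starts[-1]) + p.spacing
    gene_positions = rng.choice(np.arange(1, n_slots), size=p.n_genes,
                                replace=False)
    genes = []
    for gi, slot in enumerate(np.sort(gene_positions)):
        tss = int(slot * p.spacing + p.spacing // 2)
        strand = "+" if rng.random() < 0.5 else "-"
        tx_start, tx_end = (tss, tss + 5000) if strand == "+" else (tss - 5000, tss)
        genes.append(GeneModel(symbol=f"GENE{gi:03d}", chrom=p.chrom,
                               strand=strand, tx_start=tx_start, tx_end=tx_end))
    truth = {"planted_spans": planted_spans, "n_decoys": p.n_decoys,
             "genome_end": genome_end}
    return replicates, genes, truth


# ------------------------------------------------------------ Pol II reads

def gen_polii_reads(config: GeneratorConfig
                    ) -> tuple[list[ReadSet], list[ReadSet],
                               list[list[Peak]], list[list[Peak]],
                               dict[str, GenomicInterval], pd.DataFrame]:
    """Paired Pol II read sets, derived peak files, promoters and truth.

    Returns (control ReadSets, treated ReadSets, control peak sets, treated
    peak sets, promoter map, truth table with one row per promoter).
    """
    c = config.polii
    rng = _rng(config.seed, _STREAM_POLII)
    promoters: dict[str, GenomicInterval] = {}
    for i in range(c.n_promoters):
        start = (1 + i) * c.spacing
        promoters[f"G{i:04d}"] = GenomicInterval(c.chrom, start,
                                                 start + c.promoter_width)
    lost = np.zeros(c.n_promoters, dtype=bool)
    n_lost = int(round(c.loss_fraction * c.n_promoters))
    lost[rng.choice(c.n_promoters, size=n_lost, replace=False)] = True

    mean_reads = c.control_rpk * c.promoter_width / 1000.0
    peak_cut = c.peak_threshold_frac * mean_reads

    def one_file(condition: str, rep: int) -> tuple[ReadSet, list[Peak]]:
        reads: list[GenomicInterval] = []
        peaks: list[Peak] = []
        for i, (gene, prom) in enumerate(promoters.items()):
            mu = mean_reads
            if condition == "treated" and lost[i]:
                mu *= (1.0 - c.loss_depth)
            k = int(rng.poisson(mu))
            if k:
                starts = rng.integers(prom.start, prom.end - c.read_length,
                                      size=k)
                reads.extend(GenomicInterval(c.chrom, int(s), int(s) + c.read_length)
                             for s in np.sort(starts))
            if k >= peak_cut:
                peaks.append(Peak(interval=prom, signal=float(k), q_value=0.01,
                                  replicate_id=f"rep{rep}",
                                  mark_or_factor="POLR2A"))
        rs = ReadSet(sample_id=f"{condition}_rep{rep}", condition=condition,
                     replicate_id=f"rep{rep}", reads=tuple(reads))
        return rs, peaks

    ctrl_reads, ctrl_peaks, trt_reads, trt_peaks = [], [], [], []
    for rep in range(1, c.n_replicates + 1):
        rs, pk = one_file("control", rep)
        ctrl_reads.append(rs)
        ctrl_peaks.append(pk)
    for rep in range(1, c.n_replicates + 1):
        rs, pk = one_file("treated", rep)
        trt_reads.append(rs)
        trt_peaks.append(pk)
    truth = pd.DataFrame({"gene": list(promoters), "lost": lost})
    return ctrl_reads, trt_reads, ctrl_peaks, trt_peaks, promoters, truth


# ------------------------------------------------------------- dose plate

def _single_agent_dose(v: float, ec50: float, hill: float,
                       top: float, bottom: float) -> float:
    return ec50 * ((top - v) / (v - bottom)) ** (1.0 / hill)


def _loewe_viability(d1: float, d2: float, cfg: PlateConfig) -> float:
    """Viability at (d1, d2), both doses positive, under the Loewe
    interaction model: the level v where d1/D1(v) + d2/D2(v) equals the
    interaction parameter (1 = additivity, < 1 = synergy)."""
    from scipy.optimize import brentq

    def g(v: float) -> float:
        acc = -cfg.interaction
        if d1 > 0:
            acc += d1 / _single_agent_dose(v, cfg.ec50_1, cfg.hill_1,
                                           cfg.top, cfg.bottom)
        if d2 > 0:
            acc += d2 / _single_agent_dose(v, cfg.ec50_2, cfg.hill_2,
                                           cfg.top, cfg.bottom)
        return acc

    # g is increasing in v: g(bottom+) -> -interaction, g(top-) -> +inf,
    # so a unique root exists in the open response range
    lo = cfg.bottom + 1e-9 * (cfg.top - cfg.bottom)
    hi = cfg.top - 1e-9 * (cfg.top - cfg.bottom)
    return float(brentq(g, lo, hi, xtol=1e-12))


def gen_dose_response(config: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Dose-response plate CSV rows plus truth sidecar.

    Single-agent rows carry the other drug at dose 0; the combination block
    is the full dose grid.  With interaction 1 the surface is exactly Loewe
    additive; values below 1 are synergistic by construction.
    """
    p = config.plate
    rng = _rng(config.seed, _STREAM_PLATE)
    span = np.linspace(p.dose_span_log2[0], p.dose_span_log2[1], p.n_doses)
    doses1 = p.ec50_1 * 2.0 ** span
    doses2 = p.ec50_2 * 2.0 ** span

    rows = []

    def emit(d1: float, d2: float) -> None:
        if d1 == 0 and d2 == 0:
            v = p.top
        elif d2 == 0:
            v = float(p.bottom + (p.top - p.bottom)
                      / (1 + (d1 / p.ec50_1) ** p.hill_1))
        elif d1 == 0:
            v = float(p.bottom + (p.top - p.bottom)
                      / (1 + (d2 / p.ec50_2) ** p.hill_2))
        else:
            v = _loewe_viability(d1, d2, p)
        for rep in range(1, p.n_replicates + 1):
            noise = float(rng.normal(0, p.noise_sd)) if p.noise_sd > 0 else 0.0
            rows.append({"drug1_dose": d1, "drug2_dose": d2,
                         "viability_percent": max(v + noise, 0.0),
                         "replicate": rep})

    for d1 in doses1:
        emit(float(d1), 0.0)
    for d2 in doses2:
        emit(0.0, float(d2))
    for d1 in doses1:
        for d2 in doses2:
            emit(float(d1), float(d2))
    # combination series through the exact isobole points at the anchor
    # level: with interaction psi the pair (lam*psi*D1, (1-lam)*psi*D2)
    # produces exactly the anchor effect under the Loewe model
    v_star = 100.0 - p.anchor_level
    if p.bottom < v_star < p.top:
        d1_ref = _single_agent_dose(v_star, p.ec50_1, p.hill_1, p.top, p.bottom)
        d2_ref = _single_agent_dose(v_star, p.ec50_2, p.hill_2, p.top, p.bottom)
        for lam in p.anchor_fractions:
            d1_star = lam * p.interaction * d1_ref
            d2_star = (1 - lam) * p.interaction * d2_ref
            for scale in (0.5, 1.0, 2.0):
                emit(scale * d1_star, d2_star)
    truth = {"interaction": p.interaction,
             "ic85_1": _single_agent_dose(100 - 85.0, p.ec50_1, p.hill_1,
                                          p.top, p.bottom),
             "ic85_2": _single_agent_dose(100 - 85.0, p.ec50_2, p.hill_2,
                                          p.top, p.bottom)}
    return pd.DataFrame(rows), truth


def write_truth_json(truth: dict, path: str) -> None:
    """Persist a generator's truth sidecar as JSON."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
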