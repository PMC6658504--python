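"""Gene-set enrichment: preranked running-sum analysis and hypergeometric
overlap tests, with Benjamini-Hochberg FDR control.

The preranked mode consumes a list of genes sorted by a ranking metric
(e.g. log fold change) and computes the weighted Kolmogorov-Smirnov
running-sum enrichment score; significance comes from gene-label
permutations and NES normalizes the ES by the mean same-sign null
magnitude.  A set is conventionally called enriched at FDR q < 0.25.
The overlap mode tests a query gene list against sets in a universe with
the hypergeometric upper tail; sets are flagged significant at q < 0.05
and p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, TextIO

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "enrichment_score",
    "preranked_gsea",
    "overlap_enrichment",
    "bh_adjust",
    "read_gmt",
    "read_ranked_csv",
]

GSEA_FDR_CUTOFF = 0.25        # preranked significance convention
OVERLAP_Q_CUTOFF = 0.05
OVERLAP_P_CUTOFF = 0.05


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-set enrichment table; columns depend on the mode."""

    table: pd.DataFrame  # index: set name


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enrichment_score(ranked_genes: Sequence[str], gene_set: set[str],
                     metric: Sequence[float] | None = None,
                     weight: float = 1.0) -> float:
    """Weighted KS running-sum enrichment score over a ranked gene list.

    Hits increment the running sum by |metric|^weight (normalized over
    hits); misses decrement by 1/(N - Nh).  The ES is the running-sum
    extremum of largest magnitude.  With weight = 0 every hit counts
    equally and the ES depends only on hit positions.
    """
    genes = list(ranked_genes)
    n = len(genes)
    hits = np.array([g in gene_set for g in genes])
    nh = int(hits.sum())
    if nh == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if nh == n:
        raise ValueError("gene set covers the whole ranked list")
    if metric is None or weight == 0:
        w = np.ones(n)
    else:
        w = np.abs(np.asarray(metric, dtype=float)) ** weight
    hit_w = np.where(hits, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        hit_w = hits.astype(float)
        denom = float(nh)
    step = hit_w / denom - (~hits) / (n - nh)
    running = np.cumsum(step)
    return float(running[np.argmax(np.abs(running))])


def preranked_gsea(ranked_genes: Sequence[str],
                   gene_sets: Mapping[str, set[str]],
                   metric: Sequence[float] | None = None,
                   n_perm: int = 1000, weight: float = 1.0,
                   seed: int = 0) -> EnrichmentResult:
    """Preranked enrichment over a collection of gene sets.

    The null distribution comes from gene-label permutations of the ranked
    list (the metric profile stays in place; set membership is shuffled).
    NES = ES / mean(|null ES| of the same sign); nominal p is the same-sign
    null tail fraction; q is BH across the collection.
    """
    rng = np.random.default_rng(seed)
    genes = list(ranked_genes)
    n = len(genes)
    rows = []
    for name, gs in gene_sets.items():
        members = set(genes) & gs
        es = enrichment_score(genes, members, metric, weight)
        nh = len(members)
        null = np.empty(n_perm)
        for i in range(n_perm):
            perm_members = set(rng.choice(n, size=nh, replace=False))
            perm_set = {genes[j] for j in perm_members}
            null[i] = enrichment_score(genes, perm_set, metric, weight)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if same_sign.size == 0:
            nes = np.nan
            p = 1.0 / (n_perm + 1)
        else:
            nes = es / np.mean(np.abs(same_sign))
            p = (np.sum(np.abs(same_sign) >= abs(es)) + 1) / (same_sign.size + 1)
        rows.append({"set": name, "size": nh, "es": es, "nes": nes, "p": p})
    table = pd.DataFrame(rows).set_index("set")
    table["q"] = bh_adjust(table["p"])
    table["significant"] = table["q"] < GSEA_FDR_CUTOFF
    return EnrichmentResult(table=table)


def overlap_enrichment(query_genes: Sequence[str],
                       gene_sets: Mapping[str, set[str]],
                       universe: Sequence[str]) -> EnrichmentResult:
    """Hypergeometric overlap enrichment of a query list against gene sets.

    For a universe of size N, a set of size K and a query of size n with k
    overlapping genes, p = P(X >= k) under Hypergeometric(N, K, n).  BH q
    across sets; a set is significant at q < 0.05 and p < 0.05.
    """
    uni = set(universe)
    query = set(query_genes)
    if not query <= uni:
        raise ValueError("query genes must be a subset of the universe")
    rows = []
    for name, gs in gene_sets.items():
        if not gs <= uni:
            raise ValueError(f"gene set {name!r} is not a subset of the universe")
        k = len(query & gs)
        p = float(stats.hypergeom.sf(k - 1, len(uni), len(gs), len(query)))
        rows.append({"set": name, "set_size": len(gs), "overlap": k, "p": p})
    table = pd.DataFrame(rows).set_index("set")
    table["q"] = bh_adjust(table["p"])
    table["significant"] = (table["q"] < OVERLAP_Q_CUTOFF) & (table["p"] < OVERLAP_P_CUTOFF)
    return EnrichmentResult(table=table)


def read_gmt(source: str | TextIO) -> dict[str, set[str]]:
    """GMT gene-set file: name <tab> description <tab> gene1 <tab> ..."""
    close = False
    if isinstance(source, str):
        handle: TextIO = open(source)
        close = True
    else:
        handle = source
    sets: dict[str, set[str]] = {}
    try:
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = set(g for g in fields[2:] if g)
    finally:
        if close:
            handle.close()
    return sets


def read_ranked_csv(source: str | TextIO) -> pd.DataFrame:
    """Ranked list CSV with columns (gene, metric), sorted descending by
    metric on load."""
    df = pd.read_csv(source)
    if not {"gene", "metric"} <= set(df.columns):
        raise ValueError("ranked CSV requires 'gene' and 'metric' columns")
    return df.sort_values("metric", ascending=False).reset_index(drop=True)
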