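"""Core-enriched-gene accounting across methods and the composite
cross-dataset method score.

Leading-edge ("core-enriched") genes from significant pathways are counted
two ways per direction: deduplicated (the union of leading edges) and
non-deduplicated (the sum of leading-edge sizes over pathways). Genes
recurring in >= 2 same-direction pathways are *super core* genes; they are
exactly what drives the two counts apart, so comparing the
positive/negative ratio before and after deduplication exposes
direction-specific amplification by redundant pathways. When no gene
recurs, the two ratios coincide.

Group-level comparisons use the Kruskal-Wallis test followed by pairwise
two-sided Wilcoxon rank-sum tests with Benjamini-Hochberg adjustment.

The composite per-dataset method score (labelled ``surrogate-v1`` in all
outputs) rewards a method for (a) completing enrichment at all, (b)
gene-level/pathway-level directional concordance and (c) pathway-direction
balance: per target and repeat the contribution is 0 if the repeat produced
no significant pathways, else ``(1 - |f_path - f_gene|) * (1 - 2|f_path -
0.5|)`` where ``f_path`` is the repeat's activated-pathway fraction and
``f_gene`` the target's positive-correlate fraction; the score is the mean
contribution, in [0, 1], maximal only at perfect balance and concordance
with no failures.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gsea_prerank import ACTIVATED, SUPPRESSED, EnrichmentRecord

__all__ = ["CoreGeneStats", "MethodScore", "quantify_core", "unique_vs_shared",
           "kruskal_wallis", "wilcoxon_pairwise", "composite_score",
           "method_score"]

COMPOSITE_SCORE_VERSION = "surrogate-v1"


@dataclass
class CoreGeneStats:
    """Per-method leading-edge accounting for one direction."""

    method: str
    direction: str
    dedup_genes: set[str]
    nondedup_count: int
    super_core: dict[str, int]     # gene -> number of pathways (>= 2)
    ratio_dedup: float             # activated/suppressed dedup counts
    ratio_nondedup: float


def _direction_counts(records: Sequence[EnrichmentRecord], direction: str):
    edges = [r.leading_edge for r in records if r.direction == direction]
    counts = Counter(g for edge in edges for g in edge)
    dedup = set(counts)
    nondedup = sum(counts.values())
    super_core = {g: c for g, c in sorted(counts.items()) if c >= 2}
    return dedup, nondedup, super_core


def _ratio(num: float, den: float) -> float:
    return num / den if den else float("nan")


def quantify_core(records: Sequence[EnrichmentRecord],
                  method: str) -> dict[str, CoreGeneStats]:
    """Deduplicated/non-deduplicated leading-edge counts, ratios and super
    core genes, keyed by direction.

    The ratios (activated/suppressed totals) are shared by both directions'
    stats; a NaN ratio marks a direction with zero leading-edge genes.
    """
    per_dir = {d: _direction_counts(records, d) for d in (ACTIVATED, SUPPRESSED)}
    ratio_dedup = _ratio(len(per_dir[ACTIVATED][0]), len(per_dir[SUPPRESSED][0]))
    ratio_nondedup = _ratio(per_dir[ACTIVATED][1], per_dir[SUPPRESSED][1])
    return {
        d: CoreGeneStats(
            method=method, direction=d, dedup_genes=dedup,
            nondedup_count=nondedup, super_core=super_core,
            ratio_dedup=ratio_dedup, ratio_nondedup=ratio_nondedup)
        for d, (dedup, nondedup, super_core) in per_dir.items()
    }


def unique_vs_shared(per_method_core: Mapping[str, set[str]]):
    """Shared core (intersection over all methods), per-method unique genes
    (own core minus the union of the others) and per-method unique
    proportion unique/(own total)."""
    if len(per_method_core) < 2:
        raise ValueError("need >= 2 methods")
    methods = list(per_method_core)
    shared = set.intersection(*(set(per_method_core[m]) for m in methods))
    unique: dict[str, set[str]] = {}
    proportion: dict[str, float] = {}
    for m in methods:
        others = set().union(*(per_method_core[o] for o in methods if o != m))
        unique[m] = set(per_method_core[m]) - others
        total = len(per_method_core[m])
        proportion[m] = len(unique[m]) / total if total else float("nan")
    return shared, unique, proportion


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p on k - 1 df.

    All-identical observations give (H, p) = (0, 1) rather than an error.
    """
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 groups, each with >= 1 observation")
    flat = np.concatenate([np.asarray(g, float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def wilcoxon_pairwise(groups: Sequence[Sequence[float]],
                      labels: Sequence[str] | None = None,
                      adjust: str = "fdr_bh") -> pd.DataFrame:
    """All-pairs two-sided rank-sum tests, adjusted across pairs.

    Returns a symmetric p-value matrix with unit diagonal. A pair whose
    pooled observations are all identical gets p = 1.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 groups")
    labels = list(labels) if labels is not None else [f"g{i+1}" for i in range(k)]
    raw, pairs = [], []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = np.asarray(groups[i], float), np.asarray(groups[j], float)
            pooled = np.concatenate([a, b])
            if np.all(pooled == pooled[0]):
                p = 1.0
            else:
                no_ties = len(np.unique(pooled)) == pooled.size
                method = "exact" if no_ties and a.size * b.size <= 400 \
                    else "asymptotic"
                p = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                             method=method).pvalue)
            raw.append(min(p, 1.0))
            pairs.append((i, j))
    adjusted = multipletests(raw, method=adjust)[1] if adjust else np.array(raw)
    mat = np.eye(k)
    for (i, j), p in zip(pairs, adjusted):
        mat[i, j] = mat[j, i] = p
    return pd.DataFrame(mat, index=labels, columns=labels)


def composite_score(per_gene_results: Sequence[Mapping],
                    collection_label: str) -> float:
    """Composite per-dataset score for one method and one collection.

    ``per_gene_results``: one mapping per target with keys ``f_gene`` (the
    target's positive-correlate fraction) and ``fractions`` (the per-repeat
    activated-pathway fractions, NaN for failed repeats). See the module
    docstring for the surrogate formula.
    """
    if not per_gene_results:
        raise ValueError("no targets")
    contributions: list[float] = []
    for res in per_gene_results:
        f_gene = float(res["f_gene"])
        for f_path in res["fractions"]:
            if not np.isfinite(f_path) or not np.isfinite(f_gene):
                contributions.append(0.0)
                continue
            concordance = 1.0 - abs(f_path - f_gene)
            balance = 1.0 - 2.0 * abs(f_path - 0.5)
            contributions.append(concordance * balance)
    return float(np.mean(contributions))


@dataclass
class MethodScore:
    """Per-method composite scores; total = hallmark + kegg."""

    method: str
    hallmark_score: float
    kegg_score: float
    version: str = COMPOSITE_SCORE_VERSION

    @property
    def total_score(self) -> float:
        return self.hallmark_score + self.kegg_score


def method_score(method: str, hallmark_results: Sequence[Mapping],
                 kegg_results: Sequence[Mapping]) -> MethodScore:
    return MethodScore(
        method=method,
        hallmark_score=composite_score(hallmark_results, "hallmark"),
        kegg_score=composite_score(kegg_results, "kegg"),
    )
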