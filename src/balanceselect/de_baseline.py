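"""Wilcoxon rank-sum differential-expression baseline and DE-table
harmonization.

``wrst_de`` scores every gene with a two-sided rank-sum test between the case
and control samples — exact enumeration for small tie-free problems
(n_case * n_control <= 400), tie-corrected normal approximation otherwise —
adjusts p values across genes with Benjamini-Hochberg, and reports a
pseudocount-stabilized log2 fold change of class means. External tool
exports (DESeq2/edgeR/limma and friends) enter through
:func:`~balanceselect.formats_io.read_de_table` and are compared on equal
footing by :func:`harmonize`, which inner-joins tables on the common gene
universe and intersects their significant sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats_io import DETable, ExpressionMatrix

__all__ = ["wrst_de", "harmonize", "HarmonizedDE", "direction_of"]

_EXACT_PAIR_LIMIT = 400


def direction_of(logfc: float) -> str:
    return "flat" if logfc == 0 else ("up" if logfc > 0 else "down")


def _rank_sum_p(case: np.ndarray, ctrl: np.ndarray) -> float:
    pooled = np.concatenate([case, ctrl])
    if np.all(pooled == pooled[0]):
        return 1.0  # constant gene: no evidence either way
    has_ties = len(np.unique(pooled)) < pooled.size
    if not has_ties and case.size * ctrl.size <= _EXACT_PAIR_LIMIT:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(case, ctrl, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def wrst_de(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> DETable:
    """Per-gene two-sided Wilcoxon rank-sum test with BH adjustment.

    logFC = log2((mean_case + pseudocount) / (mean_control + pseudocount));
    a mean + pseudocount <= 0 is an error (the pseudocount must keep the
    ratio positive on the input scale).
    """
    case_mask = matrix.case_mask
    arr = matrix.values.to_numpy(dtype=float)
    case, ctrl = arr[:, case_mask], arr[:, ~case_mask]
    mean_case, mean_ctrl = case.mean(axis=1), ctrl.mean(axis=1)
    num, den = mean_case + pseudocount, mean_ctrl + pseudocount
    if (num <= 0).any() or (den <= 0).any():
        bad = matrix.values.index[(num <= 0) | (den <= 0)].tolist()
        raise ValueError(
            f"mean + pseudocount <= 0 for gene(s) {bad[:5]}; "
            "increase pseudocount or shift the input scale"
        )
    logfc = np.log2(num / den)
    pvals = np.array([_rank_sum_p(case[i], ctrl[i]) for i in range(arr.shape[0])])
    padj = multipletests(pvals, method="fdr_bh")[1]
    table = pd.DataFrame({
        "gene_id": matrix.gene_ids,
        "logfc": logfc,
        "pvalue": pvals,
        "padj": padj,
        "direction": [direction_of(l) for l in logfc],
    })
    return DETable(table=table, method_label="wrst")


@dataclass
class HarmonizedDE:
    """Per-gene per-method logFC/padj on the common universe, plus the
    per-method significant sets and their intersection."""

    table: pd.DataFrame              # gene_id + {logfc,padj}_{method} columns
    significant: dict[str, list[str]]
    intersection: list[str]
    alpha: float
    lfc_min: float


def harmonize(tables: list[DETable], alpha: float = 0.05,
              lfc_min: float = 1.0) -> HarmonizedDE:
    """Inner-join >= 2 DE tables on gene id and intersect significant sets."""
    if len(tables) < 2:
        raise ValueError("need >= 2 DE tables to harmonize")
    labels = [t.method_label for t in tables]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate method labels: {labels}")
    merged: pd.DataFrame | None = None
    for t in tables:
        part = t.table[["gene_id", "logfc", "padj"]].rename(columns={
            "logfc": f"logfc_{t.method_label}",
            "padj": f"padj_{t.method_label}",
        })
        merged = part if merged is None else merged.merge(part, on="gene_id",
                                                          how="inner")
    if len(merged) == 0:
        raise ValueError("empty intersection of gene universes")
    merged = merged.sort_values("gene_id", ignore_index=True)
    significant = {
        t.method_label: sorted(set(t.significant(alpha, lfc_min)) &
                               set(merged["gene_id"]))
        for t in tables
    }
    inter = set(merged["gene_id"])
    for genes in significant.values():
        inter &= set(genes)
    return HarmonizedDE(table=merged, significant=significant,
                        intersection=sorted(inter), alpha=alpha, lfc_min=lfc_min)
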