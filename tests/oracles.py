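"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive — explicit Python loops over sample
pairs and ranked-list positions — and shares no code with the package's
vectorized implementations.
"""

from __future__ import annotations

from itertools import combinations

from balanceselect.formats_io import ExpressionMatrix


def pair_credit(case_val: float, ctrl_val: float, up_in_case: bool) -> float:
    if case_val == ctrl_val:
        return 0.5
    correct = case_val > ctrl_val if up_in_case else case_val < ctrl_val
    return 1.0 if correct else 0.0


def oracle_auc(matrix: ExpressionMatrix, gene: str) -> tuple[float, bool]:
    """Oriented AUC by full pair enumeration; returns (auc, up_in_case)."""
    case = list(matrix.case_values(gene))
    ctrl = list(matrix.control_values(gene))
    raw = sum(pair_credit(c, k, True) for c in case for k in ctrl) / (
        len(case) * len(ctrl))
    return (raw, True) if raw >= 0.5 else (1.0 - raw, False)


def oracle_mvauc(matrix: ExpressionMatrix, genes) -> float:
    """Pair-coverage mvAUC: per pair, max credit over oriented members."""
    genes = list(dict.fromkeys(genes))
    orient = {g: oracle_auc(matrix, g)[1] for g in genes}
    case_idx = [i for i, c in enumerate(matrix.case_mask) if c]
    ctrl_idx = [i for i, c in enumerate(matrix.case_mask) if not c]
    total = 0.0
    for ci in case_idx:
        for ki in ctrl_idx:
            total += max(
                pair_credit(matrix.values.loc[g].iloc[ci],
                            matrix.values.loc[g].iloc[ki], orient[g])
                for g in genes)
    return total / (len(case_idx) * len(ctrl_idx))


def oracle_best_subset(matrix: ExpressionMatrix, max_size: int):
    """Exhaustive search over all subsets up to max_size; returns
    (best_mvauc, best_subset)."""
    best = (0.0, ())
    for size in range(1, max_size + 1):
        for subset in combinations(matrix.gene_ids, size):
            val = oracle_mvauc(matrix, subset)
            if val > best[0]:
                best = (val, subset)
    return best


def oracle_ks_es(ranked_ids, scores, members, p: float) -> float:
    """Weighted-KS enrichment score by an explicit walk down the list."""
    members = set(members) & set(ranked_ids)
    n, k = len(ranked_ids), len(members)
    hit_weight_total = sum(
        abs(s) ** p for g, s in zip(ranked_ids, scores) if g in members)
    running, best = 0.0, 0.0
    for g, s in zip(ranked_ids, scores):
        if g in members:
            if p == 0 or hit_weight_total == 0:
                running += 1.0 / k
            else:
                running += abs(s) ** p / hit_weight_total
        else:
            running -= 1.0 / (n - k)
        if abs(running) > abs(best) or (abs(running) == abs(best)
                                        and running > best):
            best = running
    return best


def oracle_rank_sum_p(a, b) -> float:
    """Exact two-sided rank-sum p by enumerating all label assignments."""
    from itertools import combinations as combos
    pooled = sorted(list(a) + list(b))
    ranks = {}
    # average ranks for ties
    for v in set(pooled):
        idx = [i + 1 for i, x in enumerate(pooled) if x == v]
        ranks[v] = sum(idx) / len(idx)
    obs = sum(ranks[x] for x in a)
    n, na = len(pooled), len(a)
    all_vals = list(a) + list(b)
    stats = [sum(ranks[all_vals[i]] for i in combo)
             for combo in combos(range(n), na)]
    mean = sum(stats) / len(stats)
    extreme = sum(abs(s - mean) >= abs(obs - mean) - 1e-12 for s in stats)
    return extreme / len(stats)
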