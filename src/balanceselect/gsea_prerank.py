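"""Preranked gene set enrichment analysis with direction accounting.

Genes are ranked by Spearman correlation with a target gene (descending), and
each gene set is scored with the weighted Kolmogorov-Smirnov running
statistic: walking down the ranked list, set members ("hits") push the
running sum up by |score|^p normalized over the set's hits, non-members
("misses") pull it down by 1/(N - N_hits); the enrichment score (ES) is the
signed maximum deviation from zero and the leading-edge (core-enriched)
genes are the members at or before the extremum (at or after it, for a
negative ES). ``weight_exponent`` p = 1 is the usual weighted statistic;
p = 0 recovers the classical unweighted KS statistic.

Significance uses gene-set permutation — the only null available for a
single-target correlation ranking: random member sets of equal size drawn
from the ranked universe. NES divides ES by the mean |null ES| of matching
sign; p is the same-sign tail fraction; FDR q compares the sign-stratified
pooled null NES distribution with the observed NES distribution. A pathway
is "activated" when NES > 0 and "suppressed" when NES < 0. Because the null
is stochastic, the per-target analysis is re-run ``n_repeats`` times
(default 20) and the activated fraction per repeat is reported, NaN when no
set passes the significance gate — never coerced to zero.

Redundant pathways (near-identical leading edges, e.g. sub-pathways or
synonymous sets) are flagged by single-linkage clustering at a Jaccard
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .correlation_balance import profile_target
from .formats_io import ExpressionMatrix, GeneSetCollection

__all__ = ["RankedList", "GseaConfig", "EnrichmentRecord", "rank_by_target",
           "enrichment_score", "significance", "enrich_collection",
           "repeat_fraction", "redundancy_flag"]

ACTIVATED, SUPPRESSED = "activated", "suppressed"


@dataclass
class RankedList:
    """Gene ids ordered by nonincreasing score."""

    ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.ids) != self.scores.size:
            raise ValueError("ids and scores length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in ranked list")
        if (np.diff(self.scores) > 1e-12).any():
            raise ValueError("scores must be nonincreasing")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class GseaConfig:
    weight_exponent: float = 1.0
    n_permutations: int = 1000
    min_set_size: int = 5
    max_set_size: int = 500
    n_repeats: int = 20
    alpha: float = 0.25       # significance gate on FDR q for direction counts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weight_exponent < 0:
            raise ValueError("weight_exponent must be >= 0")
        if min(self.n_permutations, self.min_set_size, self.max_set_size,
               self.n_repeats) < 1:
            raise ValueError("counts must be positive")
        if self.min_set_size >= self.max_set_size:
            raise ValueError("min_set_size must be < max_set_size")


@dataclass
class EnrichmentRecord:
    set_name: str
    es: float
    nes: float
    pvalue: float
    fdr_q: float
    direction: str
    leading_edge: list[str]
    collection_label: str = "custom"
    n_members: int = 0


def rank_by_target(matrix: ExpressionMatrix, target_gene: str) -> RankedList:
    """Rank every other gene by Spearman correlation with the target,
    descending, ties broken lexicographically; genes with undefined
    correlation (constant) are dropped."""
    prof = profile_target(matrix, target_gene)
    if prof.degenerate:
        raise ValueError(f"target {target_gene!r} is constant; ranking undefined")
    items = [(g, r) for g, r in prof.rho_of.items() if np.isfinite(r)]
    items.sort(key=lambda gr: (-gr[1], gr[0]))
    return RankedList(ids=[g for g, _ in items],
                      scores=np.array([r for _, r in items]))


# ---------------------------------------------------------------------------
# ES computation (compact, hit-position form; vectorized over permutations)
# ---------------------------------------------------------------------------


def _es_from_positions(pos: np.ndarray, scores: np.ndarray, n: int,
                       p: float) -> tuple[np.ndarray, np.ndarray]:
    """ES for one or many hit-position sets.

    ``pos``: (n_sets, k) sorted hit positions into a ranked list of length
    ``n`` with the given scores. Returns (es, extremum_hit_index) where the
    extremum index is the hit ordinal attaining the ES (for leading-edge
    extraction). Exact ties between the positive and negative extreme
    resolve to the positive side.
    """
    pos = np.atleast_2d(pos)
    k = pos.shape[1]
    if p == 0:
        w = np.full(pos.shape, 1.0 / k)
    else:
        w = np.abs(scores[pos]) ** p
        tot = w.sum(axis=1, keepdims=True)
        uniform = tot == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(uniform, 1.0 / k, w / np.where(uniform, 1.0, tot))
    m = 1.0 / (n - k)
    j = np.arange(k)
    miss_drop = (pos - j) * m            # misses accumulated before hit j
    cumw = np.cumsum(w, axis=1)
    after = cumw - miss_drop             # running sum just after hit j
    before = after - w                   # running sum just before hit j
    jmax = np.argmax(after, axis=1)
    jmin = np.argmin(before, axis=1)
    es_pos = after[np.arange(len(after)), jmax]
    es_neg = before[np.arange(len(before)), jmin]
    take_pos = es_pos >= -es_neg
    es = np.where(take_pos, es_pos, es_neg)
    extremum = np.where(take_pos, jmax, jmin)
    return es, extremum


def enrichment_score(ranked: RankedList, members: Sequence[str],
                     p: float = 1.0) -> tuple[float, list[str]]:
    """Weighted-KS enrichment score and leading-edge genes of one set."""
    index = {g: i for i, g in enumerate(ranked.ids)}
    hits = sorted(index[g] for g in set(members) if g in index)
    n = len(ranked)
    if not hits:
        raise ValueError("no overlap between set and ranked universe")
    if len(hits) >= n:
        raise ValueError("set covers the entire universe")
    es, extremum = _es_from_positions(np.array([hits]), ranked.scores, n, p)
    es, j = float(es[0]), int(extremum[0])
    if es > 0:
        leading = [ranked.ids[i] for i in hits[: j + 1]]
    elif es < 0:
        leading = [ranked.ids[i] for i in hits[j:]]
    else:
        leading = []
    return es, leading


def _null_es(ranked: RankedList, k: int, config: GseaConfig,
             rng: np.random.Generator) -> np.ndarray:
    n = len(ranked)
    draws = rng.random((config.n_permutations, n)).argsort(axis=1)[:, :k]
    draws.sort(axis=1)
    es, _ = _es_from_positions(draws, ranked.scores, n, config.weight_exponent)
    return es


def _nes(es: float | np.ndarray, null: np.ndarray):
    """Normalize by the mean |null ES| of matching sign; NaN if that side of
    the null is empty."""
    pos_mean = np.abs(null[null > 0]).mean() if (null > 0).any() else np.nan
    neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
    scale = np.where(np.asarray(es) >= 0, pos_mean, neg_mean)
    with np.errstate(invalid="ignore"):
        return np.asarray(es) / scale


def _tail_p(es: float, null: np.ndarray) -> float:
    same = null[null > 0] if es >= 0 else null[null < 0]
    if same.size == 0:
        return float("nan")
    return float((np.abs(same) >= abs(es)).mean())


def significance(ranked: RankedList, members: Sequence[str],
                 config: GseaConfig,
                 collection_label: str = "custom") -> EnrichmentRecord:
    """Permutation significance of one gene set (its own null; q = p here —
    collection-wide FDR comes from :func:`enrich_collection`)."""
    rng = np.random.default_rng(config.seed)
    es, leading = enrichment_score(ranked, members, config.weight_exponent)
    index = set(ranked.ids)
    k = len(set(members) & index)
    null = _null_es(ranked, k, config, rng)
    nes = float(_nes(es, null))
    pval = _tail_p(es, null)
    return EnrichmentRecord(
        set_name="set", es=es, nes=nes, pvalue=pval, fdr_q=pval,
        direction=ACTIVATED if es >= 0 else SUPPRESSED,
        leading_edge=leading, collection_label=collection_label, n_members=k)


def enrich_collection(ranked: RankedList, collection: GeneSetCollection,
                      config: GseaConfig) -> list[EnrichmentRecord]:
    """Score every admissible set of a collection with collection-wide,
    sign-stratified FDR q values.

    Sets whose overlap with the ranked universe falls outside
    [min_set_size, max_set_size] are skipped; records whose NES is undefined
    (empty same-sign null) are dropped.
    """
    universe = set(ranked.ids)
    rng = np.random.default_rng(config.seed)
    names = sorted(collection.sets)
    obs: list[tuple[str, float, list[str], int]] = []
    null_nes_all: list[np.ndarray] = []
    nes_list: list[float] = []
    for name in names:
        members = set(collection.members(name)) & universe
        k = len(members)
        if not (config.min_set_size <= k <= config.max_set_size) or k >= len(ranked):
            continue
        es, leading = enrichment_score(ranked, members, config.weight_exponent)
        null = _null_es(ranked, k, config, rng)
        nes = float(_nes(es, null))
        if not np.isfinite(nes):
            continue
        obs.append((name, es, leading, k))
        nes_list.append(nes)
        null_nes_all.append(np.asarray(_nes(null, null)))
    records: list[EnrichmentRecord] = []
    if not obs:
        return records
    pooled = np.concatenate(null_nes_all)
    pooled = pooled[np.isfinite(pooled)]
    nes_arr = np.array(nes_list)
    for (name, es, leading, k), nes, null in zip(obs, nes_arr, null_nes_all):
        # same-sign normalization is monotone, so the NES tail equals the
        # raw-ES tail against the set's own null
        pval = _tail_p(nes, null)
        same_null = pooled[pooled > 0] if nes >= 0 else pooled[pooled < 0]
        same_obs = nes_arr[nes_arr > 0] if nes >= 0 else nes_arr[nes_arr < 0]
        if same_null.size == 0:
            q = float("nan")
        else:
            null_frac = (np.abs(same_null) >= abs(nes)).mean()
            obs_frac = max((np.abs(same_obs) >= abs(nes)).mean(),
                           1.0 / max(len(same_obs), 1))
            q = float(min(1.0, null_frac / obs_frac))
        records.append(EnrichmentRecord(
            set_name=name, es=float(es), nes=float(nes), pvalue=pval,
            fdr_q=q, direction=ACTIVATED if nes >= 0 else SUPPRESSED,
            leading_edge=leading, collection_label=collection.collection_label,
            n_members=k))
    return records


def repeat_fraction(matrix: ExpressionMatrix, target_gene: str,
                    collection: GeneSetCollection,
                    config: GseaConfig) -> list[float]:
    """Activated-pathway fraction per stochastic repeat.

    Each repeat reseeds the permutation null; the fraction is
    activated / (activated + suppressed) among records with q < alpha, and
    NaN for repeats where no record passes (a failed enrichment is
    information, not a zero).
    """
    ranked = rank_by_target(matrix, target_gene)
    fractions: list[float] = []
    for r in range(config.n_repeats):
        seed_r = int(np.random.SeedSequence([config.seed, r]).generate_state(1)[0]
                     % (2 ** 31))
        records = enrich_collection(ranked, collection,
                                    replace(config, seed=seed_r))
        sig = [rec for rec in records if rec.fdr_q < config.alpha]
        n_act = sum(rec.direction == ACTIVATED for rec in sig)
        n_sup = sum(rec.direction == SUPPRESSED for rec in sig)
        fractions.append(n_act / (n_act + n_sup) if n_act + n_sup
                         else float("nan"))
    return fractions


@dataclass
class RedundancyCluster:
    representative: str       # member with the largest |NES|
    members: list[str]
    direction: str


def redundancy_flag(records: Sequence[EnrichmentRecord],
                    jaccard_threshold: float = 0.8) -> list[RedundancyCluster]:
    """Single-linkage clusters of same-direction records whose leading-edge
    Jaccard similarity reaches the threshold; redundant pathway groups
    (sub-pathways, synonymous sets) surface as multi-member clusters."""
    if not records:
        raise ValueError("need >= 1 record")
    parent = list(range(len(records)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    edges = [
        (i, j)
        for i in range(len(records)) for j in range(i + 1, len(records))
        if records[i].direction == records[j].direction
        and _jaccard(records[i].leading_edge, records[j].leading_edge)
        >= jaccard_threshold
    ]
    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    groups: dict[int, list[int]] = {}
    for i in range(len(records)):
        groups.setdefault(find(i), []).append(i)
    clusters = []
    for idxs in groups.values():
        rep = max(idxs, key=lambda i: (abs(records[i].nes)
                                       if np.isfinite(records[i].nes) else -1,
                                       records[i].set_name))
        clusters.append(RedundancyCluster(
            representative=records[rep].set_name,
            members=sorted(records[i].set_name for i in idxs),
            direction=records[rep].direction))
    return sorted(clusters, key=lambda c: c.representative)


def _jaccard(a: Sequence[str], b: Sequence[str]) -> float:
    sa, sb = set(a), set(b)
    union = sa | sb
    return len(sa & sb) / len(union) if union else 0.0
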