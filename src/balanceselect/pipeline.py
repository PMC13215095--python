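"""End-to-end benchmark: selection methods -> intersection target set ->
correlation balance -> preranked GSEA -> core-gene stats -> composite
scores, from one config, reproducibly.

The benchmark mirrors the evaluation design around the toolkit: several
selection methods run on the same two-class matrix, the genes every method
agrees on become the shared target set, and all downstream direction-balance
analyses are performed on that shared set so methods are compared on equal
footing. On synthetic data the designed ground truth additionally yields a
direction-recovery accuracy for the enrichment stage.

All randomness flows from one root seed: stage ``i`` draws its seed from
``SeedSequence([root_seed, i])`` (GSEA repeats derive theirs the same way
one level down), so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .autofs_ensemble import AutoFSConfig, autofs
from .correlation_balance import (BalanceReport, balance_index,
                                  discrepancy_rank, profile_target)
from .de_baseline import wrst_de
from .enrichment_stats import (COMPOSITE_SCORE_VERSION, MethodScore,
                               method_score, quantify_core)
from .formats_io import ExpressionMatrix, GeneSetCollection, _json_default
from .gsea_prerank import (ACTIVATED, EnrichmentRecord, GseaConfig,
                           enrich_collection, rank_by_target)
from .mvauc_select import macfc_v2
from .synthetic_data import (GroundTruth, SyntheticConfig, generate_dataset,
                             generate_gene_sets)

__all__ = ["BenchmarkConfig", "BenchmarkReport", "target_gene_set",
           "run_benchmark"]

KNOWN_METHODS = ("wrst", "mvauc", "autofs")

# stage indices for seed derivation
_STAGE_DATA, _STAGE_SETS_A, _STAGE_SETS_B, _STAGE_AUTOFS, _STAGE_GSEA = range(5)


def _derive_seed(root: int, *path: int) -> int:
    return int(np.random.SeedSequence([root, *path]).generate_state(1)[0]
               % (2 ** 31))


@dataclass
class BenchmarkConfig:
    """One config for the whole chain. Defaults are desk-scale: a 500-gene,
    80-sample balanced synthetic cohort, three selection methods, two
    10-set collections, 3 GSEA targets x 20 stochastic repeats."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    methods: Sequence[str] = KNOWN_METHODS
    corr_threshold: float = 0.5
    de_alpha: float = 0.05
    de_lfc_min: float = 0.5
    de_pseudocount: float | None = None   # None -> shift to keep means positive
    mvauc_threshold: float = 0.95
    mvauc_max_features: int = 50
    mvauc_min_gain: float = 1e-6
    autofs: AutoFSConfig = field(default_factory=lambda: AutoFSConfig(
        k_univariate=50, cv_folds=3, n_search_iterations=5,
        rfe_step=0.25, rfe_prefilter=40))
    gsea: GseaConfig = field(default_factory=lambda: GseaConfig(
        n_permutations=200, n_repeats=20))
    n_gene_sets: int = 10
    set_size: int = 15
    set_purity: float = 0.9
    n_gsea_targets: int = 3
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        unknown = [m for m in self.methods if m not in KNOWN_METHODS]
        if unknown:
            raise ValueError(
                f"unknown method(s) {unknown}; known: {list(KNOWN_METHODS)}")
        if len(self.methods) < 2:
            raise ValueError("need >= 2 methods for an intersection benchmark")


@dataclass
class BenchmarkReport:
    matrix: ExpressionMatrix
    truth: GroundTruth
    selections: dict[str, list[str]]
    targets: list[str]
    balance: BalanceReport
    per_method_ncg: dict[str, dict[str, int]]
    discrepancy: list[tuple[str, int]]
    gsea_targets: list[str]
    records: pd.DataFrame            # all repeats, all collections
    fractions: pd.DataFrame          # per target x collection x repeat
    core_stats: pd.DataFrame
    scores: dict[str, MethodScore]
    direction_accuracy: float        # fraction of significant records whose
                                     # NES sign matches the designed direction
    manifest: dict


def target_gene_set(per_method_selected: Mapping[str, Sequence[str]]) -> list[str]:
    """Intersection of all methods' selected genes, sorted lexicographically."""
    if len(per_method_selected) < 2:
        raise ValueError("need >= 2 methods")
    sets = [set(v) for v in per_method_selected.values()]
    inter = set.intersection(*sets)
    if not inter:
        raise ValueError(
            "empty intersection of selected genes; relax the selection "
            "thresholds or significance gates")
    return sorted(inter)


def _run_selections(matrix: ExpressionMatrix, cfg: BenchmarkConfig
                    ) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for m in cfg.methods:
        if m == "wrst":
            pc = cfg.de_pseudocount
            if pc is None:
                arr = matrix.values.to_numpy()
                case = arr[:, matrix.case_mask].mean(axis=1).min()
                ctrl = arr[:, ~matrix.case_mask].mean(axis=1).min()
                pc = 1.0 + max(0.0, -min(case, ctrl))
            de = wrst_de(matrix, pseudocount=pc)
            out[m] = sorted(de.significant(cfg.de_alpha, cfg.de_lfc_min))
        elif m == "mvauc":
            trace = macfc_v2(matrix, auc_threshold=cfg.mvauc_threshold,
                             max_features=cfg.mvauc_max_features,
                             min_gain=cfg.mvauc_min_gain)
            out[m] = sorted(trace.selected)
        elif m == "autofs":
            acfg = replace(cfg.autofs, seed=_derive_seed(cfg.seed, _STAGE_AUTOFS))
            out[m] = sorted(autofs(matrix, acfg).selected)
    return out


def _designed_sign(truth: GroundTruth, gene: str) -> int:
    """Target's designed coupling sign to its anchor (+1 anchor/pos, -1 neg,
    0 null/unknown)."""
    if gene in truth.anchor_ids:
        return 1
    return truth.sign_of.get(gene, 0)


def run_benchmark(config: BenchmarkConfig) -> BenchmarkReport:
    """Execute the full chain on synthetic data and (optionally) write the
    report bundle to ``config.outdir``."""
    cfg = config
    syn = replace(cfg.synthetic, seed=_derive_seed(cfg.seed, _STAGE_DATA))
    matrix, truth = generate_dataset(syn)
    collections = {
        "hallmark_like": generate_gene_sets(
            truth, cfg.n_gene_sets, cfg.set_size, cfg.set_purity,
            seed=_derive_seed(cfg.seed, _STAGE_SETS_A)),
        "kegg_like": generate_gene_sets(
            truth, cfg.n_gene_sets, cfg.set_size, cfg.set_purity,
            seed=_derive_seed(cfg.seed, _STAGE_SETS_B)),
    }

    selections = _run_selections(matrix, cfg)
    targets = target_gene_set(selections)

    # gene-level balance on the full-matrix universe
    profiles = [profile_target(matrix, t, cfg.corr_threshold) for t in targets]
    balance = balance_index(profiles)

    # per-method NCG counts with the correlation universe restricted to each
    # method's own selected genes (the method-dependent view)
    per_method_ncg: dict[str, dict[str, int]] = {}
    method_profiles: dict[str, dict[str, float]] = {}
    for m, genes in selections.items():
        per_method_ncg[m] = {}
        method_profiles[m] = {}
        for t in targets:
            prof = profile_target(matrix, t, cfg.corr_threshold, universe=genes)
            per_method_ncg[m][t] = len(prof.ncg)
            method_profiles[m][t] = prof.pos_fraction
    focal = "mvauc" if "mvauc" in selections else list(selections)[0]
    discrepancy = discrepancy_rank(per_method_ncg, focal)
    gsea_targets = [t for t, _ in discrepancy[: cfg.n_gsea_targets]]

    # GSEA: per target x collection x repeat, reseeded per repeat
    rec_rows, frac_rows = [], []
    sig_records: list[tuple[str, str, int, EnrichmentRecord]] = []
    n_correct = n_signed = 0
    for t in gsea_targets:
        ranked = rank_by_target(matrix, t)
        sign = _designed_sign(truth, t)
        for cname, coll in collections.items():
            for r in range(cfg.gsea.n_repeats):
                seed_r = _derive_seed(cfg.seed, _STAGE_GSEA,
                                      gsea_targets.index(t),
                                      list(collections).index(cname), r)
                records = enrich_collection(ranked, coll,
                                            replace(cfg.gsea, seed=seed_r))
                sig = [rec for rec in records if rec.fdr_q < cfg.gsea.alpha]
                n_act = sum(rec.direction == ACTIVATED for rec in sig)
                n_tot = len(sig)
                frac_rows.append({
                    "target": t, "collection": cname, "repeat": r,
                    "fraction": n_act / n_tot if n_tot else float("nan")})
                for rec in records:
                    rec_rows.append({
                        "target": t, "collection": cname, "repeat": r,
                        "set_name": rec.set_name, "es": rec.es,
                        "nes": rec.nes, "pvalue": rec.pvalue,
                        "fdr_q": rec.fdr_q, "direction": rec.direction,
                        "n_leading": len(rec.leading_edge),
                        "significant": rec.fdr_q < cfg.gsea.alpha})
                for rec in sig:
                    sig_records.append((t, cname, r, rec))
                    if sign != 0:
                        designed = 1 if rec.set_name.startswith("ACT") else -1
                        expected = designed * sign
                        n_signed += 1
                        n_correct += (np.sign(rec.nes) == expected)

    records_df = pd.DataFrame(rec_rows)
    fractions_df = pd.DataFrame(frac_rows)
    direction_accuracy = n_correct / n_signed if n_signed else float("nan")

    # per-method core-gene accounting: each significant record's leading edge
    # restricted to the method's selected genes (which core signal a method's
    # selection retains); repeat 0 only, to count each pathway once
    core_rows = []
    first_repeat = [rec for (_, _, r, rec) in sig_records if r == 0]
    for m, genes in selections.items():
        gset = set(genes)
        restricted = [
            replace_leading(rec, [g for g in rec.leading_edge if g in gset])
            for rec in first_repeat
        ]
        restricted = [rec for rec in restricted if rec.leading_edge]
        if not restricted:
            continue
        stats = quantify_core(restricted, m)
        for d, st in stats.items():
            core_rows.append({
                "method": m, "direction": d,
                "n_dedup": len(st.dedup_genes),
                "n_nondedup": st.nondedup_count,
                "n_super_core": len(st.super_core),
                "ratio_dedup": st.ratio_dedup,
                "ratio_nondedup": st.ratio_nondedup})
    core_df = pd.DataFrame(core_rows)

    # composite scores: shared pathway fractions, method-specific gene-level
    # fractions (the method's own correlation universe)
    scores: dict[str, MethodScore] = {}
    for m in selections:
        per_coll = {}
        for cname in collections:
            per_coll[cname] = [
                {"f_gene": method_profiles[m][t],
                 "fractions": fractions_df.loc[
                     (fractions_df["target"] == t)
                     & (fractions_df["collection"] == cname),
                     "fraction"].tolist()}
                for t in gsea_targets
            ]
        scores[m] = method_score(m, per_coll["hallmark_like"],
                                 per_coll["kegg_like"])

    manifest = {
        "package_version": __version__,
        "composite_score_version": COMPOSITE_SCORE_VERSION,
        "root_seed": cfg.seed,
        "config": _config_dict(cfg),
        "n_genes": matrix.n_genes,
        "n_samples": len(matrix.sample_ids),
        "methods": list(cfg.methods),
        "n_targets": len(targets),
        "gsea_targets": gsea_targets,
        "target_designed_signs": {t: _designed_sign(truth, t)
                                  for t in gsea_targets},
    }

    report = BenchmarkReport(
        matrix=matrix, truth=truth, selections=selections, targets=targets,
        balance=balance, per_method_ncg=per_method_ncg,
        discrepancy=discrepancy, gsea_targets=gsea_targets,
        records=records_df, fractions=fractions_df, core_stats=core_df,
        scores=scores, direction_accuracy=direction_accuracy,
        manifest=manifest)
    if cfg.outdir:
        _write_bundle(report, Path(cfg.outdir))
    return report


def replace_leading(rec: EnrichmentRecord, leading: list[str]) -> EnrichmentRecord:
    return replace(rec, leading_edge=leading)


def _config_dict(cfg: BenchmarkConfig) -> dict:
    d = asdict(cfg)
    d["autofs"].pop("search_space", None)  # distributions are not JSON-safe
    d.pop("outdir", None)                  # manifest describes the run, not
    return d                               # where it was written


def _write_bundle(report: BenchmarkReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(m, g) for m, genes in sorted(report.selections.items())
         for g in genes], columns=["method", "gene_id"]
    ).to_csv(outdir / "selections.tsv", sep="\t", index=False)
    pd.DataFrame({"target": report.targets}).to_csv(
        outdir / "targets.tsv", sep="\t", index=False)
    report.balance.per_target.to_csv(
        outdir / "balance_per_target.tsv", sep="\t", index=False,
        float_format="%.6g")
    pd.DataFrame(
        [(m, t, c) for m, counts in sorted(report.per_method_ncg.items())
         for t, c in sorted(counts.items())],
        columns=["method", "target", "n_ncg"],
    ).to_csv(outdir / "per_method_ncg.tsv", sep="\t", index=False)
    pd.DataFrame(report.discrepancy, columns=["target", "score"]).to_csv(
        outdir / "discrepancy.tsv", sep="\t", index=False)
    report.records.to_csv(outdir / "gsea_records.tsv", sep="\t", index=False,
                          float_format="%.6g")
    report.fractions.to_csv(outdir / "repeat_fractions.tsv", sep="\t",
                            index=False, float_format="%.6g")
    report.core_stats.to_csv(outdir / "core_stats.tsv", sep="\t", index=False,
                             float_format="%.6g")
    summary = {
        "balance_index": report.balance.balance_index,
        "n_targets": len(report.targets),
        "direction_accuracy": report.direction_accuracy,
        "scores": {m: {"hallmark": s.hallmark_score, "kegg": s.kegg_score,
                       "total": s.total_score, "version": s.version}
                   for m, s in sorted(report.scores.items())},
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2, sort_keys=True,
                  default=_json_default)
        fh.write("\n")
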