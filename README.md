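# balanceselect

Interaction-aware gene selection for two-class transcriptomics, with a
framework for asking a question most selection tools never face: **is the
method directionally balanced?** Differential-expression screens (DESeq2,
edgeR, limma, the Wilcoxon rank-sum test) can systematically favour genes
whose strong coexpression partners lie on one side — mostly positively or
mostly negatively correlated — and that bias propagates downstream, skewing
the apparent ratio of activated to suppressed pathways. `balanceselect`
implements two complementarity-aware selectors and the statistics needed to
measure this bias at the gene and the pathway level, on real matrices or on
synthetic cohorts with designed ground truth.

## What is in the box

**Selection**

- **mvAUC greedy selection** (`MvAUCSelector`, `macfc_main`, `macfc_v2`).
  A single gene's discrimination is its oriented AUC,
  max(AUC, 1 − AUC) ∈ [0.5, 1]. A gene *set* is scored by pair coverage:
  for every (case, control) sample pair the set earns the best credit any
  oriented member achieves (1 if it orders the pair correctly, ½ on a tie,
  0 otherwise), and

  mvAUC(S) = (1 / n₁n₀) Σ_pairs max_{g∈S} credit_g(pair).

  This reduces to the oriented AUC for singletons, is monotone under
  feature addition, and makes complementarity literal: a gene earns its
  place by covering pairs the current set misses. `macfc_main` builds the
  subset greedily from scratch; `macfc_v2` first keeps every gene with
  oriented AUC > 0.95 as high-confidence seeds and then adds complementary
  genes on top.
- **AutoFS** (`AutoFSSelector`, `autofs`): the union of a univariate ANOVA-F
  filter and ensemble recursive elimination (linear max-margin classifier,
  decision tree, gradient boosting) scored by stratified CV, with randomized
  hyperparameter search and a stacked (logistic-regression meta-learner)
  final model. Both selectors are scikit-learn compatible transformers.

**Evaluation**

- Wilcoxon rank-sum DE baseline with BH adjustment, plus adapters that
  harmonize external DE result tables onto a common gene universe.
- Correlation balance: per target gene, Spearman-classify every other gene
  at |ρ| > 0.5 into positively/negatively correlated sets; the **balance
  index** is the mean positive fraction across targets (0.5 = balanced).
- Preranked GSEA (weighted-KS, gene-permutation null, NES/p/FDR,
  leading-edge extraction, 20-repeat direction fractions) and redundancy
  flagging of near-identical pathways.
- Core-gene accounting: deduplicated vs non-deduplicated leading-edge
  counts, super-core genes (recurring across ≥ 2 same-direction pathways)
  and their ratio-amplification effect, Kruskal–Wallis + pairwise Wilcoxon
  comparisons, and a composite cross-dataset method score (labelled
  `surrogate-v1`).
- A synthetic-data generator with designed positively/negatively coupled
  gene blocks and matched activated/suppressed gene sets, so every stage
  can be validated against known truth.

## Worked example

```python
import balanceselect as bs

cfg = bs.SyntheticConfig(n_case=30, n_control=30, n_anchor=1,
                         pos_block_size=40, neg_block_size=40,
                         null_block_size=119, seed=7)
matrix, truth = bs.generate_dataset(cfg)

trace = bs.macfc_v2(matrix, auc_threshold=0.95)
print("selected:", trace.selected)
print("weights:", [round(w, 4) for w in trace.weights])
print("cumulative mvAUC:", [round(c, 4) for c in trace.cumulative_mvauc])

prof = bs.profile_target(matrix, truth.anchor_ids[0])
print(f"PCG {len(prof.pcg)}  NCG {len(prof.ncg)}  "
      f"pos_fraction {prof.pos_fraction:.3f}")
```

prints

```
selected: ['POS_01_0029', 'NULL_0107', 'NULL_0006']
weights: [0.4311, 0.06, 0.0089]
cumulative mvAUC: [0.9311, 0.9911, 1.0]
PCG 40  NCG 40  pos_fraction 0.500
```

The first gene alone orders 93% of case/control pairs (oriented AUC
0.9311); two further genes cover the remaining pairs, and selection stops
once coverage saturates at mvAUC = 1. The anchor's strong correlates split
40/40 between positive and negative — a positive fraction of exactly 0.5,
i.e. a perfectly balanced coexpression neighbourhood, as designed.

The same workflow is available from the shell:

```sh
balanceselect simulate --seed 7 --outdir data/
balanceselect select-mvauc data/expression.tsv data/classes.tsv --variant v2
balanceselect gsea data/expression.tsv data/classes.tsv data/gene_sets.gmt \
    --targets ANCHOR_01
balanceselect run --seed 7 --outdir results/benchmark
```

`balanceselect run` executes the whole benchmark: all selection methods,
the intersection target set, balance profiling, repeated preranked GSEA,
core-gene statistics and composite scores, writing TSV/JSON reports plus a
manifest that makes the run bit-for-bit reproducible.

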