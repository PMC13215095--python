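# Methods

This note documents the models, operational definitions, defaults and
numerical choices behind `balanceselect`, and what the synthetic validation
does and does not demonstrate.

## The pair-coverage mvAUC

For a two-class matrix with n₁ case and n₀ control samples, a gene's raw
AUC is the Mann–Whitney statistic over the n₁·n₀ between-class sample pairs
(ties count ½). The *oriented* AUC folds it onto [0.5, 1] and records which
direction won; a constant gene scores 0.5 with "up-in-case" orientation by
convention.

The set statistic is defined per pair: the credit of set S on a pair is the
maximum credit of any oriented member (1 correct, ½ tie, 0 wrong), and
mvAUC(S) is the mean over pairs. Only a verbal characterization of the
multivariate AUC exists in the feature-selection literature this follows
("net gain in joint classification performance"), so the pair-coverage
union is this package's operational definition, chosen because it

- reduces exactly to the oriented AUC on singletons,
- is monotone under feature addition (coverage is a union), and
- makes the greedy marginal gain the literal number of newly covered pairs.

Greedy selection (`macfc_main`) picks the best single oriented AUC first
(weight = AUC − 0.5), then repeatedly the gene with maximal marginal gain;
ties resolve to the lexicographically smallest gene id for cross-platform
determinism. Stopping rules: marginal gain ≤ `min_gain` (default 1e-6),
coverage = 1, or `max_features` (default 50). The seeded variant
(`macfc_v2`) first retains every gene with oriented AUC strictly above
`auc_threshold` (default 0.95) — appended in descending-AUC order with
sequential marginal gains as weights — then continues greedily. Whether
ties should receive half credit inside the multivariate statistic is not
settled by the sources this design follows; the choice is isolated in one
function (`_pair_credits`) and mirrored by the test oracle.

**Boundary caveat.** Exact label-swap invariance of mvAUC holds for genes
with a defined direction (raw AUC ≠ 0.5). At raw AUC exactly 0.5 the
orientation is conventional, and with asymmetric ties the per-pair credit
vector — hence a multi-gene coverage — can differ after a swap even though
every AUC value is preserved. Continuous data reach this boundary with
probability zero; heavily tied integer data can sit on it.

On clean synthetic data coverage saturates quickly (mvAUC reaches 1 with a
handful of genes), so selected sets are much smaller than on noisy real
matrices; `min_gain = 0` forces exhaustive complementary pickup if larger
panels are wanted.

## AutoFS

The ensemble selector unions two screens: the top-k genes by one-way
ANOVA F (k defaults to min(100, n_genes/10); a constant gene has undefined
F and ranks last with score 0), and recursive elimination over three base
learners — LinearSVC, a decision tree, gradient-boosted trees — where each
round drops the lowest mean normalized importance (|coefficients| for the
linear model, impurity gains for the trees, each learner's vector
normalized to sum 1 before averaging; the fusion rule is this package's
choice) and every visited subset size is scored by mean stratified
cross-validated accuracy across the learners; the size with the best score
wins, smaller on ties. `rfe_step` (default 1 gene per round; a fraction
drops that share per round) and `rfe_prefilter` (restrict elimination to
the top-N univariate genes) scale the procedure to larger matrices.
Hyperparameters come from per-learner randomized search (default 25 draws,
CV-accuracy objective — the search metric is likewise a package choice);
the final model stacks out-of-fold base-learner predictions under a
logistic-regression meta-learner. Importances reported for the selected
union are the ensemble means restricted to those genes, renormalized to
sum 1. Note the subset-size maximization inflates the *selection* CV
accuracy on null data (winner's curse); generalization claims need folds
independent of those used for selection, which is how the null-accuracy
test evaluates it.

## Differential-expression baseline

`wrst_de` computes a two-sided rank-sum p per gene — exact enumeration when
n₁·n₀ ≤ 400 and the gene has no ties (the exact distribution does not
accommodate ties), otherwise the tie-corrected normal approximation with
continuity correction — BH adjustment across genes, and
log2((mean_case + c)/(mean_control + c)) with pseudocount c (default 1; an
error if a shifted mean is nonpositive, since the input scale is taken as
given and never renormalized). Significance gates default to BH α = 0.05
and |logFC| > 1 and are always echoed in output metadata; on the synthetic
Gaussian scale the benchmark uses |logFC| > 0.5 with an automatic
pseudocount shift keeping class means positive. External DESeq2/edgeR/limma
result tables enter through a column-mapping adapter and are compared — not
re-derived; their internals are deliberately out of scope.

## Correlation balance

Spearman ρ is the Pearson correlation of average ranks; undefined (NaN) for
constant vectors, never coerced to 0. A target's strong correlates are
classified at strict inequalities ρ > t and ρ < −t (default t = 0.5,
matching the common strong-correlation convention); genes exactly at the
threshold are excluded. The balance index is the mean positive fraction
over targets with at least one strong correlate; targets without any are
excluded and counted. The correlation universe is a parameter — the full
matrix (default) or a method's selected genes; the benchmark uses the full
matrix for the headline index and the per-method universe for the
method-comparison counts, and records the choice in metadata. The
discrepancy ranking orders targets by (focal method's NCG count − best
other method's), descending; the benchmark inspects the top 3.

## Preranked GSEA

Genes are ranked by Spearman correlation with a target (descending, ties
lexicographic; genes with undefined correlation dropped). The weighted-KS
running statistic uses hit increments |score|^p normalized over the set's
hits (p = 1 default; p = 0 is the classical unweighted KS statistic, all
hit weights degenerate to equal shares) and miss decrements 1/(N − N_hits).
ES is the signed maximum deviation; an exact tie between the positive and
negative extreme resolves to the positive side. The leading edge comprises
member genes at or before the extremum (at or after, for negative ES) and
is never empty when ES ≠ 0.

Significance uses gene-set permutation — the only null available for a
single-target correlation ranking: `n_permutations` (default 1000) random
equal-size member sets. NES = ES / mean |null ES| of matching sign
(undefined when that side of the null is empty; such records are dropped
with a diagnostic); p is the same-sign tail fraction (equivalently computed
on the NES scale, where the normalization is monotone). Collection-wide
FDR q compares the pooled sign-stratified null NES distribution against
the observed NES distribution, clipped to [0, 1]. The direction gate for
counting activated vs suppressed pathways is q < 0.25 (the conventional
exploratory GSEA gate), configurable. Because the null is stochastic the
per-target analysis repeats `n_repeats` = 20 times with seeds derived from
the root seed; a repeat with no significant set reports NaN — a failed
enrichment is information and is never coerced to 0. Redundant pathways
are flagged by single-linkage clustering of same-direction leading edges at
Jaccard ≥ 0.8, reporting the largest-|NES| member as representative.

## Core-gene accounting and the composite score

Per direction, deduplicated counts are the union of leading edges and
non-deduplicated counts the sum of leading-edge sizes; genes in ≥ 2
same-direction pathways are super-core genes (threshold 2 = the minimal
reading of "recurrent"). When recurrence is confined to one side, the
non-deduplicated positive/negative ratio can only move toward that side —
the amplification law the property tests enforce. Ratios are reported
alongside raw counts, NaN (with a diagnostic) when a direction is empty.

The composite per-dataset score is a **surrogate** (`surrogate-v1` in all
outputs): the exact aggregation used for published cross-dataset rankings
is not reproducible from available text, so the package defines its own —
per target and repeat, contribution 0 for a failed repeat, else
(1 − |f_path − f_gene|)·(1 − 2|f_path − 0.5|) where f_path is the repeat's
activated-pathway fraction and f_gene the target's positive-correlate
fraction; the score is the mean over targets and repeats, in [0, 1],
maximal only at perfect balance and concordance with zero failures. Scores
from this surrogate are comparable with each other, not with externally
published score values.

## Synthetic data: what it emulates, what it does not

The generator is a latent single-factor model: anchor = δ·1[case] + N(0,1)
(δ = 2 default, a strong but imperfect marker, oriented AUC ≈ 0.92);
coupled genes are ±β·anchor + N(0, σ) (β = 1.5, σ = 1 default, attained
|Spearman ρ| ≈ 0.8; β = 5 gives near-deterministic coupling, β ↔ σ trades
off the attained |ρ| monotonically). Equal positive and negative blocks
make the designed balance exactly 0.5; matched gene sets draw
round(purity·size) members from one block and the rest from null genes.
Chosen over explicit correlation-matrix sampling because it guarantees the
sign structure and gives one-knob control of correlation strength.

It does **not** emulate: negative-binomial count noise (the downstream
machinery is rank-based and inputs are assumed normalized), batch effects,
correlated null genes, heavy-tailed expression, or anything about gene
identity. Passing tests therefore demonstrate the *statistical machinery*
is correct and calibrated under a known factor structure — not that any
method is unbiased on real tumor/normal cohorts. With several anchors
sharing one class shift, anchors correlate with each other (ρ ≈ 0.5 at
δ = 2), so cross-block correlations exist by design; single-anchor
configurations are used where exact block recovery is asserted.

## Benchmark design and problem sizes

The default benchmark is a 500-gene × 80-sample balanced cohort (3 anchors,
50 + 50 coupled genes each, 197 null genes), three methods (rank-sum DE,
seeded mvAUC, AutoFS), two 10-set collections of size 15 at purity 0.9,
3 GSEA targets × 20 repeats × 200 permutations — sizes chosen so the whole
chain stays interactive on a laptop while every stage still has enough
signal for its calibration bands. AutoFS runs with desk-scale overrides
(k = 50, 3 folds, 5 search draws, 25% elimination steps over a 40-gene
prefilter). All stage seeds derive from one root seed via
`numpy.random.SeedSequence([root, stage, ...])`, so a rerun is bit-for-bit
identical; output floats are written with fixed formatting and manifests
with sorted keys for the same reason.

On this synthetic cohort the per-method GSEA differences enter through each
method's gene-level correlation universe and through restricting leading
edges to each method's selected genes; the enrichment rankings themselves
are target-level and method-independent, a deliberate desk-scale
simplification recorded in the manifest.

## Known limitations

- mvAUC coverage saturates fast on strongly separated data, so selected
  panels are small; the statistic says nothing about redundancy *within*
  covered pairs beyond the greedy ordering.
- Gene-permutation GSEA ignores inter-gene correlation in the null and is
  anti-conservative for sets of co-regulated genes; on the synthetic data
  this is partly mitigated by the q < 0.25 gate but not removed.
- The composite score's failure penalty (0 contribution) conflates "no
  significant pathway" with "maximally imbalanced"; both are treated as
  evidence against a method.
- Exact rank-sum enumeration is skipped in the presence of ties; with
  heavily discretized data and small samples the normal approximation can
  be slightly liberal.
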