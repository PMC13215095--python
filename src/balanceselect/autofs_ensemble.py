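"""AutoFS: ensemble- and search-based feature selection.

The strategy unions two complementary screens:

* a univariate filter — top-k genes by the one-way ANOVA F statistic
  between the two classes (statistic-driven signal);
* recursive elimination over an ensemble of base learners — a maximal-margin
  linear classifier, a decision tree and gradient-boosted trees — dropping
  the lowest mean-importance features and scoring every visited subset size
  by stratified cross-validated accuracy (model-driven signal).

Hyperparameters of the base learners are chosen by randomized search over a
predefined space, and the final model is a stacked generalization: level-1
out-of-fold predictions of the base learners, fused by a logistic-regression
meta-learner. The result is a ranked core feature subset with normalized
importances and per-gene provenance (which screen proposed it).

:class:`AutoFSSelector` is the scikit-learn estimator; :func:`autofs` is the
ExpressionMatrix-facing wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import loguniform
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import GradientBoostingClassifier, StackingClassifier
from sklearn.feature_selection import SelectorMixin, f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import (ParameterSampler, StratifiedKFold,
                                     cross_val_score)
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted, check_X_y

from .formats_io import ExpressionMatrix

__all__ = ["AutoFSConfig", "AutoFSResult", "AutoFSSelector",
           "univariate_rank", "recursive_eliminate", "autofs"]


def default_search_space() -> dict[str, dict]:
    return {
        "svm": {"C": loguniform(1e-2, 1e2)},
        "tree": {"max_depth": [1, 2, 3, 4, 5, 6],
                 "min_samples_leaf": [1, 2, 3, 5]},
        "gboost": {"n_estimators": [25, 50, 100],
                   "learning_rate": loguniform(0.01, 0.3),
                   "max_depth": [1, 2, 3]},
    }


@dataclass
class AutoFSConfig:
    """Knobs of the AutoFS pipeline.

    ``k_univariate`` defaults to min(100, n_genes // 10) (at least 1) when
    left as None. ``rfe_step`` drops that many lowest-importance features
    per elimination round (a fraction in (0, 1) drops that fraction);
    ``rfe_prefilter`` restricts elimination to the top-N univariate genes,
    None meaning no prefilter.
    """

    k_univariate: int | None = None
    cv_folds: int = 5
    n_search_iterations: int = 25
    search_space: Mapping[str, Mapping] = field(default_factory=default_search_space)
    base_learners: Sequence[str] = ("svm", "tree", "gboost")
    rfe_step: float = 1
    rfe_prefilter: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_search_iterations < 1:
            raise ValueError("n_search_iterations must be >= 1")
        unknown = set(self.search_space) - set(self.base_learners)
        if unknown:
            raise ValueError(f"search_space keys not in base_learners: {unknown}")
        if not self.base_learners:
            raise ValueError("need at least one base learner")

    def resolved_k(self, n_genes: int) -> int:
        if self.k_univariate is not None:
            if not 1 <= self.k_univariate <= n_genes:
                raise ValueError("k_univariate out of range")
            return self.k_univariate
        return max(1, min(100, n_genes // 10))


@dataclass
class AutoFSResult:
    """Ranked core subset with importances summing to one."""

    selected: list[str]
    importances: dict[str, float]
    cv_accuracy: float
    provenance: dict[str, str]      # gene -> {univariate, recursive, both}
    hyperparameters: dict[str, dict]
    base_cv_accuracy: dict[str, float]


def _make_learner(name: str, seed: int, params: Mapping | None = None):
    params = dict(params or {})
    if name == "svm":
        return LinearSVC(random_state=seed, max_iter=20000, **params)
    if name == "tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if name == "gboost":
        params.setdefault("n_estimators", 50)
        return GradientBoostingClassifier(random_state=seed, **params)
    raise ValueError(f"unknown base learner {name!r}")


def _importance(model) -> np.ndarray:
    if hasattr(model, "feature_importances_"):
        imp = np.asarray(model.feature_importances_, dtype=float)
    else:
        imp = np.abs(np.asarray(model.coef_, dtype=float)).ravel()
    total = imp.sum()
    return imp / total if total > 0 else np.full_like(imp, 1.0 / imp.size)


class AutoFSSelector(SelectorMixin, BaseEstimator):
    """scikit-learn estimator wrapping the AutoFS strategy.

    Attributes (after fit): ``selected_idx_``, ``importances_`` (aligned with
    ``selected_idx_``, sum 1), ``provenance_``, ``cv_accuracy_`` (stacked
    model), ``base_cv_accuracy_``, ``best_params_``.
    """

    def __init__(self, config: AutoFSConfig | None = None):
        self.config = config

    # -- stages -------------------------------------------------------------

    @staticmethod
    def _f_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            f, _ = f_classif(X, y)
        return np.nan_to_num(f, nan=0.0, posinf=0.0)  # constant gene -> 0

    def _univariate_order(self, X, y, names) -> np.ndarray:
        f = self._f_scores(X, y)
        return np.lexsort((names, -f))

    def _ensemble_importance(self, X, y, cfg: AutoFSConfig,
                             params: Mapping[str, Mapping]) -> np.ndarray:
        imps = []
        for name in cfg.base_learners:
            model = _make_learner(name, cfg.seed, params.get(name))
            model.fit(X, y)
            imps.append(_importance(model))
        return np.mean(imps, axis=0)

    def _cv_score(self, model, X, y, cfg: AutoFSConfig) -> float:
        cv = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True,
                             random_state=cfg.seed)
        return float(cross_val_score(model, X, y, cv=cv, scoring="accuracy").mean())

    def _eliminate(self, X, y, idx: np.ndarray, cfg: AutoFSConfig,
                   params: Mapping[str, Mapping]) -> np.ndarray:
        """Recursive elimination: returns the surviving column indices of the
        subset size with the best mean CV accuracy (ties -> smaller)."""
        n0 = len(idx)
        if min(np.bincount(y)) < cfg.cv_folds:
            raise ValueError("fewer samples per class than CV folds")
        best: tuple[float, int, np.ndarray] | None = None
        current = idx.copy()
        while True:
            Xs = X[:, current]
            score = np.mean([
                self._cv_score(_make_learner(n, cfg.seed, params.get(n)),
                               Xs, y, cfg)
                for n in cfg.base_learners
            ])
            if best is None or score > best[0] or \
                    (score == best[0] and len(current) < best[1]):
                best = (float(score), len(current), current.copy())
            if len(current) == 1:
                break
            imp = self._ensemble_importance(Xs, y, cfg, params)
            step = cfg.rfe_step
            drop = max(1, int(round(step * len(current)))) if step < 1 else int(step)
            drop = min(drop, len(current) - 1)
            order = np.argsort(imp, kind="stable")  # lowest importance first
            current = np.delete(current, order[:drop])
        return best[2]

    def _search(self, X, y, cfg: AutoFSConfig) -> tuple[dict, dict]:
        """Randomized per-learner hyperparameter search, CV-accuracy scored."""
        chosen: dict[str, dict] = {}
        base_scores: dict[str, float] = {}
        for name in cfg.base_learners:
            space = cfg.search_space.get(name, {})
            if not space:
                chosen[name] = {}
                base_scores[name] = self._cv_score(
                    _make_learner(name, cfg.seed), X, y, cfg)
                continue
            sampler = ParameterSampler(dict(space), cfg.n_search_iterations,
                                       random_state=cfg.seed)
            best_score, best_params = -np.inf, {}
            for params in sampler:
                score = self._cv_score(_make_learner(name, cfg.seed, params),
                                       X, y, cfg)
                if score > best_score:
                    best_score, best_params = score, params
            chosen[name] = best_params
            base_scores[name] = best_score
        return chosen, base_scores

    def _stack(self, cfg: AutoFSConfig, params: Mapping[str, Mapping]):
        estimators = [(n, _make_learner(n, cfg.seed, params.get(n)))
                      for n in cfg.base_learners]
        return StackingClassifier(
            estimators=estimators,
            final_estimator=LogisticRegression(max_iter=2000,
                                               random_state=cfg.seed),
            cv=StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True,
                               random_state=cfg.seed),
        )

    # -- fit ----------------------------------------------------------------

    def fit(self, X, y, feature_names=None):
        cfg = self.config or AutoFSConfig()
        if hasattr(X, "columns") and feature_names is None:
            feature_names = [str(c) for c in X.columns]
        X, y = check_X_y(X, y)
        if len(np.unique(y)) != 2:
            raise ValueError("AutoFS requires exactly two classes")
        n_feat = X.shape[1]
        names = np.asarray(
            feature_names if feature_names is not None
            else [f"x{i}" for i in range(n_feat)], dtype=object)

        k = cfg.resolved_k(n_feat)
        uni_order = self._univariate_order(X, y, names)
        uni_idx = uni_order[:k]

        rfe_pool = uni_order[:cfg.rfe_prefilter] if cfg.rfe_prefilter \
            else np.arange(n_feat)
        chosen, base_scores = self._search(X[:, np.sort(rfe_pool)], y, cfg)
        # remap: search ran on the pool; params are learner-level, reusable
        rfe_idx = self._eliminate(X, y, np.sort(rfe_pool), cfg, chosen)

        uni_set, rfe_set = set(uni_idx.tolist()), set(rfe_idx.tolist())
        selected = sorted(uni_set | rfe_set, key=lambda j: str(names[j]))
        prov = {}
        for j in selected:
            prov[str(names[j])] = (
                "both" if j in uni_set and j in rfe_set
                else "univariate" if j in uni_set else "recursive")

        Xsel = X[:, selected]
        stack = self._stack(cfg, chosen)
        cv_acc = self._cv_score(stack, Xsel, y, cfg)
        stack.fit(Xsel, y)

        imp = self._ensemble_importance(Xsel, y, cfg, chosen)
        imp = imp / imp.sum()

        self.config_ = cfg
        self.n_features_in_ = n_feat
        self.feature_names_in_ = names
        self.selected_idx_ = list(selected)
        self.importances_ = imp
        self.provenance_ = prov
        self.cv_accuracy_ = float(cv_acc)
        self.base_cv_accuracy_ = base_scores
        self.best_params_ = chosen
        self.stacked_model_ = stack
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "selected_idx_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_idx_] = True
        return mask

    def result_(self) -> AutoFSResult:
        check_is_fitted(self, "selected_idx_")
        names = self.feature_names_in_
        sel = [str(names[j]) for j in self.selected_idx_]
        return AutoFSResult(
            selected=sel,
            importances={g: float(w) for g, w in zip(sel, self.importances_)},
            cv_accuracy=self.cv_accuracy_,
            provenance=dict(self.provenance_),
            hyperparameters={k: dict(v) for k, v in self.best_params_.items()},
            base_cv_accuracy=dict(self.base_cv_accuracy_),
        )


# ---------------------------------------------------------------------------
# ExpressionMatrix-facing functions
# ---------------------------------------------------------------------------


def univariate_rank(matrix: ExpressionMatrix, k: int) -> list[str]:
    """Top-k genes by the between-class ANOVA F statistic (descending F,
    ties and degenerate constant genes ordered lexicographically last)."""
    if not 1 <= k <= matrix.n_genes:
        raise ValueError(f"k={k} out of range [1, {matrix.n_genes}]")
    names = np.asarray(matrix.gene_ids, dtype=object)
    f = AutoFSSelector._f_scores(matrix.X, matrix.y)
    order = np.lexsort((names, -f))
    return [str(names[j]) for j in order[:k]]


def recursive_eliminate(matrix: ExpressionMatrix,
                        config: AutoFSConfig | None = None) -> list[str]:
    """Ensemble recursive elimination; returns the CV-optimal gene subset."""
    cfg = config or AutoFSConfig()
    sel = AutoFSSelector(cfg)
    names = np.asarray(matrix.gene_ids, dtype=object)
    X, y = matrix.X, matrix.y
    pool = np.arange(matrix.n_genes)
    if cfg.rfe_prefilter:
        pool = np.sort(sel._univariate_order(X, y, names)[:cfg.rfe_prefilter])
    params = {n: {} for n in cfg.base_learners}
    idx = sel._eliminate(X, y, pool, cfg, params)
    return sorted(str(names[j]) for j in idx)


def autofs(matrix: ExpressionMatrix,
           config: AutoFSConfig | None = None) -> AutoFSResult:
    """Full AutoFS pipeline on an expression matrix."""
    sel = AutoFSSelector(config)
    sel.fit(matrix.X, matrix.y, feature_names=matrix.gene_ids)
    return sel.result_()
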