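"""Elastic-net logistic models over expression or principal-component
feature spaces.

Feature recipes are fit on training cells only: gene-wise z-scaling, greedy
correlation pruning (no retained pair with |Pearson r| above the cutoff;
genes visited in variance-descending order, keeping the earlier gene), and an
optional filter — a per-gene rank-sum association test (p < 0.01), a
DE-based Bonferroni filter (adjusted p < 0.05), or, in PCA space, the
explained-variance rule (> 1e-4). The classifier broadcasts clone labels to
cells, fits a penalized logistic model (mixing alpha in [0, 1], 0 = ridge,
1 = lasso; strength lambda), aggregates cell probabilities to clones by max
and thresholds like the signature family.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.stats as st
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

from .io import CellMatrix
from .scoring import ScoreVector, aggregate_clone_scores, fit_threshold

__all__ = [
    "FeatureRecipe",
    "ElasticNetModel",
    "fit_recipe",
    "apply_recipe",
    "fit_elastic_net",
    "predict_lr",
    "ElasticNetTrtClassifier",
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_ALPHA_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-4, 1, 6))

RNA_FILTERS = ("none", "wilcoxon_p01", "de_bonferroni05")
PCA_FILTERS = ("wilcoxon_p01", "pc_var_1e-4")


@dataclasses.dataclass
class FeatureRecipe:
    """Train-fitted feature construction (space, filter, artifacts)."""

    space: str  # 'rna' | 'pca'
    filter: str
    correlation_cutoff: float = 0.8
    # fitted artifacts
    kept_genes_: list | None = None
    gene_mean_: np.ndarray | None = None
    gene_sd_: np.ndarray | None = None
    gene_index_: list | None = None
    components_: np.ndarray | None = None
    explained_variance_ratio_: np.ndarray | None = None
    kept_pcs_: np.ndarray | None = None


@dataclasses.dataclass
class ElasticNetModel:
    """Fitted penalized logistic model (alpha mixing, lambda strength)."""

    alpha: float
    lam: float
    coef: np.ndarray
    intercept: float
    recipe: FeatureRecipe | None = None


def _greedy_corr_prune(Z: np.ndarray, cutoff: float) -> np.ndarray:
    """Indices of kept columns: visit in variance-descending order of the
    unscaled data handled by the caller; here columns are assumed already
    ordered, keep a column unless |r| > cutoff with an earlier kept one."""
    n = Z.shape[1]
    if n == 0:
        return np.array([], dtype=int)
    C = np.corrcoef(Z, rowvar=False)
    C = np.nan_to_num(C, nan=0.0)
    kept: list[int] = []
    for j in range(n):
        if all(abs(C[j, k]) <= cutoff for k in kept):
            kept.append(j)
    return np.asarray(kept, dtype=int)


def fit_recipe(
    cm: CellMatrix,
    labels: np.ndarray,
    space: str = "rna",
    filter: str = "none",
    correlation_cutoff: float = 0.8,
    de_fn=None,
) -> FeatureRecipe:
    """Fit a feature recipe on training cells.

    ``labels`` is boolean per cell (True = reactive); it is only used by the
    association filters. ``de_fn`` supplies the DE engine for the
    ``de_bonferroni05`` filter (default: the cell-level rank-sum engine).
    """
    if cm.lognorm is None:
        raise ValueError("lognorm layer absent")
    labels = np.asarray(labels, dtype=bool)
    if space == "rna" and filter not in RNA_FILTERS:
        raise ValueError(f"filter {filter!r} invalid for rna space")
    if space == "pca" and filter not in PCA_FILTERS:
        raise ValueError(f"filter {filter!r} invalid for pca space")

    X = cm.lognorm.T  # cells x genes
    mean, sd = X.mean(axis=0), X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = (X - mean) / sd_safe

    recipe = FeatureRecipe(
        space=space,
        filter=filter,
        correlation_cutoff=correlation_cutoff,
        gene_mean_=mean,
        gene_sd_=sd_safe,
        gene_index_=list(cm.gene_ids),
    )

    if space == "rna":
        order = np.argsort(-X.var(axis=0), kind="stable")
        kept_rel = _greedy_corr_prune(Z[:, order], correlation_cutoff)
        kept = order[kept_rel]
        if filter == "wilcoxon_p01":
            p = _ranksum_p(Z[:, kept], labels)
            kept = kept[p < 0.01]
        elif filter == "de_bonferroni05":
            if de_fn is None:
                from .de import wilcoxon_de

                de_fn = wilcoxon_de
            de = de_fn(cm, labels, adjust="bonferroni")
            sig_genes = set(de.table.index[de.table["padj"] < 0.05])
            kept = np.array([j for j in kept if cm.gene_ids[j] in sig_genes], dtype=int)
        if kept.size == 0:
            raise ValueError("all features filtered out")
        kept = np.sort(kept)
        recipe.kept_genes_ = [cm.gene_ids[j] for j in kept]
        return recipe

    # pca space
    n_comp = min(Z.shape[0] - 1, Z.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full").fit(Z)
    recipe.components_ = pca.components_
    recipe.explained_variance_ratio_ = pca.explained_variance_ratio_
    scores = pca.transform(Z)
    if filter == "pc_var_1e-4":
        keep = np.flatnonzero(pca.explained_variance_ratio_ > 1e-4)
    else:
        p = _ranksum_p(scores, labels)
        keep = np.flatnonzero(p < 0.01)
    if keep.size == 0:
        raise ValueError("all features filtered out")
    recipe.kept_pcs_ = keep
    return recipe


def _ranksum_p(F: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-column two-sided rank-sum p of association with the labels."""
    x1, x0 = F[labels], F[~labels]
    flat = np.ptp(F, axis=0) == 0
    p = np.ones(F.shape[1])
    if (~flat).any():
        res = st.mannwhitneyu(
            x1[:, ~flat], x0[:, ~flat], alternative="two-sided", method="asymptotic", axis=0
        )
        p[~flat] = res.pvalue
    return p


def apply_recipe(recipe: FeatureRecipe, cm: CellMatrix) -> np.ndarray:
    """Transform cells into the recipe's feature space (train artifacts only).

    Applying a recipe is idempotent with respect to the training artifacts:
    the same matrix always maps to the same features.
    """
    idx = {g: i for i, g in enumerate(cm.gene_ids)}
    try:
        cols = [idx[g] for g in recipe.gene_index_]
    except KeyError as exc:
        raise ValueError(f"matrix lacks recipe gene {exc}") from exc
    X = cm.lognorm.T[:, cols]
    Z = (X - recipe.gene_mean_) / recipe.gene_sd_
    if recipe.space == "rna":
        keep = [recipe.gene_index_.index(g) for g in recipe.kept_genes_]
        return Z[:, keep]
    scores = Z @ recipe.components_.T
    return scores[:, recipe.kept_pcs_]


def fit_elastic_net(X: np.ndarray, y: np.ndarray, alpha: float, lam: float) -> ElasticNetModel:
    """Penalized logistic fit; objective (1/n) sum loss + lam * penalty with
    elastic-net mixing alpha (0 = ridge, 1 = lasso); intercept unpenalized."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if not np.isfinite(X).all():
        raise ValueError("non-finite features")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    n = X.shape[0]
    C = 1.0 / max(n * lam, 1e-12)
    clf = LogisticRegression(
        solver="saga",
        l1_ratio=float(alpha),
        C=C,
        max_iter=20000,
        tol=1e-7,
        random_state=0,
    )
    clf.fit(X, y)
    if clf.n_iter_[0] >= 20000:
        raise RuntimeError(
            f"elastic-net solver did not converge (alpha={alpha}, lam={lam}, "
            f"n={n}, p={X.shape[1]})"
        )
    coef = clf.coef_.ravel()
    # the intercept is unpenalized: profile it out exactly given the
    # coefficients (Newton on the 1-D logistic score; a no-op at the joint
    # optimum, and it removes solver bias in the heavy-penalty limit)
    eta0 = X @ coef
    b = float(clf.intercept_[0])
    for _ in range(100):
        p = 1.0 / (1.0 + np.exp(-(eta0 + b)))
        grad = float(np.sum(p - y))
        hess = float(np.sum(p * (1 - p)))
        if hess <= 0:
            break
        step = grad / hess
        b -= step
        if abs(step) < 1e-12:
            break
    return ElasticNetModel(alpha=float(alpha), lam=float(lam), coef=coef, intercept=b)


def predict_lr(model: ElasticNetModel, X: np.ndarray) -> np.ndarray:
    """Cell probabilities through the logistic link."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.coef.size:
        raise ValueError(
            f"feature mismatch: model has {model.coef.size}, data has {X.shape[1]}"
        )
    eta = X @ model.coef + model.intercept
    return 1.0 / (1.0 + np.exp(-eta))


class ElasticNetTrtClassifier(BaseEstimator, ClassifierMixin):
    """Tumor-reactivity classifier of the elastic-net LR family.

    Cell-level training labels are the broadcast clone labels; clone scores
    are the maximum cell probability; the decision threshold is fit on
    training clone probabilities.
    """

    def __init__(
        self,
        space="rna",
        filter="none",
        alpha=0.5,
        lam=1e-2,
        correlation_cutoff=0.8,
        de_method=None,
    ):
        self.space = space
        self.filter = filter
        self.alpha = alpha
        self.lam = lam
        self.correlation_cutoff = correlation_cutoff
        self.de_method = de_method

    def _cell_labels(self, cm: CellMatrix, ct: pd.DataFrame):
        labeled = ct[ct["label"].isin(["tumor_reactive", "non_tumor_reactive"])]
        clone_label = labeled.set_index("clone_id")["label"]
        lab = cm.cell_meta["clone_id"].map(clone_label)
        mask = lab.notna().to_numpy()
        return labeled, mask, (lab[mask] == "tumor_reactive").to_numpy()

    def fit(self, cm: CellMatrix, ct: pd.DataFrame):
        labeled, mask, y = self._cell_labels(cm, ct)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        sub = cm.subset_cells(mask)
        de_fn = None
        if self.de_method is not None:
            from .de import get_de_method

            de_fn = get_de_method(self.de_method) if isinstance(self.de_method, str) else self.de_method
        self.recipe_ = fit_recipe(
            sub,
            y,
            space=self.space,
            filter=self.filter,
            correlation_cutoff=self.correlation_cutoff,
            de_fn=de_fn,
        )
        F = apply_recipe(self.recipe_, sub)
        self.model_ = fit_elastic_net(F, y, alpha=self.alpha, lam=self.lam)
        self.model_.recipe = self.recipe_
        proba = predict_lr(self.model_, F)
        sv = ScoreVector(raw=pd.Series(proba, index=sub.cell_barcodes), method="lr_proba")
        clone_scores = aggregate_clone_scores(sv, sub, labeled)
        y_clone = (labeled["label"] == "tumor_reactive").to_numpy()
        self.threshold_model_ = fit_threshold(clone_scores.raw.to_numpy(), y_clone)
        self.classes_ = np.array([False, True])
        return self

    def decision_function(self, cm: CellMatrix, ct: pd.DataFrame) -> pd.Series:
        F = apply_recipe(self.recipe_, cm)
        proba = predict_lr(self.model_, F)
        sv = ScoreVector(raw=pd.Series(proba, index=cm.cell_barcodes), method="lr_proba")
        return aggregate_clone_scores(sv, cm, ct).raw

    def predict(self, cm: CellMatrix, ct: pd.DataFrame) -> pd.Series:
        scores = self.decision_function(cm, ct)
        return pd.Series(
            self.threshold_model_.predict(scores.to_numpy()),
            index=scores.index,
            name="trt_call",
        )
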