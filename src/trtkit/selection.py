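"""Leave-one-patient-out nested cross-validation, performance metrics,
y-randomization and signature comparison.

The outer loop holds out one whole patient per fold; the inner loop is a
LOPO cross-validation over the remaining patients used to choose
hyperparameters by mean inner MCC. The generalization estimate is the
unweighted mean of outer-fold MCCs (each patient weighted equally); pooled
metrics over all outer-fold clones are also reported. The winning model is
refit on all data after a final LOPO hyperparameter tuning pass.

MCC uses the zero-denominator -> 0 convention ("reliable" MCC).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import scipy.stats as st
from sklearn.base import clone as sk_clone
from sklearn.model_selection import ParameterGrid

from .io import CellMatrix
from .simulate import permute_labels

__all__ = [
    "mcc",
    "accuracy",
    "roc_auc",
    "jaccard",
    "FoldPlan",
    "make_lopo_folds",
    "ModelSpec",
    "evaluate_lopo",
    "nested_cv",
    "y_randomization",
    "build_signature_registry",
    "build_lr_registry",
    "default_registry",
]


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient; any zero factor in the denominator
    yields 0 by convention."""
    if min(tp, fp, tn, fn) < 0 or tp + fp + tn + fn == 0:
        raise ValueError("counts must be non-negative with a positive total")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def accuracy(tp: int, fp: int, tn: int, fn: int) -> float:
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    return (tp + tn) / total


def roc_auc(scores, labels, return_curve: bool = False):
    """AUC by the rank (Mann-Whitney) formulation with tie correction.

    Optionally returns the ROC points from a threshold sweep over the
    distinct scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = st.rankdata(scores)
    auc = (ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    if not return_curve:
        return float(auc)
    pts = [(0.0, 0.0)]
    for thr in np.unique(scores)[::-1]:
        pred = scores >= thr
        pts.append(
            (float((pred & ~labels).sum() / n0), float((pred & labels).sum() / n1))
        )
    pts.append((1.0, 1.0))
    return float(auc), pts


def jaccard(genes_a, genes_b) -> float:
    """|A intersect B| / |A union B|; both empty -> 0 by convention."""
    a, b = set(genes_a), set(genes_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray):
    tp = int(np.sum(y_pred & y_true))
    fp = int(np.sum(y_pred & ~y_true))
    tn = int(np.sum(~y_pred & ~y_true))
    fn = int(np.sum(~y_pred & y_true))
    return tp, fp, tn, fn


# ---------------------------------------------------------------------------
# folds


@dataclasses.dataclass
class FoldPlan:
    """One (train patients, test patient) pair per patient."""

    folds: list  # of (tuple_of_train_patients, test_patient)

    def __iter__(self):
        return iter(self.folds)

    def __len__(self):
        return len(self.folds)


def make_lopo_folds(ct: pd.DataFrame) -> FoldPlan:
    patients = sorted(ct["patient"].unique())
    if len(patients) < 2:
        raise ValueError("leave-one-patient-out needs at least 2 patients")
    folds = [
        (tuple(p for p in patients if p != test), test) for test in patients
    ]
    return FoldPlan(folds=folds)


# ---------------------------------------------------------------------------
# model registry


@dataclasses.dataclass
class ModelSpec:
    """A named estimator prototype with a hyperparameter grid."""

    model_id: str
    estimator: object  # sklearn-style: get_params/set_params, fit, predict
    grid: dict  # param name -> list of values

    def configurations(self):
        return list(ParameterGrid(self.grid)) if self.grid else [{}]


def build_signature_registry(
    de_methods=("ql_f", "mod_t", "wilcoxon"),
    lengths=(30, 90),
    criteria=("p_value", "logFC"),
    sides=("up", "both"),
    score_methods=("average", "rank_auc", "u_score", "rank_mean"),
) -> list:
    """One signature-score model per DE engine, with the signature and
    scoring hyperparameters as its tuning grid."""
    from .scoring import SignatureScoreClassifier

    return [
        ModelSpec(
            model_id=f"sig_{m}",
            estimator=SignatureScoreClassifier(de_method=m),
            grid={
                "criterion": list(criteria),
                "length": list(lengths),
                "side": list(sides),
                "score_method": list(score_methods),
            },
        )
        for m in de_methods
    ]


def build_lr_registry(
    de_methods=("ql_f", "mod_t", "wilcoxon"),
    alpha_grid=None,
    lambda_grid=None,
) -> list:
    """Elastic-net LR model specs: RNA space with no filter, with the
    rank-sum association filter, and with one DE-Bonferroni filter per DE
    engine, plus the two PCA-space recipes. With eight registered DE engines
    this enumerates exactly ten RNA- and two PCA-based models."""
    from .lr import DEFAULT_ALPHA_GRID, DEFAULT_LAMBDA_GRID, ElasticNetTrtClassifier

    grid = {
        "alpha": list(alpha_grid or DEFAULT_ALPHA_GRID),
        "lam": list(lambda_grid or DEFAULT_LAMBDA_GRID),
    }
    specs = [
        ModelSpec("lr_rna_none", ElasticNetTrtClassifier(space="rna", filter="none"), dict(grid)),
        ModelSpec(
            "lr_rna_wilcoxon",
            ElasticNetTrtClassifier(space="rna", filter="wilcoxon_p01"),
            dict(grid),
        ),
    ]
    for m in de_methods:
        specs.append(
            ModelSpec(
                f"lr_rna_de_{m}",
                ElasticNetTrtClassifier(space="rna", filter="de_bonferroni05", de_method=m),
                dict(grid),
            )
        )
    specs.append(
        ModelSpec(
            "lr_pca_var", ElasticNetTrtClassifier(space="pca", filter="pc_var_1e-4"), dict(grid)
        )
    )
    specs.append(
        ModelSpec(
            "lr_pca_wilcoxon",
            ElasticNetTrtClassifier(space="pca", filter="wilcoxon_p01"),
            dict(grid),
        )
    )
    return specs


def default_registry() -> list:
    return build_signature_registry() + build_lr_registry()


# ---------------------------------------------------------------------------
# evaluation


def _fit_eval_fold(estimator, params, cm, ct, train_patients, test_patient, cache=None):
    """Fit on the training patients, evaluate clone-wise on the held-out
    patient. Returns (metrics dict or None if the fold is unusable).

    ``cache`` maps test_patient -> (cm_train, cm_test); the matrix split does
    not depend on labels, so repeated evaluations (e.g. label permutations)
    can share it.
    """
    est = sk_clone(estimator)
    if params:
        est.set_params(**params)
    tr_mask = ct["patient"].isin(train_patients)
    te_mask = ct["patient"] == test_patient
    ct_tr, ct_te = ct[tr_mask], ct[te_mask]
    lab_te = ct_te[ct_te["label"].isin(["tumor_reactive", "non_tumor_reactive"])]
    if ct_tr["label"].nunique() < 2 or len(lab_te) == 0:
        return None
    if cache is not None and test_patient in cache:
        cm_tr, cm_te = cache[test_patient]
    else:
        cm_tr = cm.subset_patients(train_patients)
        cm_te = cm.subset_patients([test_patient])
        if cache is not None:
            cache[test_patient] = (cm_tr, cm_te)
    est.fit(cm_tr, ct_tr)
    y_true = (lab_te["label"] == "tumor_reactive").to_numpy()
    y_pred = est.predict(cm_te, lab_te).to_numpy()
    scores = est.decision_function(cm_te, lab_te).to_numpy()
    tp, fp, tn, fn = _confusion(y_true, y_pred)
    out = {
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "mcc": mcc(tp, fp, tn, fn),
        "accuracy": accuracy(tp, fp, tn, fn),
        "auc": roc_auc(scores, y_true) if 0 < y_true.sum() < len(y_true) else np.nan,
    }
    return out


def evaluate_lopo(
    estimator, cm: CellMatrix, ct: pd.DataFrame, params=None, _cache=None
) -> pd.DataFrame:
    """Plain LOPO evaluation of one configuration; one row per fold."""
    rows = []
    for train_patients, test_patient in make_lopo_folds(ct):
        res = _fit_eval_fold(
            estimator, params or {}, cm, ct, train_patients, test_patient, cache=_cache
        )
        if res is None:
            warnings.warn(f"fold {test_patient} skipped (one-class data)", stacklevel=2)
            continue
        res["fold"] = test_patient
        rows.append(res)
    return pd.DataFrame(rows)


def nested_cv(registry, cm: CellMatrix, ct: pd.DataFrame):
    """LOPO nested cross-validation over a model registry.

    Returns ``(perf, winner_id, final_model)``: a PerfRecord table (one row
    per model x outer fold, with the inner-selected hyperparameters and the
    outer confusion counts), the winning model id by mean outer MCC, and the
    winner refit on all data after a final LOPO tuning pass.
    """
    patients = sorted(ct["patient"].unique())
    if len(patients) < 3:
        raise ValueError("nested CV needs at least 3 patients")
    rows = []
    for spec in registry:
        for train_patients, test_patient in make_lopo_folds(ct):
            ct_outer = ct[ct["patient"].isin(train_patients)]
            best_params, best_inner = None, -np.inf
            for params in spec.configurations():
                inner = []
                for inner_train, inner_test in make_lopo_folds(ct_outer):
                    res = _fit_eval_fold(
                        spec.estimator, params, cm, ct_outer, inner_train, inner_test
                    )
                    if res is not None:
                        inner.append(res["mcc"])
                score = float(np.mean(inner)) if inner else -np.inf
                if score > best_inner:  # strict: ties keep grid order
                    best_inner, best_params = score, params
            res = _fit_eval_fold(
                spec.estimator, best_params or {}, cm, ct, train_patients, test_patient
            )
            if res is None:
                warnings.warn(f"outer fold {test_patient} skipped", stacklevel=2)
                continue
            rows.append(
                {
                    "model_id": spec.model_id,
                    "fold": test_patient,
                    "params": repr(best_params),
                    **res,
                }
            )
    perf = pd.DataFrame(rows)
    mean_mcc = perf.groupby("model_id", sort=False)["mcc"].mean()
    winner_id = mean_mcc.idxmax()
    spec = next(s for s in registry if s.model_id == winner_id)
    # final tuning: plain LOPO over all data across the winner's grid
    best_params, best_score = None, -np.inf
    for params in spec.configurations():
        folds = evaluate_lopo(spec.estimator, cm, ct, params=params)
        score = float(folds["mcc"].mean()) if len(folds) else -np.inf
        if score > best_score:
            best_score, best_params = score, params
    final = sk_clone(spec.estimator)
    if best_params:
        final.set_params(**best_params)
    final.fit(cm, ct)
    return perf, winner_id, final


def y_randomization(
    estimator, cm: CellMatrix, ct: pd.DataFrame, n_reps: int = 100, seed: int = 0, params=None
):
    """Label-permutation null of the LOPO evaluation.

    Each repetition permutes the clone-level labels uniformly, reruns the
    full LOPO train/test loop and records the fold-averaged MCC and accuracy.
    Returns ``(per_rep, summary)`` where summary holds mean/sd of both.
    """
    rng = np.random.default_rng(seed)
    rows = []
    cache: dict = {}
    for rep in range(n_reps):
        ct_perm = permute_labels(ct, seed=int(rng.integers(2**31 - 1)))
        folds = evaluate_lopo(estimator, cm, ct_perm, params=params, _cache=cache)
        rows.append(
            {
                "rep": rep,
                "mcc": float(folds["mcc"].mean()),
                "accuracy": float(folds["accuracy"].mean()),
            }
        )
    per_rep = pd.DataFrame(rows)
    summary = {
        "mcc_mean": float(per_rep["mcc"].mean()),
        "mcc_sd": float(per_rep["mcc"].std(ddof=1)) if n_reps > 1 else 0.0,
        "accuracy_mean": float(per_rep["accuracy"].mean()),
        "accuracy_sd": float(per_rep["accuracy"].std(ddof=1)) if n_reps > 1 else 0.0,
        "n_reps": n_reps,
    }
    return per_rep, summary
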