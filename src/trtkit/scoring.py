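"""Gene-signature scoring, train-based scaling, clone aggregation and
threshold fitting, plus the signature-score classifier tying them together.

Four per-cell scoring schemes are provided, generic analogues of the common
signature-scoring families (method tags: ``average``, ``rank_auc``,
``u_score``, ``rank_mean``); each maps a cell's expression and an up/down
gene signature to a scalar. Scores are scaled by training mean/sd, clone
scores are the maximum over member cells, and the decision threshold is the
training-accuracy-maximizing midpoint; thresholds and scaling are always
estimated on training data and transferred to test data unchanged.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import scipy.stats as st
from sklearn.base import BaseEstimator, ClassifierMixin

from .de import derive_signature, get_de_method
from .io import CellMatrix, Signature, pseudobulk_by_clone

__all__ = [
    "ScoreVector",
    "ThresholdModel",
    "score_average",
    "score_rank_auc",
    "score_u",
    "score_rank_mean",
    "scale_scores",
    "aggregate_clone_scores",
    "fit_threshold",
    "SignatureScoreClassifier",
]


@dataclasses.dataclass
class ScoreVector:
    """Scores for cells or clones, with optional train-based scaling."""

    raw: pd.Series  # index: barcodes or clone ids
    method: str
    mu: float | None = None
    sigma: float | None = None

    @property
    def scaled(self) -> pd.Series:
        if self.mu is None or self.sigma is None:
            raise ValueError("scores not scaled; call scale_scores")
        return (self.raw - self.mu) / self.sigma


@dataclasses.dataclass
class ThresholdModel:
    """Accuracy-maximizing decision threshold (score >= tau -> reactive)."""

    threshold: float
    train_accuracy: float

    def predict(self, scores) -> np.ndarray:
        return np.asarray(scores) >= self.threshold


def _signature_indices(cm: CellMatrix, sig: Signature):
    pos = {g: i for i, g in enumerate(cm.gene_ids)}
    up = [pos[g] for g in sig.up if g in pos]
    down = [pos[g] for g in sig.down if g in pos]
    n_missing = (len(sig.up) - len(up)) + (len(sig.down) - len(down))
    if n_missing:
        warnings.warn(f"{n_missing} signature genes absent from matrix; dropped", stacklevel=3)
    if not up and not down:
        raise ValueError("all signature genes missing from the matrix")
    return up, down


def score_average(
    cm: CellMatrix, sig: Signature, gene_stats: tuple[np.ndarray, np.ndarray] | None = None
) -> ScoreVector:
    """Mean z-scaled expression over up genes minus the down-gene mean.

    ``gene_stats`` (per-gene mean, sd) fixes the z-scaling; by default it is
    estimated from the scored cells. Pass training statistics to score test
    cells on the training scale. Genes with zero sd contribute z = 0.
    """
    up, down = _signature_indices(cm, sig)
    X = cm.lognorm
    if gene_stats is None:
        mean, sd = X.mean(axis=1), X.std(axis=1)
    else:
        mean, sd = gene_stats
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mean[:, None]) / sd[:, None]
    score = Z[up].mean(axis=0) if up else np.zeros(cm.n_cells)
    if down:
        score = score - Z[down].mean(axis=0)
    return ScoreVector(raw=pd.Series(score, index=cm.cell_barcodes), method="average")


def _ranks_desc(X: np.ndarray) -> np.ndarray:
    """Per-cell gene ranks, 1 = highest expression, average ties."""
    return st.rankdata(-X, axis=0)


def _capped_auc(ranks: np.ndarray, members: np.ndarray, cap: int) -> np.ndarray:
    """Mann-Whitney AUC between member genes and the rest after capping all
    ranks at ``cap + 1`` (columns = cells)."""
    rc = np.minimum(ranks, cap + 1)
    rr = st.rankdata(rc, axis=0)
    G = ranks.shape[0]
    S = members.size
    u = rr[members].sum(axis=0) - S * (S + 1) / 2.0
    return 1.0 - u / (S * (G - S))


def score_rank_auc(cm: CellMatrix, sig: Signature, top_frac: float = 0.05) -> ScoreVector:
    """Rank-recovery AUC of the signature within the top expression ranks.

    Genes are ranked by expression (descending, average ties) and ranks are
    capped at ``ceil(top_frac * G) + 1``; the score is the Mann-Whitney AUC
    between signature genes and background genes on the capped ranks. Perfect
    enrichment in the top ranks scores 1; a random gene set has expectation
    0.5 regardless of ``top_frac``. Down genes are scored on the reversed
    ranking and subtracted.
    """
    if not (0 < top_frac <= 1):
        raise ValueError("top_frac must lie in (0, 1]")
    up, down = _signature_indices(cm, sig)
    G = cm.n_genes
    cap = int(np.ceil(top_frac * G))
    r = _ranks_desc(cm.lognorm)
    score = _capped_auc(r, np.asarray(up), cap) if up else np.zeros(cm.n_cells)
    if down:
        r_rev = G + 1 - r
        score = score - _capped_auc(r_rev, np.asarray(down), cap)
    return ScoreVector(raw=pd.Series(score, index=cm.cell_barcodes), method="rank_auc")


def score_u(cm: CellMatrix, sig: Signature, rank_cap: int = 1500) -> ScoreVector:
    """Capped Mann-Whitney U score.

    Expression ranks (descending) are capped at ``rank_cap``; the score maps
    the capped-rank U statistic of the up genes to [0, 1], with 1 when the up
    genes occupy the top ranks and 0 when all sit at or beyond the cap. Down
    genes are scored on the reversed ranking and subtracted.
    """
    if rank_cap < 2:
        raise ValueError("rank_cap must be >= 2")
    up, down = _signature_indices(cm, sig)
    cap = min(rank_cap, cm.n_genes)
    r = _ranks_desc(cm.lognorm)

    def one_side(idx, ranks):
        S = len(idx)
        rc = np.minimum(ranks[idx], cap)
        u = rc.sum(axis=0) - S * (S + 1) / 2.0
        u_max = S * (cap - (S + 1) / 2.0)
        return 1.0 - u / u_max

    score = one_side(up, r) if up else np.zeros(cm.n_cells)
    if down:
        score = score - one_side(down, cm.n_genes + 1 - r)
    return ScoreVector(raw=pd.Series(score, index=cm.cell_barcodes), method="u_score")


def score_rank_mean(cm: CellMatrix, sig: Signature) -> ScoreVector:
    """Mean normalized rank of the up genes, centered to (-0.5, 0.5),
    minus the analogous down-gene term (high = up genes highly expressed)."""
    up, down = _signature_indices(cm, sig)
    G = cm.n_genes
    r_asc = G + 1 - _ranks_desc(cm.lognorm)  # 1 = lowest expression

    def centered(idx):
        return (r_asc[idx].mean(axis=0) - (G + 1) / 2.0) / G

    score = centered(up) if up else np.zeros(cm.n_cells)
    if down:
        score = score - centered(down)
    return ScoreVector(raw=pd.Series(score, index=cm.cell_barcodes), method="rank_mean")


def scale_scores(sv: ScoreVector, mu: float, sigma: float) -> ScoreVector:
    """Attach training mean/sd; test data never re-estimates them."""
    if sigma <= 0:
        raise ValueError("degenerate training scores: sigma must be > 0")
    return ScoreVector(raw=sv.raw, method=sv.method, mu=float(mu), sigma=float(sigma))


def aggregate_clone_scores(sv: ScoreVector, cm: CellMatrix, ct: pd.DataFrame) -> ScoreVector:
    """Clone score = maximum score over the clone's member cells."""
    clone_of_cell = cm.cell_meta["clone_id"]
    per_clone = sv.raw.groupby(clone_of_cell.to_numpy()).max()
    missing = [c for c in ct["clone_id"] if c not in per_clone.index]
    if missing:
        raise ValueError(f"clones without scored cells: {missing}")
    raw = per_clone.reindex(ct["clone_id"].to_numpy())
    raw.index = ct["clone_id"].to_numpy()
    return ScoreVector(raw=raw, method=sv.method, mu=sv.mu, sigma=sv.sigma)


def fit_threshold(scores, labels) -> ThresholdModel:
    """Exhaustive accuracy-maximizing threshold over candidate midpoints.

    Candidates are the midpoints between adjacent distinct sorted training
    scores; ties in accuracy are broken toward the smallest threshold. With
    all-equal scores the threshold falls back to that value (predicting every
    item reactive). Prediction rule: score >= tau -> tumor-reactive.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("need both classes to fit a threshold")
    uniq = np.unique(scores)
    if uniq.size == 1:
        tau = float(uniq[0])
        acc = float(np.mean(labels == (scores >= tau)))
        return ThresholdModel(threshold=tau, train_accuracy=acc)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    accs = np.array([np.mean(labels == (scores >= m)) for m in mids])
    best = int(np.argmax(accs))  # argmax takes the first (= smallest) midpoint
    return ThresholdModel(threshold=float(mids[best]), train_accuracy=float(accs[best]))


_SCORERS = {
    "average": score_average,
    "rank_auc": score_rank_auc,
    "u_score": score_u,
    "rank_mean": score_rank_mean,
}


class SignatureScoreClassifier(BaseEstimator, ClassifierMixin):
    """Tumor-reactivity classifier of the signature-score family.

    fit(cm, ct) runs differential expression between reactive and
    non-reactive training data, derives a signature (criterion / length /
    side hyperparameters), scores training cells, records the training score
    mean/sd and per-gene statistics, aggregates cell scores to clones by max,
    and fits the accuracy-maximizing threshold. predict(cm, ct) transfers all
    train-fitted quantities to new data.

    Parameters
    ----------
    de_method : str or callable
        ``'ql_f'`` / ``'mod_t'`` (pseudo-bulk on clone-average profiles),
        ``'wilcoxon'`` (cell-level), or a registered plugin name.
    criterion, length, side
        Signature-derivation hyperparameters.
    score_method : str
        One of ``average``, ``rank_auc``, ``u_score``, ``rank_mean``.
    threshold_level : str
        ``'clone'`` (default): threshold fit on clone-max scores against
        clone labels. ``'cell'``: fit on cell scores against broadcast
        labels, then applied to clone-max scores.
    """

    _PSEUDOBULK = {"ql_f", "mod_t"}

    def __init__(
        self,
        de_method="ql_f",
        criterion="p_value",
        length=90,
        side="both",
        score_method="average",
        top_frac=0.05,
        rank_cap=1500,
        adjust="bh",
        threshold_level="clone",
    ):
        self.de_method = de_method
        self.criterion = criterion
        self.length = length
        self.side = side
        self.score_method = score_method
        self.top_frac = top_frac
        self.rank_cap = rank_cap
        self.adjust = adjust
        self.threshold_level = threshold_level

    # -- internals ---------------------------------------------------------

    def _labeled(self, ct: pd.DataFrame) -> pd.DataFrame:
        return ct[ct["label"].isin(["tumor_reactive", "non_tumor_reactive"])]

    def _run_de(self, cm: CellMatrix, ct: pd.DataFrame):
        labeled = self._labeled(ct)
        if isinstance(self.de_method, str) and self.de_method in self._PSEUDOBULK:
            profiles = pseudobulk_by_clone(cm, labeled)
            y = (labeled["label"] == "tumor_reactive").to_numpy()
            return get_de_method(self.de_method)(profiles, y, adjust=self.adjust)
        # cell-level engines
        clone_label = labeled.set_index("clone_id")["label"]
        lab = cm.cell_meta["clone_id"].map(clone_label)
        mask = lab.notna().to_numpy()
        sub = cm.subset_cells(mask)
        y = (lab[mask] == "tumor_reactive").to_numpy()
        fn = self.de_method if callable(self.de_method) else get_de_method(self.de_method)
        return fn(sub, y, adjust=self.adjust)

    def _score_cells(self, cm: CellMatrix) -> ScoreVector:
        if self.score_method == "average":
            return score_average(cm, self.signature_, gene_stats=self.gene_stats_)
        if self.score_method == "rank_auc":
            return score_rank_auc(cm, self.signature_, top_frac=self.top_frac)
        if self.score_method == "u_score":
            return score_u(cm, self.signature_, rank_cap=self.rank_cap)
        if self.score_method == "rank_mean":
            return score_rank_mean(cm, self.signature_)
        raise ValueError(f"unknown score_method {self.score_method!r}")

    # -- sklearn-style API -------------------------------------------------

    def fit(self, cm: CellMatrix, ct: pd.DataFrame):
        if cm.lognorm is None:
            raise ValueError("lognorm layer absent; call normalize_log first")
        labeled = self._labeled(ct)
        if labeled["label"].nunique() < 2:
            raise ValueError("training data must contain both classes")
        de = self._run_de(cm, ct)
        self.de_result_ = de
        self.signature_ = derive_signature(
            de, criterion=self.criterion, length=self.length, side=self.side
        )
        self.gene_stats_ = (cm.lognorm.mean(axis=1), cm.lognorm.std(axis=1))
        cell_scores = self._score_cells(cm)
        mu, sigma = float(cell_scores.raw.mean()), float(cell_scores.raw.std(ddof=0))
        if sigma <= 0:
            raise ValueError("degenerate training scores (zero variance)")
        cell_scores = scale_scores(cell_scores, mu, sigma)
        self.mu_, self.sigma_ = mu, sigma
        clone_scores = aggregate_clone_scores(cell_scores, cm, labeled)
        y_clone = (labeled["label"] == "tumor_reactive").to_numpy()
        if self.threshold_level == "cell":
            clone_label = labeled.set_index("clone_id")["label"]
            lab = cm.cell_meta["clone_id"].map(clone_label)
            mask = lab.notna().to_numpy()
            self.threshold_model_ = fit_threshold(
                cell_scores.scaled.to_numpy()[mask],
                (lab[mask] == "tumor_reactive").to_numpy(),
            )
        else:
            self.threshold_model_ = fit_threshold(clone_scores.scaled.to_numpy(), y_clone)
        self.classes_ = np.array([False, True])
        return self

    def decision_function(self, cm: CellMatrix, ct: pd.DataFrame) -> pd.Series:
        """Scaled clone-level scores aligned to the clonotype table rows."""
        cell_scores = scale_scores(self._score_cells(cm), self.mu_, self.sigma_)
        return aggregate_clone_scores(cell_scores, cm, ct).scaled

    def predict(self, cm: CellMatrix, ct: pd.DataFrame) -> pd.Series:
        scores = self.decision_function(cm, ct)
        return pd.Series(
            self.threshold_model_.predict(scores.to_numpy()),
            index=scores.index,
            name="trt_call",
        )

    def score_cells(self, cm: CellMatrix) -> ScoreVector:
        """Scaled per-cell scores under the trained model."""
        return scale_scores(self._score_cells(cm), self.mu_, self.sigma_)
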