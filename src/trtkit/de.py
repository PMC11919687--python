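"""Differential expression between reactive and non-reactive cells/clones.

Three engines are implemented, covering the two method classes used for
tumor-specificity signatures:

* ``wilcoxon_de`` — single-cell two-sided rank-sum test per gene on
  log-normalized values, no gene pre-filtering. Exact null when the smaller
  group has <= 8 observations and the gene has no ties; normal approximation
  with tie correction otherwise.
* ``ql_f_de`` — pseudo-bulk quasi-likelihood F analogue: a two-group Gaussian
  working model per gene on clone-average log-normalized profiles, with a
  quasi-dispersion shrunk toward a fitted mean-variance trend by empirical
  Bayes, and a QL F-test of the group effect.
* ``moderated_t_de`` — pseudo-bulk moderated-t analogue: the same per-gene
  linear model with trend-based variance shrinkage and augmented degrees of
  freedom.

Because the pseudo-bulk input is clone-average log10-normalized expression
(already variance-stabilized), Gaussian working models with moderated
dispersions are used rather than raw-count likelihoods.

Additional engines can be registered through :func:`register_de_method`; any
callable returning a :class:`DeResult` qualifies.

logFC is reported as the log2 fold change on the analysis scale:
``(mean_reactive - mean_other) / log10(2)`` of log10-normalized values.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.special import polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .io import CellMatrix, Signature

__all__ = [
    "DeResult",
    "wilcoxon_de",
    "ql_f_de",
    "moderated_t_de",
    "derive_signature",
    "register_de_method",
    "get_de_method",
    "DE_METHODS",
]

_LOG10_2 = np.log10(2.0)


@dataclasses.dataclass
class DeResult:
    """Per-gene DE statistics: columns logFC, stat, pval, padj."""

    table: pd.DataFrame  # index gene
    method: str
    adjust: str = "bh"

    def __post_init__(self):
        p = self.table["pval"].to_numpy()
        if ((p < 0) | (p > 1)).any():
            raise ValueError("p-values outside [0, 1]")


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    how = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
    return multipletests(p, method=how)[1]


# ---------------------------------------------------------------------------
# single-cell rank-sum test


def wilcoxon_de(cm: CellMatrix, labels: np.ndarray, adjust: str = "bh") -> DeResult:
    """Two-sided Mann-Whitney rank-sum test per gene at the cell level.

    ``labels`` is a boolean array (True = reactive) aligned to the matrix
    columns. All genes are tested; no min-fraction / fold-change filters.
    """
    if cm.lognorm is None:
        raise ValueError("lognorm layer absent; call normalize_log first")
    labels = np.asarray(labels, dtype=bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both groups must be non-empty")
    x1 = cm.lognorm[:, labels]
    x0 = cm.lognorm[:, ~labels]
    logfc = (x1.mean(axis=1) - x0.mean(axis=1)) / _LOG10_2

    flat = np.array([np.ptp(row) == 0 for row in cm.lognorm])
    stats = np.full(cm.n_genes, n1 * n0 / 2.0)
    pvals = np.ones(cm.n_genes)
    todo = ~flat
    if todo.any():
        if min(n1, n0) <= 8:
            for g in np.flatnonzero(todo):
                vals = np.concatenate([x1[g], x0[g]])
                method = "exact" if len(np.unique(vals)) == len(vals) else "asymptotic"
                res = st.mannwhitneyu(x1[g], x0[g], alternative="two-sided", method=method)
                stats[g], pvals[g] = res.statistic, res.pvalue
        else:
            res = st.mannwhitneyu(
                x1[todo], x0[todo], alternative="two-sided", method="asymptotic", axis=1
            )
            stats[todo] = res.statistic
            pvals[todo] = res.pvalue
    table = pd.DataFrame(
        {"logFC": logfc, "stat": stats, "pval": pvals, "padj": _adjust(pvals, adjust)},
        index=cm.gene_ids,
    )
    return DeResult(table=table, method="wilcoxon_sc", adjust=adjust)


# ---------------------------------------------------------------------------
# moderated-variance machinery shared by the pseudo-bulk engines


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def _squeeze_var(s2: np.ndarray, df: float, amean: np.ndarray):
    """Shrink gene-wise variances toward a lowess mean-variance trend.

    Returns (posterior variances, prior df, trend variances). Prior df is
    estimated by matching the spread of log variances around the trend to
    the theoretical scaled-F distribution (method of moments on the log
    scale, via trigamma).
    """
    eps = 1e-12
    logs2 = np.log(np.maximum(s2, eps))
    if len(s2) >= 10 and np.ptp(amean) > 0:
        trend = lowess(logs2, amean, frac=0.5, it=3, return_sorted=False)
    else:
        trend = np.full_like(logs2, logs2.mean())
    s0sq = np.exp(trend)
    z = logs2 - trend
    var_z = float(np.var(z, ddof=1)) if len(z) > 1 else 0.0
    expected = float(polygamma(1, df / 2.0))
    excess = var_z - expected
    if excess <= 0:
        d0 = np.inf
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
    if np.isinf(d0):
        post = s0sq.copy()
    else:
        post = (d0 * s0sq + df * s2) / (d0 + df)
    return post, d0, s0sq


def _two_group(profiles: pd.DataFrame, labels: np.ndarray):
    labels = np.asarray(labels, dtype=bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("need at least 2 clones per group")
    Y = profiles.to_numpy(dtype=float)
    y1, y0 = Y[:, labels], Y[:, ~labels]
    m1, m0 = y1.mean(axis=1), y0.mean(axis=1)
    rss = ((y1 - m1[:, None]) ** 2).sum(axis=1) + ((y0 - m0[:, None]) ** 2).sum(axis=1)
    df = n1 + n0 - 2
    s2 = rss / df
    return m1, m0, s2, df, n1, n0, Y.mean(axis=1)


def ql_f_de(profiles: pd.DataFrame, labels: np.ndarray, adjust: str = "bh") -> DeResult:
    """Quasi-likelihood F analogue on clone-average profiles.

    ``profiles`` is genes x clones; ``labels`` boolean per clone column.
    """
    m1, m0, s2, df, n1, n0, amean = _two_group(profiles, labels)
    post, d0, _ = _squeeze_var(s2, df, amean)
    w = 1.0 / (1.0 / n1 + 1.0 / n0)
    F = w * (m1 - m0) ** 2 / np.maximum(post, 1e-300)
    df2 = df + (0 if np.isinf(d0) else d0)
    if np.isinf(d0):
        pvals = st.chi2.sf(F, 1)  # infinite denominator df limit
    else:
        pvals = st.f.sf(F, 1, df2)
    bad = ~np.isfinite(F)
    F[bad], pvals[bad] = 0.0, 1.0
    table = pd.DataFrame(
        {
            "logFC": (m1 - m0) / _LOG10_2,
            "stat": F,
            "pval": pvals,
            "padj": _adjust(pvals, adjust),
        },
        index=profiles.index,
    )
    return DeResult(table=table, method="ql_f_pseudobulk", adjust=adjust)


def moderated_t_de(
    profiles: pd.DataFrame,
    labels: np.ndarray,
    adjust: str = "bh",
    prior_df: float | None = None,
) -> DeResult:
    """Moderated t analogue with a mean-variance trend prior.

    ``prior_df=0`` disables shrinkage, giving the ordinary pooled two-sample
    t statistic; ``None`` (default) estimates the prior df from the data.
    """
    m1, m0, s2, df, n1, n0, amean = _two_group(profiles, labels)
    if prior_df == 0:
        post, d0 = s2, 0.0
    elif prior_df is None:
        post, d0, _ = _squeeze_var(s2, df, amean)
    else:
        _, _, s0sq = _squeeze_var(s2, df, amean)
        d0 = float(prior_df)
        post = (d0 * s0sq + df * s2) / (d0 + df)
    se = np.sqrt(np.maximum(post, 1e-300) * (1.0 / n1 + 1.0 / n0))
    t = (m1 - m0) / se
    df2 = df + (0 if np.isinf(d0) else d0)
    if np.isinf(d0):
        pvals = 2 * st.norm.sf(np.abs(t))
    else:
        pvals = 2 * st.t.sf(np.abs(t), df2)
    bad = ~np.isfinite(t)
    t[bad], pvals[bad] = 0.0, 1.0
    table = pd.DataFrame(
        {
            "logFC": (m1 - m0) / _LOG10_2,
            "stat": t,
            "pval": pvals,
            "padj": _adjust(pvals, adjust),
        },
        index=profiles.index,
    )
    return DeResult(table=table, method="moderated_t_pseudobulk", adjust=adjust)


# ---------------------------------------------------------------------------
# plugin registry

DE_METHODS: dict = {
    "wilcoxon": wilcoxon_de,
    "ql_f": ql_f_de,
    "mod_t": moderated_t_de,
}


def register_de_method(name: str, fn) -> None:
    """Register an additional engine (any callable returning a DeResult)."""
    DE_METHODS[name] = fn


def get_de_method(name: str):
    try:
        return DE_METHODS[name]
    except KeyError:
        raise KeyError(f"unknown DE method {name!r}; known: {sorted(DE_METHODS)}") from None


# ---------------------------------------------------------------------------
# signature derivation


def derive_signature(
    de: DeResult, criterion: str = "p_value", length: int = 90, side: str = "both"
) -> Signature:
    """Select a signature from DE statistics.

    Genes are ordered by ascending p-value (``criterion='p_value'``) or
    descending absolute logFC (``'logFC'``); ties are broken by descending
    |logFC| then lexicographic gene id. ``side='up'`` keeps only positive-fold
    genes; ``'both'`` splits the length budget between up and down genes
    proportionally to their availability. If fewer genes are available than
    requested, the signature is truncated with a warning.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if criterion not in ("p_value", "logFC"):
        raise ValueError("criterion must be 'p_value' or 'logFC'")
    if side not in ("up", "both"):
        raise ValueError("side must be 'up' or 'both'")
    tab = de.table.copy()
    tab["absfc"] = tab["logFC"].abs()
    tab["gene"] = tab.index.astype(str)
    if criterion == "p_value":
        tab = tab.sort_values(["pval", "absfc", "gene"], ascending=[True, False, True])
    else:
        tab = tab.sort_values(["absfc", "pval", "gene"], ascending=[False, True, True])
    up_pool = tab[tab["logFC"] > 0]
    down_pool = tab[tab["logFC"] < 0]
    if side == "up":
        up = up_pool["gene"].head(length).tolist()
        down = []
    else:
        n_up, n_down = len(up_pool), len(down_pool)
        total = n_up + n_down
        if total == 0:
            up, down = [], []
        else:
            budget_up = int(round(length * n_up / total))
            budget_up = min(max(budget_up, length - n_down), n_up)
            budget_down = min(length - budget_up, n_down)
            up = up_pool["gene"].head(budget_up).tolist()
            down = down_pool["gene"].head(budget_down).tolist()
    if len(up) + len(down) < length:
        import warnings

        warnings.warn(
            f"only {len(up) + len(down)} genes available for signature length {length}",
            stacklevel=2,
        )
    stats = de.table.loc[up + down, ["logFC", "padj"]]
    return Signature(
        up=up,
        down=down,
        stats=stats,
        meta={
            "criterion": criterion,
            "length": length,
            "side": side,
            "de_method": de.method,
        },
    )
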