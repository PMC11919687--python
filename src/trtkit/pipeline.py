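"""Combinatorial TCR candidate selection (MixTRTpred).

Starting from a clonotype table annotated with tumor-reactivity scores/calls
and structural-avidity calls, the pipeline (1) drops clones not called
high-avidity, (2) drops clones not called tumor-reactive, (3) ranks the
survivors by tumor-reactivity score (ties: larger clone, then clone id),
(4) keeps the top N (default 20), (5) clusters their TCRs by the
physicochemical distance with UPGMA and cuts the dendrogram into k clusters
(default 5), and (6) selects the highest-scoring clone in each cluster. The
result is a small panel of high-avidity, tumor-reactive TCRs with diverse
physicochemical profiles, one per cluster.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings

import numpy as np
import pandas as pd

from .tcr import Dendrogram, cut_clusters, distance_matrix, upgma

__all__ = ["CandidatePanel", "run_mixtrtpred", "count_clinically_relevant", "annotate_clones"]


@dataclasses.dataclass
class CandidatePanel:
    """One top-scoring high-avidity tumor-reactive TCR per cluster."""

    records: pd.DataFrame  # clone_id, patient, cdr3a, cdr3b, trt_score, cluster, frequency
    provenance: dict
    dendrogram: Dendrogram | None = None

    def __len__(self):
        return len(self.records)

    def to_csv(self, path):
        self.records.to_csv(path, index=False)


def _rank_key(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(
        ["trt_score", "n_cells", "clone_id"], ascending=[False, False, True]
    )


def run_mixtrtpred(
    ct: pd.DataFrame,
    top_n: int = 20,
    k: int = 5,
    table=None,
    weights=(1.0, 1.0),
    provenance: dict | None = None,
) -> CandidatePanel:
    """Run the full candidate-selection pipeline on an annotated table.

    Requires columns ``trt_score``, ``trt_call`` and ``avidity_call``.
    Raises if fewer than ``k`` clones survive the two filters (choose a
    smaller ``k`` in that case).
    """
    for col in ("trt_score", "trt_call", "avidity_call"):
        if col not in ct.columns:
            raise ValueError(f"clone table lacks required column {col!r}")
    survivors = ct[(ct["avidity_call"] == "high") & (ct["trt_call"] == True)]  # noqa: E712
    if len(survivors) < k:
        raise ValueError(
            f"only {len(survivors)} clones survive the avidity and reactivity "
            f"filters; choose k <= {len(survivors)} (k can be adapted)"
        )
    ranked = _rank_key(survivors).head(top_n).reset_index(drop=True)
    if ranked["cdr3b"].nunique() == 1:
        warnings.warn(
            "all candidate CDR3beta sequences identical; clustering is "
            "degenerate and clusters follow the documented tie-break order",
            stacklevel=2,
        )
    dist = distance_matrix(ranked, table=table, weights=weights)
    dendro = upgma(dist)
    clusters = cut_clusters(dendro, k)
    ranked = ranked.assign(cluster=clusters.loc[ranked["clone_id"]].to_numpy())
    picks = (
        _rank_key(ranked).groupby("cluster", sort=False).head(1)
    )
    picks = _rank_key(picks).reset_index(drop=True)
    cols = [
        c
        for c in ["clone_id", "patient", "cdr3a", "cdr3b", "trt_score", "cluster", "frequency"]
        if c in picks.columns
    ]
    prov = dict(provenance or {})
    prov["config_hash"] = hashlib.sha256(
        json.dumps({"top_n": top_n, "k": k, "weights": list(weights)}, sort_keys=True).encode()
    ).hexdigest()[:12]
    prov.setdefault("top_n", top_n)
    prov.setdefault("k", k)
    return CandidatePanel(records=picks[cols], provenance=prov, dendrogram=dendro)


def count_clinically_relevant(ct: pd.DataFrame) -> pd.Series:
    """Per-patient count of clones called both tumor-reactive and
    high-avidity (the pool the candidate panel is drawn from)."""
    mask = (ct["avidity_call"] == "high") & (ct["trt_call"] == True)  # noqa: E712
    counts = ct[mask].groupby("patient").size()
    return counts.reindex(sorted(ct["patient"].unique()), fill_value=0).astype(int)


def annotate_clones(model, cm, ct: pd.DataFrame) -> pd.DataFrame:
    """Attach a trained tumor-reactivity model's clone scores and calls."""
    out = ct.copy()
    scores = model.decision_function(cm, out)
    out["trt_score"] = scores.to_numpy()
    out["trt_call"] = model.threshold_model_.predict(scores.to_numpy())
    return out
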