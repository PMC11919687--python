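"""CDR3 physicochemical features, structural-avidity analogue and clustering.

CDR3 loops are summarized by averaging per-residue physicochemical
descriptors (default: the five Atchley factors) over the central,
solvent-exposed part of the loop (default mask drops the 3 N-terminal and 2
C-terminal residues, which are buried framework-proximal positions), plus the
number of residues retained. A binary logistic model on the pooled CDR3beta
descriptors stands in for a structural-avidity (k_off class) predictor, and a
chain-weighted Euclidean distance on the concatenated alpha/beta descriptor
vectors stands in for a physicochemical TCR-TCR metric; both are trainable /
configurable analogues of published tools whose internals are not
redistributable, and are clearly labeled as such.

Clustering is UPGMA (average linkage) on that distance, cut into k clusters
by removing the k-1 highest merges.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.preprocessing import StandardScaler

from .io import AMINO_ACIDS

__all__ = [
    "ATCHLEY_FACTORS",
    "load_property_table",
    "featurize_cdr3",
    "AvidityClassifier",
    "fit_avidity_model",
    "predict_avidity",
    "tcr_distance",
    "distance_matrix",
    "Dendrogram",
    "upgma",
    "cut_clusters",
]

# Atchley et al. five-factor solution: F1 polarity/hydrophobicity,
# F2 secondary-structure propensity, F3 size/molecular volume,
# F4 codon composition, F5 electrostatic charge.
ATCHLEY_FACTORS = pd.DataFrame(
    {
        "A": [-0.591, -1.302, -0.733, 1.570, -0.146],
        "C": [-1.343, 0.465, -0.862, -1.020, -0.255],
        "D": [1.050, 0.302, -3.656, -0.259, -3.242],
        "E": [1.357, -1.453, 1.477, 0.113, -0.837],
        "F": [-1.006, -0.590, 1.891, -0.397, 0.412],
        "G": [-0.384, 1.652, 1.330, 1.045, 2.064],
        "H": [0.336, -0.417, -1.673, -1.474, -0.078],
        "I": [-1.239, -0.547, 2.131, 0.393, 0.816],
        "K": [1.831, -0.561, 0.533, -0.277, 1.648],
        "L": [-1.019, -0.987, -1.505, 1.266, -0.912],
        "M": [-0.663, -1.524, 2.219, -1.005, 1.212],
        "N": [0.945, 0.828, 1.299, -0.169, 0.933],
        "P": [0.189, 2.081, -1.628, 0.421, -1.392],
        "Q": [0.931, -0.179, -3.005, -0.503, -1.853],
        "R": [1.538, -0.055, 1.502, 0.440, 2.897],
        "S": [-0.228, 1.399, -4.760, 0.670, -2.647],
        "T": [-0.032, 0.326, 2.213, 0.908, 1.313],
        "V": [-1.337, -0.279, -0.544, 1.242, -1.262],
        "W": [-0.595, 0.009, 0.672, -2.128, -0.184],
        "Y": [0.260, 0.830, 3.097, -0.838, 1.512],
    },
    index=["F1", "F2", "F3", "F4", "F5"],
).T

DEFAULT_MASK = (3, 2)  # residues dropped from the N- and C-terminus


def load_property_table(path) -> pd.DataFrame:
    """Load an alternative per-residue descriptor table (TSV, residue column
    + one column per descriptor); must cover all 20 canonical amino acids."""
    tab = pd.read_csv(path, sep="\t")
    tab = tab.set_index(tab.columns[0])
    missing = set(AMINO_ACIDS) - set(tab.index)
    if missing:
        raise ValueError(f"property table missing residues {sorted(missing)}")
    if not np.isfinite(tab.to_numpy(dtype=float)).all():
        raise ValueError("property table contains non-finite values")
    return tab.loc[list(AMINO_ACIDS)].astype(float)


def featurize_cdr3(
    seq: str,
    mask: tuple[int, int] = DEFAULT_MASK,
    table: pd.DataFrame | None = None,
) -> np.ndarray:
    """Descriptor vector of one CDR3: per-descriptor mean over the masked
    (central) residues, concatenated with the selected length."""
    table = ATCHLEY_FACTORS if table is None else table
    seq = str(seq)
    bad = set(seq) - set(AMINO_ACIDS)
    if bad or not seq:
        raise ValueError(f"invalid CDR3 sequence {seq!r}: characters {sorted(bad)}")
    lo, hi = mask
    if len(seq) > lo + hi:
        core = seq[lo : len(seq) - hi] if hi else seq[lo:]
    else:
        warnings.warn(
            f"CDR3 {seq!r} shorter than mask {mask}; using full sequence",
            stacklevel=2,
        )
        core = seq
    rows = table.loc[list(core)].to_numpy(dtype=float)
    return np.concatenate([rows.mean(axis=0), [float(len(core))]])


class AvidityClassifier(BaseEstimator, ClassifierMixin):
    """Binary high/low structural-avidity analogue.

    A regularized logistic regression on pooled CDR3beta physicochemical
    descriptors (standardized with training statistics). This is a trainable
    stand-in for a published k_off-class predictor whose weights are not
    redistributable; the decision threshold on the high-class probability
    defaults to 0.5 and ties go to ``high`` (>= rule).
    """

    def __init__(self, alpha=0.0, lam=1e-3, mask=DEFAULT_MASK, threshold=0.5):
        self.alpha = alpha
        self.lam = lam
        self.mask = mask
        self.threshold = threshold

    def _features(self, sequences) -> np.ndarray:
        return np.vstack([featurize_cdr3(s, mask=self.mask) for s in sequences])

    def fit(self, sequences: Sequence[str], y):
        from .lr import fit_elastic_net

        y = np.asarray([1 if v in (1, True, "high") else 0 for v in y])
        if len(np.unique(y)) < 2:
            raise ValueError("both avidity classes must be present for fitting")
        X = self._features(sequences)
        self.scaler_ = StandardScaler().fit(X)
        self.model_ = fit_elastic_net(
            self.scaler_.transform(X), y, alpha=self.alpha, lam=self.lam
        )
        self.classes_ = np.array(["low", "high"])
        return self

    def predict_proba(self, sequences) -> np.ndarray:
        from .lr import predict_lr

        X = self.scaler_.transform(self._features(sequences))
        return predict_lr(self.model_, X)

    def predict(self, sequences) -> np.ndarray:
        p = self.predict_proba(sequences)
        return np.where(p >= self.threshold, "high", "low")


def fit_avidity_model(sequences, labels, **kwargs) -> AvidityClassifier:
    return AvidityClassifier(**kwargs).fit(sequences, labels)


def predict_avidity(model: AvidityClassifier, ct: pd.DataFrame) -> pd.DataFrame:
    """Annotate a clonotype table with high/low avidity calls.

    Clones lacking a CDR3beta are set to ``unknown`` (excluded downstream).
    """
    out = ct.copy()
    has_b = out["cdr3b"].notna() & (out["cdr3b"].astype(str) != "")
    calls = np.full(len(out), "unknown", dtype=object)
    if has_b.any():
        calls[has_b.to_numpy()] = model.predict(out.loc[has_b, "cdr3b"].tolist())
    if (~has_b).any():
        warnings.warn(
            f"{int((~has_b).sum())} clones lack CDR3beta; avidity set to unknown",
            stacklevel=2,
        )
    out["avidity_call"] = calls
    return out


# ---------------------------------------------------------------------------
# distances and clustering


def _chain_vector(seq, mask, table):
    if seq is None or (isinstance(seq, float) and np.isnan(seq)) or seq == "":
        return None
    return featurize_cdr3(seq, mask=mask, table=table)


def tcr_distance(
    tcr_a,
    tcr_b,
    table: pd.DataFrame | None = None,
    weights: tuple[float, float] = (1.0, 1.0),
    mask: tuple[int, int] = DEFAULT_MASK,
) -> float:
    """Physicochemical distance between two TCRs.

    Each TCR is a ``(cdr3a, cdr3b)`` pair (cdr3a may be None/empty). The
    distance is the chain-weighted root-mean of per-chain Euclidean distances
    between descriptor vectors; if either alpha chain is missing, the beta
    chain alone is used with weight renormalization.
    """
    a1, b1 = tcr_a
    a2, b2 = tcr_b
    v_b1, v_b2 = _chain_vector(b1, mask, table), _chain_vector(b2, mask, table)
    if v_b1 is None or v_b2 is None:
        raise ValueError("both TCRs must carry a CDR3beta")
    w_a, w_b = weights
    d2, wsum = w_b * float(np.sum((v_b1 - v_b2) ** 2)), w_b
    v_a1, v_a2 = _chain_vector(a1, mask, table), _chain_vector(a2, mask, table)
    if v_a1 is not None and v_a2 is not None and w_a > 0:
        d2 += w_a * float(np.sum((v_a1 - v_a2) ** 2))
        wsum += w_a
    return float(np.sqrt(d2 / wsum))


def distance_matrix(
    ct: pd.DataFrame,
    table: pd.DataFrame | None = None,
    weights: tuple[float, float] = (1.0, 1.0),
    mask: tuple[int, int] = DEFAULT_MASK,
) -> pd.DataFrame:
    """Symmetric zero-diagonal TCR distance matrix over clonotype rows."""
    if len(ct) < 2:
        raise ValueError("need at least 2 clones")
    pairs = list(zip(ct["cdr3a"] if "cdr3a" in ct else [None] * len(ct), ct["cdr3b"]))
    n = len(pairs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tcr_distance(
                pairs[i], pairs[j], table=table, weights=weights, mask=mask
            )
    return pd.DataFrame(d, index=ct["clone_id"].to_numpy(), columns=ct["clone_id"].to_numpy())


@dataclasses.dataclass
class Dendrogram:
    """UPGMA merge tree: scipy linkage matrix plus leaf identifiers."""

    linkage: np.ndarray  # (n-1, 4) scipy format
    leaf_ids: list

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        from skbio import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, [str(i) for i in self.leaf_ids])
        return str(tree).strip()


def upgma(dist: pd.DataFrame | np.ndarray) -> Dendrogram:
    """Average-linkage (UPGMA) hierarchical clustering of a distance matrix."""
    if isinstance(dist, pd.DataFrame):
        leaf_ids = list(dist.index)
        d = dist.to_numpy(dtype=float)
    else:
        d = np.asarray(dist, dtype=float)
        leaf_ids = list(range(d.shape[0]))
    if not np.isfinite(d).all():
        raise ValueError("distance matrix contains non-finite values")
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
        raise ValueError("need a symmetric zero-diagonal distance matrix")
    Z = sch.linkage(ssd.squareform(d, checks=False), method="average")
    return Dendrogram(linkage=Z, leaf_ids=leaf_ids)


def cut_clusters(dendro: Dendrogram, k: int) -> pd.Series:
    """Cut into exactly ``k`` clusters by dropping the ``k-1`` highest merges.

    Ties in merge height are broken by merge order (later merges dropped
    first), so the cut is deterministic and always yields exactly ``k``
    clusters, even on degenerate all-equal distance matrices. Cluster labels
    are 0..k-1 in order of first appearance over the leaves.
    """
    n = dendro.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k must lie in [1, {n}]")
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # linkage rows are sorted by height; keep the first n-k merges
    roots = {}
    next_node = n
    comp = {i: i for i in range(n)}  # scipy node id -> union-find root
    for row in dendro.linkage[: n - k]:
        a, b = int(row[0]), int(row[1])
        ra, rb = find(comp[a]), find(comp[b])
        parent[rb] = ra
        comp[next_node] = ra
        next_node += 1
    labels, seen = [], {}
    for i in range(n):
        r = find(i)
        if r not in seen:
            seen[r] = len(seen)
        labels.append(seen[r])
    return pd.Series(labels, index=dendro.leaf_ids, name="cluster")
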