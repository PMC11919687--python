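"""Immune repertoire summary metrics.

Richness is the number of unique clones with positive abundance; clonality
is 1 minus Pielou's evenness, ``1 - H/ln(S)`` with H the natural-log Shannon
entropy of the normalized clone frequencies. A single-clone repertoire is
maximally clonal (clonality 1) by convention.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "richness",
    "clonality",
    "cumulative_frequency",
    "repertoire_metrics_table",
]


def _as_abundance(rep) -> pd.Series:
    s = pd.Series(rep, dtype=float) if not isinstance(rep, pd.Series) else rep.astype(float)
    if len(s) == 0:
        raise ValueError("empty repertoire")
    if (s < 0).any():
        raise ValueError("abundances must be non-negative")
    s = s[s > 0]
    if len(s) == 0:
        raise ValueError("repertoire has no positive abundance")
    return s


def richness(rep) -> int:
    """Number of unique clones present (abundance > 0)."""
    return int(len(_as_abundance(rep)))


def clonality(rep) -> float:
    """1 - Pielou's evenness = 1 - H/ln(S), in [0, 1].

    0 for a perfectly even repertoire; 1 when dominated by a single clone
    (S = 1 returns 1 by convention).
    """
    ab = _as_abundance(rep)
    s = len(ab)
    if s == 1:
        return 1.0
    p = (ab / ab.sum()).to_numpy()
    h = -np.sum(p * np.log(p))
    return float(1.0 - h / np.log(s))


def cumulative_frequency(rep, clones) -> float:
    """Summed normalized frequency of a clone subset (missing ids -> 0)."""
    ab = _as_abundance(rep)
    freq = ab / ab.sum()
    clones = list(clones)
    missing = [c for c in clones if c not in freq.index]
    if missing:
        warnings.warn(f"{len(missing)} clones absent from the repertoire", stacklevel=2)
    present = [c for c in clones if c in freq.index]
    return float(freq.loc[present].sum()) if present else 0.0


def repertoire_metrics_table(ct: pd.DataFrame, by=("patient",)) -> pd.DataFrame:
    """Richness and clonality per patient (or other grouping columns),
    using clone cell counts as abundances."""
    rows = []
    for keys, grp in ct.groupby(list(by)):
        keys = keys if isinstance(keys, tuple) else (keys,)
        ab = pd.Series(grp["n_cells"].to_numpy(), index=grp["clone_id"].to_numpy())
        rows.append(dict(zip(by, keys)) | {
            "richness": richness(ab),
            "clonality": clonality(ab),
        })
    return pd.DataFrame(rows)
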