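"""Synthetic multi-patient cohorts with planted tumor-reactivity structure.

The generator emulates the statistical structure the predictor assumes:
patients carrying clonally expanded T cells, negative-binomial UMI counts
with gene-specific log-normal baselines, a planted up/down differential
signature separating tumor-reactive from bystander clones (applied to every
cell of a clone, mirroring clone-wise annotation), and CDR3 amino-acid
sequences organized into mutational families with a learnable structural
avidity rule.

The negative binomial is parameterized by mean mu and dispersion phi with
Var = mu + phi*mu^2.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import AMINO_ACIDS, CellMatrix, validate_clone_table
from .tcr import featurize_cdr3

__all__ = ["SimConfig", "simulate_cohort", "simulate_cdr3_families", "permute_labels"]


@dataclasses.dataclass
class SimConfig:
    """Cohort-generator settings; defaults define the reference conditions.

    ``effect_size`` is a natural-log mean shift: up-signal genes have their
    negative-binomial mean multiplied by exp(effect_size) in cells of reactive
    clones, down-signal genes by exp(-effect_size).
    """

    n_patients: int = 10
    clones_per_patient: int = 40
    cells_per_clone_mean: float = 4.0  # geometric distribution mean (>=1)
    n_genes: int = 1000
    n_signal_genes_up: int = 50
    n_signal_genes_down: int = 25
    effect_size: float = 1.0
    nb_dispersion: float = 0.3
    frac_reactive: float = 0.5
    cdr3_cluster_count: int = 5
    cdr3_mutations_per_member: int = 2
    avidity_noise: float = 0.05  # label-flip probability on the planted rule
    baseline_log_mean: float = np.log(0.2)
    baseline_log_sd: float = 1.2
    seed: int = 0

    def validate(self) -> "SimConfig":
        if min(self.n_patients, self.clones_per_patient, self.n_genes) < 1:
            raise ValueError("counts must be positive")
        if not (0.0 < self.frac_reactive < 1.0):
            raise ValueError("frac_reactive must lie strictly inside (0, 1)")
        if self.cells_per_clone_mean < 1:
            raise ValueError("cells_per_clone_mean must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        n_reactive = int(round(self.clones_per_patient * self.frac_reactive))
        if n_reactive == 0 or n_reactive == self.clones_per_patient:
            raise ValueError(
                "frac_reactive rounds to an all-one-class patient; "
                "adjust clones_per_patient or frac_reactive"
            )
        if self.n_signal_genes_up + self.n_signal_genes_down > self.n_genes:
            raise ValueError("more signal genes than genes")
        return self


def simulate_cohort(cfg: SimConfig):
    """Generate a cohort.

    Returns
    -------
    cm : CellMatrix
        Counts only (call :func:`trtkit.io.normalize_log` for the layer).
    ct : pandas.DataFrame
        Clonotype table with ground-truth ``label`` and ``avidity_call``.
    truth : dict
        Planted structure: up/down signal genes, CDR3 family labels, the
        avidity rule threshold.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    base_mu = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes))
    sig_idx = rng.choice(
        cfg.n_genes, cfg.n_signal_genes_up + cfg.n_signal_genes_down, replace=False
    )
    up_idx = sig_idx[: cfg.n_signal_genes_up]
    down_idx = sig_idx[cfg.n_signal_genes_up :]

    n_reactive = int(round(cfg.clones_per_patient * cfg.frac_reactive))
    n_families = cfg.cdr3_cluster_count

    rows = []
    barcodes, patients_of_cell, clones_of_cell = [], [], []
    reactive_cells = []
    k_total = cfg.n_patients * cfg.clones_per_patient
    cdr3b_all, fam_all = simulate_cdr3_families(
        n_families,
        int(np.ceil(k_total / n_families)),
        cfg.cdr3_mutations_per_member,
        seed=int(rng.integers(2**31 - 1)),
    )
    cdr3a_all, _ = simulate_cdr3_families(
        n_families,
        int(np.ceil(k_total / n_families)),
        cfg.cdr3_mutations_per_member,
        seed=int(rng.integers(2**31 - 1)),
    )

    ci = 0
    for p in range(cfg.n_patients):
        patient = f"P{p + 1:02d}"
        labels = np.array(
            ["tumor_reactive"] * n_reactive
            + ["non_tumor_reactive"] * (cfg.clones_per_patient - n_reactive)
        )
        rng.shuffle(labels)
        # geometric on {1, 2, ...} with mean m  ->  p = 1/m
        sizes = rng.geometric(1.0 / cfg.cells_per_clone_mean, cfg.clones_per_patient)
        for j in range(cfg.clones_per_patient):
            clone_id = f"{patient}_C{j + 1:03d}"
            n_cells = int(sizes[j])
            for c in range(n_cells):
                barcodes.append(f"{clone_id}_cell{c + 1}")
                patients_of_cell.append(patient)
                clones_of_cell.append(clone_id)
                reactive_cells.append(labels[j] == "tumor_reactive")
            rows.append(
                {
                    "clone_id": clone_id,
                    "patient": patient,
                    "cdr3a": cdr3a_all[ci],
                    "cdr3b": cdr3b_all[ci],
                    "n_cells": n_cells,
                    "label": labels[j],
                    "family": int(fam_all[ci]),
                }
            )
            ci += 1

    n_cells_total = len(barcodes)
    reactive_cells = np.asarray(reactive_cells)

    mu = np.tile(base_mu[:, None], (1, n_cells_total))
    mu[np.ix_(up_idx, np.flatnonzero(reactive_cells))] *= np.exp(cfg.effect_size)
    mu[np.ix_(down_idx, np.flatnonzero(reactive_cells))] *= np.exp(-cfg.effect_size)

    # NB(mean mu, dispersion phi): shape r = 1/phi, p = r/(r+mu)
    r = 1.0 / cfg.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    cm = CellMatrix(
        gene_ids=genes,
        cell_barcodes=barcodes,
        counts=sp.csr_matrix(counts),
        cell_meta=pd.DataFrame(
            {"patient": patients_of_cell, "clone_id": clones_of_cell},
            index=pd.Index(barcodes, name="barcode"),
        ),
    )

    ct = pd.DataFrame(rows)
    # planted avidity rule: first-factor mean of the masked CDR3b residues
    feats = np.array([featurize_cdr3(s)[0] for s in ct["cdr3b"]])
    thresh = float(np.median(feats))
    high = feats >= thresh
    flip = rng.random(len(ct)) < cfg.avidity_noise
    ct["avidity_call"] = np.where(high ^ flip, "high", "low")
    totals = ct.groupby("patient")["n_cells"].transform("sum")
    ct["frequency"] = ct["n_cells"] / totals
    truth = {
        "up_genes": [genes[i] for i in up_idx],
        "down_genes": [genes[i] for i in down_idx],
        "families": {r["clone_id"]: r["family"] for r in rows},
        "avidity_threshold": thresh,
        "avidity_high": {c: bool(h) for c, h in zip(ct["clone_id"], high)},
    }
    ct = ct.drop(columns=["family"])
    validate_clone_table(ct, cm)
    return cm, ct, truth


def simulate_cdr3_families(
    k: int, members_per_family: int, mutations: int, seed: int = 0
):
    """CDR3 beta-like sequences in ``k`` mutational families.

    Each family derives from one random ancestor (length 10-18, canonical
    20-letter alphabet) by at most ``mutations`` point substitutions per
    member. Returns ``(sequences, family_labels)``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    seqs, fams = [], []
    for f in range(k):
        length = int(rng.integers(10, 19))
        ancestor = rng.choice(aa, size=length)
        for _ in range(members_per_family):
            member = ancestor.copy()
            n_mut = int(rng.integers(0, mutations + 1)) if mutations else 0
            if n_mut:
                pos = rng.choice(length, size=min(n_mut, length), replace=False)
                member[pos] = rng.choice(aa, size=len(pos))
            seqs.append("".join(member))
            fams.append(f)
    return seqs, np.asarray(fams)


def permute_labels(ct: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Uniformly permute the clone-level label column (multiset preserved)."""
    if "label" not in ct.columns:
        raise ValueError("clone table has no label column")
    rng = np.random.default_rng(seed)
    out = ct.copy()
    labels = out["label"].to_numpy().copy()
    rng.shuffle(labels)
    out["label"] = labels
    return out


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)
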