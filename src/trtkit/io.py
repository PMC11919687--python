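"""Core data model and on-disk formats.

The package works on two linked containers: a :class:`CellMatrix` holding the
genes x cells UMI count matrix (10x-convention MatrixMarket triplet) together
with a log10-normalized layer and per-cell patient/clone annotations, and a
clonotype table (a validated :class:`pandas.DataFrame`) with one row per
(clone_id, patient) pair carrying CDR3 sequences, sizes, tumor-reactivity
labels, scores and avidity calls.

Matrix orientation is genes x cells everywhere; normalization is
``log10(1 + scale * count / colsum)`` with ``scale`` defaulting to the 10x
community convention of 10,000.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CellMatrix",
    "Signature",
    "FormatError",
    "AMINO_ACIDS",
    "CLONE_TABLE_COLUMNS",
    "LABELS",
    "load_expression",
    "normalize_log",
    "pseudobulk_by_clone",
    "read_clone_table",
    "write_clone_table",
    "validate_clone_table",
    "read_signature",
    "write_signature",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

LABELS = ("tumor_reactive", "non_tumor_reactive", "unknown")
AVIDITY_LEVELS = ("high", "low", "unknown")

#: mandatory columns of the clonotype CSV
CLONE_TABLE_COLUMNS = [
    "clone_id",
    "patient",
    "cdr3a",
    "cdr3b",
    "n_cells",
    "label",
    "avidity_call",
    "frequency",
]

#: optional columns written/read when present
CLONE_TABLE_OPTIONAL = ["trt_score", "trt_call"]


class FormatError(ValueError):
    """Raised when an on-disk file violates the expected format."""


@dataclasses.dataclass
class CellMatrix:
    """Genes x cells expression container.

    Attributes
    ----------
    gene_ids : list of str
        Gene symbols, one per matrix row.
    cell_barcodes : list of str
        Unique cell barcodes, one per matrix column.
    counts : scipy.sparse.csr_matrix
        Non-negative integer UMI counts, genes x cells.
    lognorm : numpy.ndarray or None
        log10-normalized counts (same shape, dense); absent until
        :func:`normalize_log` is called.
    cell_meta : pandas.DataFrame
        Indexed by barcode with columns ``patient`` and ``clone_id``
        (``clone_id`` may be NA for cells without TCR information).
    """

    gene_ids: list
    cell_barcodes: list
    counts: sp.spmatrix
    lognorm: np.ndarray | None = None
    cell_meta: pd.DataFrame | None = None

    def __post_init__(self):
        if len(set(self.cell_barcodes)) != len(self.cell_barcodes):
            raise FormatError("duplicate cell barcodes")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_barcodes)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_barcodes)} cells"
            )
        if self.counts.nnz and self.counts.min() < 0:
            raise FormatError("negative counts")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(
                {"patient": pd.NA, "clone_id": pd.NA},
                index=pd.Index(self.cell_barcodes, name="barcode"),
            )
        else:
            self.cell_meta = self.cell_meta.reindex(self.cell_barcodes)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_barcodes)

    def subset_cells(self, mask: np.ndarray) -> "CellMatrix":
        """Column subset (boolean mask or integer indices); copies layers."""
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CellMatrix(
            gene_ids=list(self.gene_ids),
            cell_barcodes=[self.cell_barcodes[i] for i in idx],
            counts=self.counts[:, idx],
            lognorm=None if self.lognorm is None else self.lognorm[:, idx],
            cell_meta=self.cell_meta.iloc[idx],
        )

    def subset_patients(self, patients: Iterable[str]) -> "CellMatrix":
        keep = set(patients)
        mask = self.cell_meta["patient"].isin(keep).to_numpy()
        return self.subset_cells(mask)


@dataclasses.dataclass
class Signature:
    """Ordered up/down gene lists with the DE statistics that produced them."""

    up: list
    down: list
    stats: pd.DataFrame | None = None  # index gene, columns logFC, padj
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if set(self.up) & set(self.down):
            raise ValueError("up and down gene sets overlap")

    @property
    def genes(self) -> list:
        return list(self.up) + list(self.down)

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


# ---------------------------------------------------------------------------
# expression I/O


def load_expression(matrix_path, genes_path, barcodes_path) -> CellMatrix:
    """Read a 10x-convention MTX triplet into a :class:`CellMatrix`.

    The matrix file is MatrixMarket coordinate format, genes x cells; the
    genes/barcodes files are one-entry-per-line TSV.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # pragma: no cover - scipy message passthrough
        raise FormatError(f"cannot read matrix {matrix_path}: {exc}") from exc
    genes = _read_column(genes_path)
    barcodes = _read_column(barcodes_path)
    mat = sp.csr_matrix(mat)
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix is {mat.shape} but files define "
            f"{len(genes)} genes and {len(barcodes)} barcodes"
        )
    if mat.nnz and (np.any(mat.data < 0) or np.any(mat.data != np.round(mat.data))):
        raise FormatError("counts must be non-negative integers")
    return CellMatrix(gene_ids=genes, cell_barcodes=barcodes, counts=mat)


def write_expression(cm: CellMatrix, matrix_path, genes_path, barcodes_path) -> None:
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(cm.counts))
    Path(genes_path).write_text("\n".join(map(str, cm.gene_ids)) + "\n")
    Path(barcodes_path).write_text("\n".join(map(str, cm.cell_barcodes)) + "\n")


def _read_column(path) -> list:
    lines = [ln.split("\t")[0].strip() for ln in Path(path).read_text().splitlines()]
    return [ln for ln in lines if ln]


def normalize_log(cm: CellMatrix, scale: float = 10_000.0) -> CellMatrix:
    """Depth-normalize and log-transform: ``log10(1 + scale*c/colsum)``.

    Cells with zero total count stay all-zero. Returns a new object sharing
    the count matrix.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    colsum = np.asarray(cm.counts.sum(axis=0)).ravel()
    denom = np.where(colsum > 0, colsum, 1.0)
    dense = np.asarray(cm.counts.todense(), dtype=float)
    lognorm = np.log10(1.0 + scale * dense / denom)
    return CellMatrix(
        gene_ids=list(cm.gene_ids),
        cell_barcodes=list(cm.cell_barcodes),
        counts=cm.counts,
        lognorm=lognorm,
        cell_meta=cm.cell_meta,
    )


def pseudobulk_by_clone(cm: CellMatrix, ct: pd.DataFrame) -> pd.DataFrame:
    """Clone-average log-normalized profiles, genes x clones.

    Column ``j`` is the arithmetic mean of the lognorm layer over the cells of
    clone ``j``; column order follows the clonotype table.
    """
    if cm.lognorm is None:
        raise ValueError("lognorm layer absent; call normalize_log first")
    clones = ct["clone_id"].to_numpy()
    codes = pd.Categorical(
        cm.cell_meta["clone_id"], categories=clones
    ).codes  # -1 for cells outside the table
    keep = np.flatnonzero(codes >= 0)
    sizes = np.bincount(codes[keep], minlength=len(clones)).astype(float)
    if (sizes == 0).any():
        missing = [c for c, s in zip(clones, sizes) if s == 0]
        raise ValueError(f"clones with no matched cells: {missing}")
    indicator = sp.csr_matrix(
        (np.ones(keep.size), (keep, codes[keep])),
        shape=(cm.n_cells, len(clones)),
    )
    profiles = (cm.lognorm @ indicator.toarray()) / sizes
    return pd.DataFrame(profiles, index=cm.gene_ids, columns=clones)


# ---------------------------------------------------------------------------
# clonotype table I/O


def validate_clone_table(ct: pd.DataFrame, cm: CellMatrix | None = None) -> pd.DataFrame:
    missing = [c for c in CLONE_TABLE_COLUMNS if c not in ct.columns]
    if missing:
        raise FormatError(f"clone table missing mandatory columns: {missing}")
    if ct.duplicated(subset=["clone_id", "patient"]).any():
        raise FormatError("(clone_id, patient) pairs must be unique")
    for col in ("cdr3a", "cdr3b"):
        for i, seq in ct[col].items():
            if seq is None or (isinstance(seq, float) and np.isnan(seq)) or seq == "":
                continue
            bad = set(str(seq)) - set(AMINO_ACIDS)
            if bad:
                raise FormatError(
                    f"row {i}: {col} contains non-amino-acid characters {sorted(bad)}"
                )
    bad_labels = set(ct["label"].dropna()) - set(LABELS)
    if bad_labels:
        raise FormatError(f"unknown labels: {sorted(bad_labels)}")
    bad_av = set(ct["avidity_call"].dropna()) - set(AVIDITY_LEVELS)
    if bad_av:
        raise FormatError(f"unknown avidity levels: {sorted(bad_av)}")
    if (ct["n_cells"].fillna(0) <= 0).any():
        raise FormatError("n_cells must be positive")
    freq = ct["frequency"].dropna()
    if len(freq) and ((freq < 0).any() or (freq > 1).any()):
        raise FormatError("frequencies must lie in [0, 1]")
    for patient, grp in ct.groupby("patient"):
        s = grp["frequency"].dropna().sum()
        if s > 1 + 1e-9:
            raise FormatError(f"frequencies for patient {patient} sum to {s} > 1")
    if cm is not None:
        counts = cm.cell_meta["clone_id"].value_counts()
        for _, row in ct.iterrows():
            n = int(counts.get(row["clone_id"], 0))
            if n != int(row["n_cells"]):
                raise FormatError(
                    f"clone {row['clone_id']}: n_cells={row['n_cells']} but "
                    f"matrix carries {n} cells"
                )
    return ct


def write_clone_table(ct: pd.DataFrame, path) -> None:
    """CSV writer; absent values serialized as empty strings."""
    cols = CLONE_TABLE_COLUMNS + [c for c in CLONE_TABLE_OPTIONAL if c in ct.columns]
    out = ct[cols].copy()
    out.to_csv(path, index=False, na_rep="")


def read_clone_table(path) -> pd.DataFrame:
    ct = pd.read_csv(
        path,
        dtype={"clone_id": str, "patient": str, "cdr3a": str, "cdr3b": str},
        keep_default_na=True,
    )
    missing = [c for c in CLONE_TABLE_COLUMNS if c not in ct.columns]
    if missing:
        raise FormatError(f"clone table missing mandatory columns: {missing}")
    if "trt_call" in ct.columns:
        ct["trt_call"] = ct["trt_call"].map(
            lambda v: v if pd.isna(v) else bool(v) if isinstance(v, (bool, np.bool_)) else str(v) == "True"
        )
    ct["n_cells"] = ct["n_cells"].astype(int)
    return validate_clone_table(ct)


# ---------------------------------------------------------------------------
# signature I/O (TSV: gene, direction, logFC, adj_p, rank)


def write_signature(sig: Signature, path) -> None:
    rows = []
    for rank, gene in enumerate(sig.up, start=1):
        rows.append((gene, "up", rank))
    for rank, gene in enumerate(sig.down, start=1):
        rows.append((gene, "down", rank))
    df = pd.DataFrame(rows, columns=["gene", "direction", "rank"])
    if sig.stats is not None:
        df["logFC"] = df["gene"].map(sig.stats["logFC"]).to_numpy()
        df["adj_p"] = df["gene"].map(sig.stats["padj"]).to_numpy()
    else:
        df["logFC"] = np.nan
        df["adj_p"] = np.nan
    df[["gene", "direction", "logFC", "adj_p", "rank"]].to_csv(path, sep="\t", index=False)


def read_signature(path) -> Signature:
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "direction", "rank"):
        if col not in df.columns:
            raise FormatError(f"signature file missing column {col}")
    up = df[df["direction"] == "up"].sort_values("rank")["gene"].tolist()
    down = df[df["direction"] == "down"].sort_values("rank")["gene"].tolist()
    stats = df.set_index("gene")[["logFC", "adj_p"]].rename(columns={"adj_p": "padj"})
    return Signature(up=up, down=down, stats=stats)
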