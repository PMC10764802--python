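"""In-memory expression-data model and plain-text I/O.

The pipeline's working container is :class:`ExpressionMatrix`: a sparse
cells x genes matrix plus cell/gene identifiers and a per-cell metadata
table (cell-type label, batch).  On disk the package speaks the Matrix
Market + genes.tsv + barcodes.tsv dialect used by CellRanger-style
exports, and flat TSV for metadata, predictions and embeddings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

MISSING_LABEL = "__missing__"
"""Sentinel for cells without a label/batch; never a real cell-type name."""


class TransformState(str, Enum):
    RAW_COUNTS = "raw_counts"
    NORMALIZED_LOG = "normalized_log"


@dataclass
class ExpressionMatrix:
    """Sparse cells x genes expression matrix with aligned metadata.

    Attributes
    ----------
    values
        ``scipy.sparse.csr_matrix`` of shape ``(n_cells, n_genes)``.
        Non-negative integers while ``transform_state`` is raw counts,
        real-valued after log-normalization.
    cell_ids, gene_ids
        Unique string identifiers for rows and columns.
    cell_meta
        DataFrame indexed by ``cell_id`` with optional ``label`` and
        ``batch`` columns; missing entries carry :data:`MISSING_LABEL`.
    """

    values: sp.csr_matrix
    cell_ids: list[str]
    gene_ids: list[str]
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    transform_state: TransformState = TransformState.RAW_COUNTS

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids are not unique")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids are not unique")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(
                {"label": MISSING_LABEL, "batch": MISSING_LABEL},
                index=pd.Index(self.cell_ids, name="cell_id"),
            )
        if self.transform_state == TransformState.RAW_COUNTS:
            data = self.values.data
            if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
                raise ValueError("raw count matrix has negative or non-integer entries")

    # -- convenience -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def labels(self) -> np.ndarray:
        return self.cell_meta.loc[self.cell_ids, "label"].to_numpy()

    @property
    def batches(self) -> np.ndarray:
        return self.cell_meta.loc[self.cell_ids, "batch"].to_numpy()

    def subset_cells(self, mask_or_ids) -> "ExpressionMatrix":
        """Row-subset by boolean mask or list of cell ids (order kept)."""
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            pos = {c: i for i, c in enumerate(self.cell_ids)}
            idx = np.array([pos[c] for c in mask_or_ids], dtype=int)
        cells = [self.cell_ids[i] for i in idx]
        return replace(
            self,
            values=self.values[idx],
            cell_ids=cells,
            cell_meta=self.cell_meta.loc[cells],
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Column-subset/reorder to ``gene_ids`` (all must be present)."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = np.array([pos[g] for g in gene_ids], dtype=int)
        return replace(self, values=self.values[:, idx].tocsr(), gene_ids=list(gene_ids))

    def to_anndata(self):
        """Optional AnnData view for interop with the scanpy ecosystem."""
        import anndata

        return anndata.AnnData(
            X=self.values.copy(),
            obs=self.cell_meta.loc[self.cell_ids].copy(),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )


@dataclass(frozen=True)
class LabelVocabulary:
    """Ordered, bijective mapping between cell-type names and 0..T-1."""

    types: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.types) < 1:
            raise ValueError("vocabulary needs at least one type")
        if len(set(self.types)) != len(self.types):
            raise ValueError("duplicate types in vocabulary")

    @classmethod
    def from_labels(cls, labels: Sequence[str]) -> "LabelVocabulary":
        present = sorted({str(l) for l in labels if str(l) != MISSING_LABEL})
        return cls(tuple(present))

    @property
    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.types)}

    def encode(self, labels: Sequence[str]) -> np.ndarray:
        idx = self.index
        try:
            return np.array([idx[str(l)] for l in labels], dtype=int)
        except KeyError as e:  # pragma: no cover - message path
            raise KeyError(f"label {e} not in vocabulary") from e

    def __len__(self) -> int:
        return len(self.types)


class SplitScheme(str, Enum):
    STRATIFIED_RANDOM = "stratified_random"
    BATCH = "batch"
    UNSEEN_TYPE = "unseen_type"


@dataclass
class SplitAssignment:
    """Role (train/validation/test) per cell id for one experiment split."""

    roles: dict[str, str]  # cell_id -> {"train","validation","test"}
    seed: int
    scheme: SplitScheme

    def ids_for(self, role: str) -> list[str]:
        return [c for c, r in self.roles.items() if r == role]

    def counts(self) -> dict[str, int]:
        out = {"train": 0, "validation": 0, "test": 0}
        for r in self.roles.values():
            out[r] += 1
        return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_id_column(path) -> list[str]:
    # CellRanger genes.tsv has two columns; only the first is the id.
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def read_matrix_market(
    matrix_path,
    genes_path,
    barcodes_path,
    orientation: str = "genes_x_cells",
    transform_state: TransformState = TransformState.RAW_COUNTS,
) -> ExpressionMatrix:
    """Read an MTX triplet into the internal cells x genes orientation.

    ``orientation`` describes the on-disk matrix: ``genes_x_cells`` (the
    CellRanger convention, transposed on load) or ``cells_x_genes``.
    Raw counts (the default ``transform_state``) must be non-negative
    integers; pass ``TransformState.NORMALIZED_LOG`` to read an
    already-normalized real-valued matrix.
    """
    if orientation not in ("genes_x_cells", "cells_x_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    mat = sp.coo_matrix(scipy.io.mmread(matrix_path))
    genes = _read_id_column(genes_path)
    cells = _read_id_column(barcodes_path)
    if orientation == "genes_x_cells":
        exp_shape = (len(genes), len(cells))
    else:
        exp_shape = (len(cells), len(genes))
    if mat.shape != exp_shape:
        raise ValueError(
            f"matrix header is {mat.shape[0]} x {mat.shape[1]} but id files give "
            f"{len(genes)} genes and {len(cells)} barcodes (expected {exp_shape})"
        )
    transform_state = TransformState(transform_state)
    if transform_state == TransformState.RAW_COUNTS and mat.data.size and (
        np.any(mat.data < 0) or np.any(mat.data != np.round(mat.data))
    ):
        raise ValueError("count matrix has negative or non-integer entries")
    if orientation == "genes_x_cells":
        mat = mat.T
    return ExpressionMatrix(
        values=mat.tocsr(), cell_ids=cells, gene_ids=genes, transform_state=transform_state
    )


def write_matrix_market(matrix: ExpressionMatrix, out_dir, orientation: str = "genes_x_cells") -> None:
    """Write matrix.mtx + genes.tsv + barcodes.tsv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vals = matrix.values.T if orientation == "genes_x_cells" else matrix.values
    scipy.io.mmwrite(str(out / "matrix.mtx"), sp.coo_matrix(vals))
    (out / "genes.tsv").write_text("".join(f"{g}\t{g}\n" for g in matrix.gene_ids))
    (out / "barcodes.tsv").write_text("".join(f"{c}\n" for c in matrix.cell_ids))


def attach_metadata(matrix: ExpressionMatrix, meta_path) -> ExpressionMatrix:
    """Populate ``cell_meta`` from a TSV with columns cell_id[, label, batch].

    Cells absent from the table keep the missing marker; metadata rows for
    unknown cells trigger a warning with their count.  Duplicate cell ids in
    the table are an error.
    """
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if "cell_id" not in meta.columns:
        raise ValueError("metadata TSV must have a 'cell_id' column")
    if meta["cell_id"].duplicated().any():
        dups = meta.loc[meta["cell_id"].duplicated(), "cell_id"].tolist()
        raise ValueError(f"duplicate cell_id rows in metadata: {dups[:5]}")
    known = set(matrix.cell_ids)
    unknown = [c for c in meta["cell_id"] if c not in known]
    if unknown:
        warnings.warn(
            f"{len(unknown)} metadata rows reference cells absent from the matrix",
            stacklevel=2,
        )
    meta = meta.set_index("cell_id")
    new_meta = pd.DataFrame(
        {"label": MISSING_LABEL, "batch": MISSING_LABEL},
        index=pd.Index(matrix.cell_ids, name="cell_id"),
    )
    for col in ("label", "batch"):
        if col in meta.columns:
            shared = meta.index.intersection(new_meta.index)
            vals = meta.loc[shared, col]
            vals = vals.where(vals.notna() & (vals != ""), MISSING_LABEL)
            new_meta.loc[shared, col] = vals
    return replace(matrix, cell_meta=new_meta)


def write_metadata(matrix: ExpressionMatrix, path) -> None:
    df = matrix.cell_meta.loc[matrix.cell_ids].reset_index()
    df.to_csv(path, sep="\t", index=False)


def write_predictions(predictions, path) -> None:
    """Write a predictions TSV (cell_id, predicted_label, vote_fraction)."""
    n = len(predictions.cell_ids)
    if not (len(predictions.labels) == len(predictions.vote_fractions) == n):
        raise ValueError("prediction field lengths do not match")
    df = pd.DataFrame(
        {
            "cell_id": predictions.cell_ids,
            "predicted_label": predictions.labels,
            "vote_fraction": predictions.vote_fractions,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_embeddings(cell_ids: Sequence[str], Z: np.ndarray, path) -> None:
    """Write embeddings TSV (cell_id, e1..e_d') at full float precision."""
    Z = np.asarray(Z)
    if len(cell_ids) != Z.shape[0]:
        raise ValueError(f"{len(cell_ids)} cell ids but {Z.shape[0]} embedding rows")
    cols = [f"e{i + 1}" for i in range(Z.shape[1])]
    df = pd.DataFrame(Z, columns=cols)
    df.insert(0, "cell_id", list(cell_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_embeddings(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    ids = df["cell_id"].tolist()
    Z = df.drop(columns="cell_id").to_numpy(dtype=float)
    return ids, Z
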