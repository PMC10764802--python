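"""Quality control, HVG selection, normalization, and experiment splits.

The preprocessing recipe: (1) remove cells with a high mitochondrial
count fraction, cells expressing too few genes, and genes detected in
too few cells; (2) rank genes by the variance of their analytic Pearson
residuals under a gamma-Poisson null and keep the top ``n_top``;
(3) scale each cell to a fixed total count and apply log(x+1).

Three split schemes cover the standard annotation protocols:
stratified random 8:1:1, batch-held-out (9:1 train:validation within
the training batches), and unseen-type (a label deleted from train and
validation but kept in test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp

from .core_data import (
    MISSING_LABEL,
    ExpressionMatrix,
    SplitAssignment,
    SplitScheme,
    TransformState,
)

__all__ = [
    "QCConfig",
    "QCReport",
    "HVGResult",
    "qc_filter",
    "select_hvgs",
    "normalize_log",
    "stratified_split",
    "batch_split",
    "remove_types",
]


@dataclass
class QCConfig:
    """Cell/gene filtering thresholds.

    ``max_mito_fraction``: cells whose mitochondrial counts exceed this
    fraction of their total are removed (mito genes are recognized by a
    case-insensitive gene-id prefix, "MT-" by default).
    ``min_genes_per_cell`` / ``min_cells_per_gene`` use strict "<"
    comparisons: a cell expressing exactly ``min_genes_per_cell`` genes
    is kept.
    """

    max_mito_fraction: float = 0.05
    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 3
    mito_gene_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_mito_fraction <= 1.0):
            raise ValueError("max_mito_fraction must lie in [0, 1]")
        if self.min_genes_per_cell < 0 or self.min_cells_per_gene < 0:
            raise ValueError("QC thresholds must be non-negative")


@dataclass
class QCReport:
    n_cells_removed_mito: int = 0
    n_cells_removed_min_genes: int = 0
    n_genes_removed_min_cells: int = 0


@dataclass
class HVGResult:
    """Selected genes plus the per-gene residual variances behind the ranking."""

    gene_ids: list[str]
    residual_variance: np.ndarray  # aligned with the INPUT matrix's genes
    theta: float


def qc_filter(matrix: ExpressionMatrix, cfg: QCConfig | None = None) -> tuple[ExpressionMatrix, QCReport]:
    """Apply the three QC rules in order: mito fraction, min genes, min cells.

    The gene filter counts expressing cells after the two cell filters.
    Raises if any rule empties the matrix, naming the rule.
    """
    cfg = cfg or QCConfig()
    if matrix.transform_state != TransformState.RAW_COUNTS:
        raise ValueError("qc_filter expects raw counts")
    X = matrix.values
    report = QCReport()

    prefix = cfg.mito_gene_prefix.lower()
    mito_mask = np.array([g.lower().startswith(prefix) for g in matrix.gene_ids])
    totals = np.asarray(X.sum(axis=1)).ravel()
    if mito_mask.any():
        mito_counts = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.divide(mito_counts, totals, out=np.zeros_like(mito_counts, dtype=float), where=totals > 0)
        keep_cells = frac <= cfg.max_mito_fraction
    else:
        keep_cells = np.ones(matrix.n_cells, dtype=bool)
    report.n_cells_removed_mito = int((~keep_cells).sum())
    if not keep_cells.any():
        raise ValueError("mitochondrial-fraction filter removed every cell")
    matrix = matrix.subset_cells(keep_cells)

    genes_per_cell = (matrix.values > 0).sum(axis=1)
    genes_per_cell = np.asarray(genes_per_cell).ravel()
    keep_cells = genes_per_cell >= cfg.min_genes_per_cell
    report.n_cells_removed_min_genes = int((~keep_cells).sum())
    if not keep_cells.any():
        raise ValueError("min-genes-per-cell filter removed every cell")
    matrix = matrix.subset_cells(keep_cells)

    cells_per_gene = np.asarray((matrix.values > 0).sum(axis=0)).ravel()
    keep_genes = cells_per_gene >= cfg.min_cells_per_gene
    report.n_genes_removed_min_cells = int((~keep_genes).sum())
    if not keep_genes.any():
        raise ValueError("min-cells-per-gene filter removed every gene")
    matrix = matrix.subset_genes([g for g, k in zip(matrix.gene_ids, keep_genes) if k])
    return matrix, report


def pearson_residual_variance(matrix: ExpressionMatrix, theta: float = 100.0) -> np.ndarray:
    """Per-gene variance of clipped analytic Pearson residuals.

    For cell c (total n_c) and gene g (pooled fraction p_g), the null
    expectation is mu_cg = n_c * p_g and the residual

        r_cg = (x_cg - mu_cg) / sqrt(mu_cg + mu_cg^2 / theta),

    clipped to +/- sqrt(n_cells).  Genes with zero total have mu = 0
    everywhere and contribute residual 0 (variance 0).
    """
    if matrix.transform_state != TransformState.RAW_COUNTS:
        raise ValueError("Pearson residuals are defined on raw counts")
    X = matrix.values.astype(float)
    n_cells = matrix.n_cells
    cell_tot = np.asarray(X.sum(axis=1)).ravel()
    gene_tot = np.asarray(X.sum(axis=0)).ravel()
    grand = gene_tot.sum()
    if grand == 0:
        raise ValueError("all-zero matrix")
    p = gene_tot / grand

    clip = np.sqrt(n_cells)
    # densify in gene blocks: O(n_cells * block) memory, vectorized math
    Xc = X.tocsc()
    var = np.zeros(matrix.n_genes)
    block = 256
    for start in range(0, matrix.n_genes, block):
        sl = slice(start, min(start + block, matrix.n_genes))
        xd = Xc[:, sl].toarray()
        mu = np.outer(cell_tot, p[sl])
        denom = np.sqrt(mu + mu * mu / theta)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(mu > 0, (xd - mu) / denom, 0.0)
        np.clip(r, -clip, clip, out=r)
        var[sl] = r.var(axis=0)
    return var


def select_hvgs(matrix: ExpressionMatrix, n_top: int = 2000, theta: float = 100.0) -> HVGResult:
    """Rank genes by Pearson-residual variance; return the ``n_top`` largest.

    Ties and ranking are deterministic (stable sort on -variance, then
    gene order).  If ``n_top`` >= n_genes all genes are returned, still
    ordered by decreasing residual variance.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    var = pearson_residual_variance(matrix, theta=theta)
    order = np.lexsort((np.arange(matrix.n_genes), -var))
    chosen = order[: min(n_top, matrix.n_genes)]
    return HVGResult(
        gene_ids=[matrix.gene_ids[i] for i in chosen],
        residual_variance=var,
        theta=theta,
    )


def normalize_log(matrix: ExpressionMatrix, target_sum: float = 1e4) -> ExpressionMatrix:
    """Scale each cell to ``target_sum`` total counts, then log1p.

    Zeros stay zero (sparsity preserved).  A zero-total cell is an error:
    it should have been removed by QC.
    """
    if matrix.transform_state != TransformState.RAW_COUNTS:
        raise ValueError("normalize_log expects raw counts")
    X = matrix.values.astype(float).tocsr()
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        bad = [matrix.cell_ids[i] for i in np.flatnonzero(totals == 0)[:5]]
        raise ValueError(f"cells with zero total count (run QC first): {bad}")
    scale = target_sum / totals
    X = sp.diags(scale) @ X
    X.data = np.log1p(X.data)
    return replace(matrix, values=X.tocsr(), transform_state=TransformState.NORMALIZED_LOG)


# ---------------------------------------------------------------------------
# Split schemes
# ---------------------------------------------------------------------------

def _folds(ids: np.ndarray, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Seeded shuffle then contiguous slicing into ``n_folds`` folds."""
    perm = rng.permutation(ids)
    return np.array_split(perm, n_folds)


def stratified_split(labels: dict[str, str] | "np.ndarray", seed: int, cell_ids=None) -> SplitAssignment:
    """Per-label 10-fold partition: folds 1-8 train, 9 validation, 10 test.

    ``labels`` is either a mapping cell_id -> label or an array aligned
    with ``cell_ids``.  Deterministic given ``seed``.  Labels with fewer
    than 10 cells get a warning and best-effort allocation (empty folds
    simply contribute no cells to that role).
    """
    if cell_ids is not None:
        labels = dict(zip(cell_ids, labels))
    if any(str(v) == MISSING_LABEL for v in labels.values()):
        raise ValueError("stratified_split requires every cell to be labeled")
    rng = np.random.default_rng(seed)
    roles: dict[str, str] = {}
    by_label: dict[str, list[str]] = {}
    for c, l in labels.items():
        by_label.setdefault(str(l), []).append(c)
    for label in sorted(by_label):
        ids = np.array(by_label[label], dtype=object)
        if ids.size < 10:
            warnings.warn(f"label {label!r} has only {ids.size} cells; 8:1:1 split is best-effort")
        folds = _folds(ids, 10, rng)
        for i, fold in enumerate(folds):
            role = "train" if i < 8 else ("validation" if i == 8 else "test")
            for c in fold:
                roles[c] = role
    return SplitAssignment(roles=roles, seed=seed, scheme=SplitScheme.STRATIFIED_RANDOM)


def batch_split(
    batches: dict[str, str],
    labels: dict[str, str],
    train_batches,
    test_batches,
    seed: int,
) -> SplitAssignment:
    """Hold out whole batches as test; split the rest 9:1 train:validation.

    The 9:1 split is stratified by label within the training batches.
    ``train_batches`` and ``test_batches`` must be disjoint and together
    cover every batch present.
    """
    train_batches, test_batches = set(train_batches), set(test_batches)
    if train_batches & test_batches:
        raise ValueError("train and test batches overlap")
    present = {str(b) for b in batches.values()}
    missing = present - (train_batches | test_batches)
    if missing:
        raise ValueError(f"batches not assigned to either group: {sorted(missing)}")
    unknown = (train_batches | test_batches) - present
    if unknown:
        raise ValueError(f"unknown batch tags: {sorted(unknown)}")
    if not test_batches:
        raise ValueError("test_batches is empty")

    rng = np.random.default_rng(seed)
    roles: dict[str, str] = {}
    by_label: dict[str, list[str]] = {}
    for c, b in batches.items():
        if str(b) in test_batches:
            roles[c] = "test"
        else:
            by_label.setdefault(str(labels[c]), []).append(c)
    for label in sorted(by_label):
        ids = np.array(by_label[label], dtype=object)
        folds = _folds(ids, 10, rng)
        for i, fold in enumerate(folds):
            role = "train" if i < 9 else "validation"
            for c in fold:
                roles[c] = role
    return SplitAssignment(roles=roles, seed=seed, scheme=SplitScheme.BATCH)


def remove_types(
    matrix: ExpressionMatrix,
    split: SplitAssignment,
    types_to_remove,
) -> tuple[ExpressionMatrix, SplitAssignment]:
    """Drop the listed cell types from train and validation roles only.

    The test role is untouched, producing the unseen-type protocol.
    Types absent from the data are a warning, not an error.  Raises if
    the removal empties the training set.
    """
    types_to_remove = {str(t) for t in types_to_remove}
    present = set(map(str, matrix.labels))
    absent = types_to_remove - present
    if absent:
        warnings.warn(f"types not present in the data: {sorted(absent)}")
    label_of = dict(zip(matrix.cell_ids, map(str, matrix.labels)))
    drop = {
        c
        for c, role in split.roles.items()
        if role in ("train", "validation") and label_of.get(c) in types_to_remove
    }
    keep_ids = [c for c in matrix.cell_ids if c not in drop]
    new_roles = {c: r for c, r in split.roles.items() if c not in drop}
    if not any(r == "train" for r in new_roles.values()):
        raise ValueError("removal emptied the training set")
    return matrix.subset_cells(keep_ids), SplitAssignment(
        roles=new_roles, seed=split.seed, scheme=SplitScheme.UNSEEN_TYPE
    )
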