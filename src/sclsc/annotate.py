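"""KNN label transfer in the learned embedding space.

Reference and query cells are embedded with the trained encoder (eval
mode); each query cell receives the majority label of its k nearest
reference cells by Euclidean distance (k = 10 by default).  Vote ties
are broken by the smaller summed neighbor distance, then
lexicographically — deterministic and distance-respecting.  There is no
rejection option: a query of a type absent from the reference still
gets some reference label, visible only through a low vote fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .core_data import ExpressionMatrix
from .encoder import embed, load_checkpoint

__all__ = ["Predictions", "knn_predict", "transfer_labels", "align_genes"]


@dataclass
class Predictions:
    """Per-query predicted label with its vote support."""

    cell_ids: list[str]
    labels: np.ndarray
    vote_fractions: np.ndarray  # winning votes / k, in (0, 1]
    neighbor_indices: np.ndarray | None = field(default=None, repr=False)


def knn_predict(
    ref_Z: np.ndarray,
    ref_labels,
    query_Z: np.ndarray,
    k: int = 10,
    query_ids: list[str] | None = None,
) -> Predictions:
    """Majority vote among the k Euclidean-nearest reference embeddings."""
    if k <= 0:
        raise ValueError("k must be positive")
    ref_Z = np.asarray(ref_Z, dtype=float)
    query_Z = np.asarray(query_Z, dtype=float)
    if ref_Z.shape[1] != query_Z.shape[1]:
        raise ValueError("reference and query embedding dimensions differ")
    if k > ref_Z.shape[0]:
        raise ValueError(f"k={k} exceeds the {ref_Z.shape[0]} reference cells")
    ref_labels = np.asarray([str(l) for l in ref_labels])

    nn = NearestNeighbors(n_neighbors=k, metric="euclidean").fit(ref_Z)
    dist, idx = nn.kneighbors(query_Z)

    n = query_Z.shape[0]
    out_labels = np.empty(n, dtype=object)
    fractions = np.empty(n)
    for i in range(n):
        neigh_labels = ref_labels[idx[i]]
        cands: dict[str, tuple[int, float]] = {}
        for l, d in zip(neigh_labels, dist[i]):
            votes, sdist = cands.get(l, (0, 0.0))
            cands[l] = (votes + 1, sdist + d)
        # most votes, then smaller summed distance, then lexicographic
        winner = min(cands.items(), key=lambda kv: (-kv[1][0], kv[1][1], kv[0]))
        out_labels[i] = winner[0]
        fractions[i] = winner[1][0] / k
    if query_ids is None:
        query_ids = [f"query{i}" for i in range(n)]
    return Predictions(
        cell_ids=list(query_ids),
        labels=out_labels.astype(str),
        vote_fractions=fractions,
        neighbor_indices=idx,
    )


def align_genes(matrix: ExpressionMatrix, gene_ids: list[str]) -> np.ndarray:
    """Dense matrix re-indexed to ``gene_ids``, zero-filling absent genes."""
    pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    missing = [g for g in gene_ids if g not in pos]
    if missing:
        warnings.warn(
            f"{len(missing)} checkpoint genes absent from the query; zero-filled",
            stacklevel=2,
        )
    out = np.zeros((matrix.n_cells, len(gene_ids)))
    present = [(j, pos[g]) for j, g in enumerate(gene_ids) if g in pos]
    if present:
        cols_out, cols_in = zip(*present)
        out[:, list(cols_out)] = np.asarray(matrix.values[:, list(cols_in)].todense())
    return out


def transfer_labels(
    checkpoint_path,
    ref_matrix: ExpressionMatrix,
    ref_labels,
    query_matrix: ExpressionMatrix,
    k: int = 10,
) -> tuple[Predictions, np.ndarray, np.ndarray]:
    """Embed reference and query through a checkpoint, then KNN-vote.

    Both matrices must already be preprocessed (normalized-log); their
    genes are aligned to the checkpoint's stored HVG list.  Returns
    (predictions, ref_Z, query_Z).
    """
    params, cfg, meta = load_checkpoint(checkpoint_path)
    gene_ids = meta["gene_ids"] or ref_matrix.gene_ids
    if ref_matrix.n_cells < k:
        raise ValueError(f"only {ref_matrix.n_cells} reference cells for k={k}")
    Xr = align_genes(ref_matrix, gene_ids)
    Xq = align_genes(query_matrix, gene_ids)
    ref_Z = embed(params, Xr, cfg, mode="eval")
    query_Z = embed(params, Xq, cfg, mode="eval")
    preds = knn_predict(ref_Z, ref_labels, query_Z, k=k, query_ids=query_matrix.cell_ids)
    return preds, ref_Z, query_Z
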