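"""Cell-type dendrograms from type representatives.

Averaging cells per type in either the HVG input space or the learned
embedding space gives one representative vector per type; single-linkage
agglomeration on the Euclidean distance matrix between representatives
yields a dendrogram whose topology can be compared across spaces — a
compact check of whether the embedding preserves between-type structure.
Trees are exported as Newick strings with branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist

from .core_data import LabelVocabulary
from .encoder import embed, load_checkpoint
from .training import compute_representatives

__all__ = [
    "Dendrogram",
    "type_representations",
    "single_linkage_dendrogram",
    "write_newick",
    "newick_string",
]


@dataclass
class Dendrogram:
    """Binary merge tree over type labels (scipy linkage encoding).

    ``merges`` is the (T-1, 4) linkage matrix; heights are non-decreasing
    root-ward, as single linkage guarantees.
    """

    labels: list[str]
    merges: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def merge_order_pairs(self) -> list[set[str]]:
        """Leaf sets merged at each step, in height order (for tests)."""
        clusters: dict[int, set[str]] = {i: {l} for i, l in enumerate(self.labels)}
        out = []
        n = len(self.labels)
        for step, (a, b, _, _) in enumerate(self.merges):
            merged = clusters[int(a)] | clusters[int(b)]
            clusters[n + step] = merged
            out.append(merged)
        return out


def type_representations(
    matrix,
    labels,
    space: str = "input",
    checkpoint_path=None,
) -> tuple[np.ndarray, LabelVocabulary]:
    """Per-type arithmetic mean profiles in input or embedding space.

    ``matrix`` may be an ExpressionMatrix (its ``.values`` are used) or a
    plain array.  Embedding space requires a checkpoint; cells are
    embedded in eval mode first, then averaged per type.
    """
    X = matrix.values if hasattr(matrix, "values") and hasattr(matrix, "gene_ids") else matrix
    vocab = LabelVocabulary.from_labels(labels)
    if space == "input":
        reps = compute_representatives(X, labels, vocab).matrix
    elif space == "embedding":
        if checkpoint_path is None:
            raise ValueError("embedding-space representations need a checkpoint")
        from .annotate import align_genes

        params, cfg, meta = load_checkpoint(checkpoint_path)
        if hasattr(matrix, "gene_ids") and meta["gene_ids"]:
            Xd = align_genes(matrix, meta["gene_ids"])
        else:
            Xd = np.asarray(X.todense() if hasattr(X, "todense") else X, dtype=float)
        Z = embed(params, Xd, cfg, mode="eval")
        reps = compute_representatives(Z, labels, vocab).matrix
    else:
        raise ValueError(f"unknown space {space!r}")
    return reps, vocab


def single_linkage_dendrogram(reps: np.ndarray, labels: list[str]) -> Dendrogram:
    """Single-linkage agglomeration on Euclidean distances between rows.

    Deterministic: with distinct distances the merge sequence is unique;
    exact ties are resolved by cluster index order, i.e. lexicographic
    when ``labels`` are supplied sorted.  Duplicate rows simply merge at
    height zero.
    """
    reps = np.asarray(reps, dtype=float)
    if reps.shape[0] < 2:
        raise ValueError("need at least two types for a dendrogram")
    if len(labels) != reps.shape[0]:
        raise ValueError("labels and representative rows differ in length")
    Z = linkage(pdist(reps, metric="euclidean"), method="single")
    return Dendrogram(labels=list(labels), merges=Z)


def newick_string(dendrogram: Dendrogram) -> str:
    """Newick with branch lengths = parent merge height - child merge height."""
    root = to_tree(dendrogram.merges)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{dendrogram.labels[node.id]}:{length:.10g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    inner = render(root, root.dist)
    # strip the root's zero-length suffix
    return inner.rsplit(":", 1)[0] + ";"


def write_newick(dendrogram: Dendrogram, path) -> None:
    with open(path, "w") as fh:
        fh.write(newick_string(dendrogram) + "\n")
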