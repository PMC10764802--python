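"""Gamma-Poisson grouped count simulator for single-cell RNA-seq.

Generates overdispersed counts for a configurable number of cell groups
(types), in the style of the Splatter family of simulators: gene base
means drawn from a gamma distribution, per-group log-normal
differential-expression (DE) factors, log-normal library sizes, optional
multiplicative per-batch factors, and Poisson sampling around the
cell-specific expected expression.  Marginally the counts are
gamma-Poisson (negative-binomial-like) overdispersed.

Two generators are provided:

* :func:`simulate_counts` — flat groups, the workhorse for annotation
  benchmarks and scalability-style tests.
* :func:`simulate_hierarchy` — groups arranged on a tree, with DE
  factors accumulated along root-to-leaf paths so that sibling leaves
  share ancestral DE genes; used to probe whether learned embeddings
  preserve between-type hierarchy.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_data import ExpressionMatrix, TransformState

__all__ = ["SimConfig", "SimTruth", "simulate_counts", "simulate_hierarchy"]


@dataclass
class SimConfig:
    """Simulation parameters.

    Defaults follow the common configuration for this kind of simulator:
    2000 genes and ten equiprobable groups; gamma(shape=0.6, rate=0.3)
    base gene means; log-normal library sizes around 10,000 counts; 10%
    of genes DE per group with log-normal factors.
    """

    n_cells: int = 1000
    n_genes: int = 2000
    group_probs: tuple[float, ...] = tuple([0.1] * 10)
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    lib_loc: float = float(np.log(1e4))
    lib_scale: float = 0.25
    de_prob: float = 0.1
    de_fac_loc: float = 0.3
    de_fac_scale: float = 0.4
    batch_fac_loc: float = 0.1
    batch_fac_scale: float = 0.1
    n_batches: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.group_probs, dtype=float)
        if p.ndim != 1 or p.size < 1 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("group_probs must be non-negative and sum to 1")
        if not (0.0 <= self.de_prob <= 1.0):
            raise ValueError("de_prob must lie in [0, 1]")
        for name in ("mean_shape", "mean_rate", "lib_scale", "de_fac_scale", "batch_fac_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.n_cells < p.size:
            raise ValueError("need at least one cell per group")


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated matrix (for tests/oracles)."""

    group: np.ndarray  # group name per cell
    batch: np.ndarray  # batch name per cell
    de_factor: np.ndarray  # (n_groups, n_genes) multiplicative factors
    base_means: np.ndarray  # (n_genes,)
    group_names: list[str] = field(default_factory=list)
    expected_expression: np.ndarray | None = None  # (n_cells, n_genes)

    def expected_group_means(self) -> np.ndarray:
        """Noise-free group mean profiles (groups x genes), library-normalized."""
        w = self.base_means[None, :] * self.de_factor
        return w / w.sum(axis=1, keepdims=True)


def largest_remainder_sizes(n: int, probs: Sequence[float]) -> np.ndarray:
    """Deterministic integer allocation of ``n`` items to ``probs``.

    Floors the exact shares, then hands remaining items to the largest
    fractional remainders (lowest index first on ties).
    """
    probs = np.asarray(probs, dtype=float)
    exact = n * probs
    sizes = np.floor(exact).astype(int)
    rem = n - sizes.sum()
    if rem > 0:
        frac = exact - np.floor(exact)
        order = np.lexsort((np.arange(len(probs)), -frac))
        sizes[order[:rem]] += 1
    return sizes


def _draw_de_factors(rng, n_groups, n_genes, de_prob, loc, scale):
    """(n_groups, n_genes) log-normal DE factors, 1 for non-DE genes.

    Each factor is inverted to 1/f with probability 0.5 so that DE can be
    either up- or down-regulation.
    """
    fac = np.ones((n_groups, n_genes))
    if de_prob == 0:
        return fac
    is_de = rng.random((n_groups, n_genes)) < de_prob
    raw = rng.lognormal(mean=loc, sigma=scale, size=(n_groups, n_genes))
    invert = rng.random((n_groups, n_genes)) < 0.5
    raw = np.where(invert, 1.0 / raw, raw)
    fac[is_de] = raw[is_de]
    return fac


def _assemble(cfg: SimConfig, rng, de_factor, group_names, group_of_cell):
    """Common tail of both simulators: libraries, batches, Poisson draw."""
    n_groups = len(group_names)
    base_means = rng.gamma(shape=cfg.mean_shape, scale=1.0 / cfg.mean_rate, size=cfg.n_genes)

    lib = rng.lognormal(mean=cfg.lib_loc, sigma=cfg.lib_scale, size=cfg.n_cells)

    if cfg.n_batches > 1:
        batch_fac = rng.lognormal(
            mean=cfg.batch_fac_loc, sigma=cfg.batch_fac_scale, size=(cfg.n_batches, cfg.n_genes)
        )
    else:
        batch_fac = np.ones((1, cfg.n_genes))
    # round-robin batch assignment within each group keeps group/batch balanced
    batch_of_cell = np.zeros(cfg.n_cells, dtype=int)
    for j in range(n_groups):
        idx = np.flatnonzero(group_of_cell == j)
        batch_of_cell[idx] = np.arange(idx.size) % cfg.n_batches

    weights = base_means[None, :] * de_factor  # (n_groups, n_genes)
    expected = np.empty((cfg.n_cells, cfg.n_genes))
    for k in range(cfg.n_batches):
        for j in range(n_groups):
            idx = np.flatnonzero((group_of_cell == j) & (batch_of_cell == k))
            if idx.size == 0:
                continue
            w = weights[j] * batch_fac[k]
            expected[idx] = lib[idx, None] * (w / w.sum())

    counts = rng.poisson(expected)

    cell_ids = [f"Cell{i + 1}" for i in range(cfg.n_cells)]
    gene_ids = [f"Gene{g + 1}" for g in range(cfg.n_genes)]
    group_labels = np.array([group_names[j] for j in group_of_cell])
    batch_labels = np.array([f"Batch{k + 1}" for k in batch_of_cell])
    meta = pd.DataFrame(
        {"label": group_labels, "batch": batch_labels},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    matrix = ExpressionMatrix(
        values=sp.csr_matrix(counts),
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        cell_meta=meta,
        transform_state=TransformState.RAW_COUNTS,
    )
    truth = SimTruth(
        group=group_labels,
        batch=batch_labels,
        de_factor=de_factor,
        base_means=base_means,
        group_names=list(group_names),
        expected_expression=expected,
    )
    return matrix, truth


def simulate_counts(cfg: SimConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Simulate a grouped gamma-Poisson count matrix with ground truth.

    Group sizes follow deterministic largest-remainder rounding of
    ``n_cells * group_probs``, so tests can assert exact counts.  Cell
    labels are the group names ("Group1", ...).
    """
    rng = np.random.default_rng(cfg.seed)
    n_groups = len(cfg.group_probs)
    group_names = [f"Group{j + 1}" for j in range(n_groups)]

    sizes = largest_remainder_sizes(cfg.n_cells, cfg.group_probs)
    group_of_cell = np.repeat(np.arange(n_groups), sizes)

    de_factor = _draw_de_factors(
        rng, n_groups, cfg.n_genes, cfg.de_prob, cfg.de_fac_loc, cfg.de_fac_scale
    )
    return _assemble(cfg, rng, de_factor, group_names, group_of_cell)


# ---------------------------------------------------------------------------
# Hierarchical variant
# ---------------------------------------------------------------------------

def _tree_leaves(tree) -> list[str]:
    if isinstance(tree, str):
        return [tree]
    out: list[str] = []
    for child in tree:
        out.extend(_tree_leaves(child))
    return out


def _tree_depth(tree) -> int:
    if isinstance(tree, str):
        return 0
    return 1 + max(_tree_depth(c) for c in tree)


def simulate_hierarchy(
    tree,
    level_de: Sequence[tuple[float, float, float]],
    cfg: SimConfig,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Simulate counts for leaf types arranged on a nested-tuple tree.

    ``tree`` is a nested tuple of leaf-name strings, e.g.
    ``(("A", "B"), ("C", "D"))``.  ``level_de[l]`` gives
    ``(de_prob, de_fac_loc, de_fac_scale)`` for edges entering depth
    ``l + 1`` (level 0 = edges leaving the root).  DE factors multiply
    cumulatively along each root-to-leaf path, so sibling leaves share
    all ancestral DE genes and differ only by their own terminal edges;
    expected mean-profile distance therefore grows with tree distance.

    Leaf group sizes follow largest-remainder rounding of a uniform
    split of ``cfg.n_cells`` (``cfg.group_probs`` is ignored).
    """
    leaves = _tree_leaves(tree)
    if isinstance(tree, str) or len(leaves) < 2:
        raise ValueError("tree must have at least two leaves")
    if len(set(leaves)) != len(leaves):
        raise ValueError("duplicate leaf names in tree")
    depth = _tree_depth(tree)
    if depth < 2:
        raise ValueError("tree must have at least two levels")
    if len(level_de) < depth:
        raise ValueError(f"need DE parameters for {depth} levels, got {len(level_de)}")

    rng = np.random.default_rng(cfg.seed)
    n_leaves = len(leaves)
    leaf_index = {name: i for i, name in enumerate(leaves)}
    de_factor = np.ones((n_leaves, cfg.n_genes))

    def descend(node, level: int) -> None:
        if isinstance(node, str):
            return
        for child in node:
            de_prob, loc, scale = level_de[level]
            edge = _draw_de_factors(rng, 1, cfg.n_genes, de_prob, loc, scale)[0]
            for leaf in _tree_leaves(child):
                de_factor[leaf_index[leaf]] *= edge
            descend(child, level + 1)

    descend(tree, 0)

    sizes = largest_remainder_sizes(cfg.n_cells, np.full(n_leaves, 1.0 / n_leaves))
    group_of_cell = np.repeat(np.arange(n_leaves), sizes)
    cfg = replace(cfg, group_probs=tuple(np.full(n_leaves, 1.0 / n_leaves)))
    return _assemble(cfg, rng, de_factor, leaves, group_of_cell)
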