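"""Recover planted differential genes with analytic Pearson residuals.

Builds a two-group count matrix in which 50 of 2,000 genes carry a
4-fold between-group expression shift, ranks genes by the variance of
their analytic Pearson residuals, and reports how many planted genes
land in the top 200.
"""

import numpy as np
import scipy.sparse as sp

from sclsc import ExpressionMatrix, select_hvgs

rng = np.random.default_rng(7)
n_cells, n_genes = 1000, 2000
base = rng.gamma(0.6, 1 / 0.3, size=n_genes)
de_genes = rng.choice(n_genes, size=50, replace=False)
factors = np.ones((2, n_genes))
factors[1, de_genes] = 4.0
group = np.repeat([0, 1], n_cells // 2)
lib = rng.lognormal(np.log(1e4), 0.25, size=n_cells)
w = base[None, :] * factors
w /= w.sum(axis=1, keepdims=True)
counts = rng.poisson(lib[:, None] * w[group])

matrix = ExpressionMatrix(
    values=sp.csr_matrix(counts),
    cell_ids=[f"c{i}" for i in range(n_cells)],
    gene_ids=[f"g{j}" for j in range(n_genes)],
)
res = select_hvgs(matrix, n_top=200)
recovered = sum(1 for g in de_genes if f"g{g}" in set(res.gene_ids))
print(f"planted strong-DE genes recovered in top 200: {recovered} / 50")
print("residual variance of the best-ranked gene: "
      f"{max(res.residual_variance):.2f} (a no-signal gene is near 1)")
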