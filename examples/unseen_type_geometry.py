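"""What happens to a cell type the encoder never saw?

Deletes one simulated group from the training and validation folds,
trains, and inspects the test-fold embedding: the unseen type cannot be
predicted correctly (KNN must assign a known label) but still forms its
own cluster, measured by a positive mean silhouette against the other
types.
"""

import numpy as np
from sklearn.metrics import silhouette_samples

from sclsc import SimConfig, TrainConfig, run_experiment, simulate_counts

cfg = SimConfig(
    n_cells=3000, n_genes=1000, group_probs=tuple([0.1] * 10),
    de_prob=0.2, de_fac_loc=1.0, seed=3,
)
matrix, _ = simulate_counts(cfg)
result = run_experiment(
    "unseen_type", matrix, seed=3, n_hvgs=1000,
    enc_cfg={"output_dim": 16}, train_cfg=TrainConfig(margin=1.0, seed=3),
    k=10, types_to_remove=["Group5"],
)

unseen = result.test_labels_true == "Group5"
sil = silhouette_samples(result.test_Z, result.test_labels_true)
votes = result.predictions.vote_fractions
print(f"types seen in training: {len(result.vocab)}")
print(f"unseen cells in test fold: {unseen.sum()}")
print(f"labels KNN assigned to them: {sorted(set(map(str, result.predictions.labels[unseen])))}")
print(f"mean vote fraction, unseen vs seen: "
      f"{votes[unseen].mean():.2f} vs {votes[~unseen].mean():.2f}")
print(f"mean silhouette of the unseen type: {sil[unseen].mean():.2f}")
print("a positive silhouette means the unseen type still occupies its own "
      "region of the embedding even though no label can be transferred to it.")
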