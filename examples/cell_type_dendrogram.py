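"""Check that the embedding preserves cell-type hierarchy.

Simulates four cell types on the tree ((A,B),(C,D)) — siblings share
differential genes inherited from their common ancestor — trains the
encoder, and builds single-linkage dendrograms of the type
representatives in input space and in embedding space.  If the learned
space preserves biology, A merges with B and C with D in both trees.
"""

from sclsc import SimConfig, TrainConfig, simulate_hierarchy
from sclsc.encoder import EncoderConfig, save_checkpoint
from sclsc.hierarchy import newick_string, single_linkage_dendrogram, type_representations
from sclsc.pipeline import prepare_inputs
from sclsc.preprocess import stratified_split
from sclsc.training import train
import tempfile
from pathlib import Path

matrix, truth = simulate_hierarchy(
    (("A", "B"), ("C", "D")),
    level_de=[(0.3, 1.2, 0.3), (0.1, 0.4, 0.3)],
    cfg=SimConfig(n_cells=1600, n_genes=600, seed=2),
)
labels = dict(zip(matrix.cell_ids, map(str, matrix.labels)))
split = stratified_split(labels, seed=2)
norm, hvg_genes, role_ids = prepare_inputs(matrix, split, n_hvgs=300)
tr, va = (norm.subset_cells(role_ids[r]) for r in ("train", "validation"))

enc = EncoderConfig(input_dim=norm.n_genes, output_dim=16, seed=2)
params, reps, log = train(tr.values, tr.labels, va.values, va.labels, enc,
                          TrainConfig(margin=1.0, seed=2, max_epochs=60))

ckpt = Path(tempfile.mkdtemp()) / "model"
save_checkpoint(params, enc, ckpt, gene_ids=norm.gene_ids)

for space in ("input", "embedding"):
    reps_s, vocab = type_representations(
        norm, norm.labels, space=space,
        checkpoint_path=ckpt if space == "embedding" else None,
    )
    dend = single_linkage_dendrogram(reps_s, list(vocab.types))
    print(f"{space:>9} space: {newick_string(dend)}")
print("in both Newick strings the sibling types (A,B) and (C,D) should "
      "appear as the innermost pairs, i.e. the tree topology is preserved.")
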