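"""End-to-end experiment protocols: random split, batch split, unseen type.

Each protocol runs the full recipe on a labeled count matrix: QC ->
split -> HVG selection -> per-cell normalization -> encoder training ->
KNN label transfer onto the test cells -> metric report.  HVG selection
is computed on the training cells by default to avoid test leakage; set
``hvg_on_full=True`` to select on the whole dataset before splitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotate import Predictions, knn_predict
from .core_data import ExpressionMatrix, LabelVocabulary, SplitAssignment
from .encoder import EncoderConfig, EncoderParams, embed
from .evaluate import MetricReport, evaluate_predictions
from .preprocess import (
    QCConfig,
    batch_split,
    normalize_log,
    qc_filter,
    remove_types,
    select_hvgs,
    stratified_split,
)
from .training import RepresentativeSet, TrainConfig, TrainLog, train

__all__ = ["ExperimentResult", "run_experiment", "prepare_inputs"]


@dataclass
class ExperimentResult:
    """Everything an experiment produced, for inspection and testing."""

    metrics: MetricReport
    predictions: Predictions
    params: EncoderParams
    enc_cfg: EncoderConfig
    representatives: RepresentativeSet
    train_log: TrainLog
    vocab: LabelVocabulary
    hvg_genes: list[str]
    split: SplitAssignment
    test_labels_true: np.ndarray
    test_Z: np.ndarray
    ref_Z: np.ndarray
    raw_metrics: MetricReport | None = None
    extras: dict = field(default_factory=dict)


def prepare_inputs(
    matrix: ExpressionMatrix,
    split: SplitAssignment,
    n_hvgs: int = 2000,
    target_sum: float = 1e4,
    hvg_on_full: bool = False,
):
    """HVG-select, subset and normalize; return per-role dense views.

    Returns (norm_matrix, hvg_genes, role_ids) where ``norm_matrix`` is
    the normalized-log matrix restricted to the selected HVGs and
    ``role_ids`` maps role -> cell id list (matrix order).
    """
    roles = split.roles
    order = {c: i for i, c in enumerate(matrix.cell_ids)}
    role_ids = {
        r: sorted((c for c, rr in roles.items() if rr == r and c in order), key=order.get)
        for r in ("train", "validation", "test")
    }
    hvg_source = matrix if hvg_on_full else matrix.subset_cells(role_ids["train"])
    hvg = select_hvgs(hvg_source, n_top=n_hvgs)
    sub = matrix.subset_genes(hvg.gene_ids)
    norm = normalize_log(sub, target_sum=target_sum)
    return norm, hvg.gene_ids, role_ids


def _train_and_annotate(
    norm: ExpressionMatrix,
    role_ids: dict,
    enc_cfg_base: dict,
    train_cfg: TrainConfig,
    k: int,
):
    labels = dict(zip(norm.cell_ids, map(str, norm.labels)))
    train_m = norm.subset_cells(role_ids["train"])
    val_m = norm.subset_cells(role_ids["validation"])
    test_m = norm.subset_cells(role_ids["test"])

    vocab = LabelVocabulary.from_labels(train_m.labels)
    enc_cfg = EncoderConfig(input_dim=norm.n_genes, **enc_cfg_base)
    params, reps, log = train(
        train_m.values,
        train_m.labels,
        val_m.values,
        val_m.labels,
        enc_cfg,
        train_cfg,
        vocab=vocab,
    )
    Xr = np.asarray(train_m.values.todense(), dtype=float)
    Xq = np.asarray(test_m.values.todense(), dtype=float)
    ref_Z = embed(params, Xr, enc_cfg, mode="eval")
    test_Z = embed(params, Xq, enc_cfg, mode="eval")
    preds = knn_predict(ref_Z, train_m.labels, test_Z, k=k, query_ids=test_m.cell_ids)
    y_true = np.asarray([labels[c] for c in test_m.cell_ids])
    return dict(
        params=params,
        enc_cfg=enc_cfg,
        reps=reps,
        log=log,
        vocab=vocab,
        preds=preds,
        y_true=y_true,
        ref_Z=ref_Z,
        test_Z=test_Z,
        train_m=train_m,
        test_m=test_m,
    )


def run_experiment(
    scheme: str,
    matrix: ExpressionMatrix,
    seed: int = 0,
    qc: QCConfig | None = None,
    n_hvgs: int = 2000,
    target_sum: float = 1e4,
    hvg_on_full: bool = False,
    enc_cfg: dict | None = None,
    train_cfg: TrainConfig | None = None,
    k: int = 10,
    train_batches=None,
    test_batches=None,
    types_to_remove=None,
    compare_raw_knn: bool = False,
    skip_qc: bool = False,
) -> ExperimentResult:
    """Run one of the three annotation protocols end to end.

    ``scheme`` is "random_split" (stratified 8:1:1), "batch_split"
    (whole batches held out as test, 9:1 train:validation inside the
    training batches) or "unseen_type" (random split, then
    ``types_to_remove`` deleted from train/validation only).  With
    ``compare_raw_knn`` the same KNN is additionally run on the raw
    normalized HVG profiles, for embedding-vs-raw comparisons.
    """
    if scheme not in ("random_split", "batch_split", "unseen_type"):
        raise ValueError(f"unknown scheme {scheme!r}")
    train_cfg = train_cfg or TrainConfig(seed=seed)
    enc_cfg = dict(enc_cfg or {})

    if not skip_qc:
        matrix, _ = qc_filter(matrix, qc or QCConfig())
    labels = dict(zip(matrix.cell_ids, map(str, matrix.labels)))

    if scheme == "batch_split":
        if train_batches is None or test_batches is None:
            raise ValueError("batch_split needs train_batches and test_batches")
        batches = dict(zip(matrix.cell_ids, map(str, matrix.batches)))
        split = batch_split(batches, labels, train_batches, test_batches, seed)
    else:
        split = stratified_split(labels, seed)
        if scheme == "unseen_type":
            if not types_to_remove:
                raise ValueError("unseen_type needs types_to_remove")
            matrix, split = remove_types(matrix, split, types_to_remove)
            labels = dict(zip(matrix.cell_ids, map(str, matrix.labels)))

    norm, hvg_genes, role_ids = prepare_inputs(
        matrix, split, n_hvgs=n_hvgs, target_sum=target_sum, hvg_on_full=hvg_on_full
    )
    r = _train_and_annotate(norm, role_ids, enc_cfg, train_cfg, k)

    metrics = evaluate_predictions(r["y_true"], r["preds"].labels)
    raw_metrics = None
    if compare_raw_knn:
        Xr = np.asarray(r["train_m"].values.todense(), dtype=float)
        Xq = np.asarray(r["test_m"].values.todense(), dtype=float)
        raw_preds = knn_predict(Xr, r["train_m"].labels, Xq, k=k, query_ids=r["test_m"].cell_ids)
        raw_metrics = evaluate_predictions(r["y_true"], raw_preds.labels)

    return ExperimentResult(
        metrics=metrics,
        predictions=r["preds"],
        params=r["params"],
        enc_cfg=r["enc_cfg"],
        representatives=r["reps"],
        train_log=r["log"],
        vocab=r["vocab"],
        hvg_genes=hvg_genes,
        split=split,
        test_labels_true=r["y_true"],
        test_Z=r["test_Z"],
        ref_Z=r["ref_Z"],
        raw_metrics=raw_metrics,
    )
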