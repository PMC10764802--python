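"""QC filtering, Pearson-residual HVG selection, normalization and splits."""

import numpy as np
import pytest
import scipy.sparse as sp

from sclsc import ExpressionMatrix, SimConfig, simulate_counts
from sclsc.preprocess import (
    QCConfig,
    batch_split,
    normalize_log,
    qc_filter,
    remove_types,
    select_hvgs,
    stratified_split,
)


def _matrix(dense, gene_ids=None, labels=None, batches=None):
    dense = np.asarray(dense)
    n, g = dense.shape
    m = ExpressionMatrix(
        values=sp.csr_matrix(dense),
        cell_ids=[f"c{i}" for i in range(n)],
        gene_ids=gene_ids or [f"g{j}" for j in range(g)],
    )
    if labels is not None:
        m.cell_meta["label"] = labels
    if batches is not None:
        m.cell_meta["batch"] = batches
    return m


class TestQCFilter:
    # 4 cells x 4 genes; gene 0 is mitochondrial. Cell 0 has 10% mito.
    def _toy(self):
        dense = [
            [2, 6, 6, 6],   # mito fraction 0.1 -> removed by rule 1
            [0, 5, 5, 5],
            [0, 4, 4, 4],
            [0, 3, 3, 3],
        ]
        return _matrix(dense, gene_ids=["MT-1", "g1", "g2", "g3"])

    def test_high_mito_cell_removed_and_counted(self):
        cfg = QCConfig(max_mito_fraction=0.05, min_genes_per_cell=0, min_cells_per_gene=0)
        out, report = qc_filter(self._toy(), cfg)
        assert report.n_cells_removed_mito == 1
        assert out.cell_ids == ["c1", "c2", "c3"]

    def test_no_mito_genes_and_expressive_cells_is_identity(self, rng):
        dense = rng.poisson(3.0, size=(6, 5)) + 1  # every gene expressed everywhere
        m = _matrix(dense)
        out, report = qc_filter(m, QCConfig(min_genes_per_cell=5, min_cells_per_gene=3))
        assert out.cell_ids == m.cell_ids and out.gene_ids == m.gene_ids
        assert (report.n_cells_removed_mito, report.n_cells_removed_min_genes,
                report.n_genes_removed_min_cells) == (0, 0, 0)

    def test_gene_at_exact_threshold_is_retained(self):
        # gene g3 expressed in exactly 3 cells; strict "<" keeps it
        dense = np.ones((4, 4), dtype=int)
        dense[0, 3] = 0
        m = _matrix(dense)
        out, report = qc_filter(m, QCConfig(min_genes_per_cell=0, min_cells_per_gene=3))
        assert "g3" in out.gene_ids
        assert report.n_genes_removed_min_cells == 0

    def test_min_genes_rule_counts_expressed_genes(self):
        dense = [[1, 1, 1, 0], [1, 0, 0, 0], [1, 1, 1, 1], [1, 1, 1, 1]]
        out, report = qc_filter(_matrix(dense), QCConfig(min_genes_per_cell=2, min_cells_per_gene=0))
        assert report.n_cells_removed_min_genes == 1
        assert "c1" not in out.cell_ids

    def test_idempotent(self, rng):
        dense = rng.poisson(1.0, size=(30, 20))
        cfg = QCConfig(min_genes_per_cell=5, min_cells_per_gene=3)
        once, _ = qc_filter(_matrix(dense), cfg)
        twice, rep2 = qc_filter(once, cfg)
        assert twice.cell_ids == once.cell_ids and twice.gene_ids == once.gene_ids
        assert (rep2.n_cells_removed_mito, rep2.n_cells_removed_min_genes,
                rep2.n_genes_removed_min_cells) == (0, 0, 0)

    def test_emptied_matrix_names_the_rule(self):
        dense = [[1, 0, 0], [0, 1, 0]]
        with pytest.raises(ValueError, match="min-genes-per-cell"):
            qc_filter(_matrix(dense), QCConfig(min_genes_per_cell=3, min_cells_per_gene=0))


class TestSelectHVGs:
    def test_gene_tracking_cell_totals_has_zero_residual_variance(self, rng):
        # gene 0 = exactly n_c * p_g for every cell -> residuals all 0
        other = rng.poisson(5.0, size=(8, 3)) + 1
        tot_other = other.sum(axis=1)
        g0 = tot_other.copy()  # now p_0 = 1/2, mu_c0 = tot_c/2 = g0 exactly
        dense = np.column_stack([g0, other])
        res = select_hvgs(_matrix(dense), n_top=4)
        assert res.residual_variance[0] < 1e-12
        assert res.gene_ids[-1] == "g0"  # ranked last

    def test_n_top_all_genes_ordered_by_decreasing_variance(self, rng):
        dense = rng.poisson(2.0, size=(20, 6)) + 1
        res = select_hvgs(_matrix(dense), n_top=6)
        var_of = dict(zip([f"g{j}" for j in range(6)], res.residual_variance))
        ordered = [var_of[g] for g in res.gene_ids]
        assert ordered == sorted(ordered, reverse=True)

    def test_all_zero_gene_is_safe_and_last(self, rng):
        dense = rng.poisson(2.0, size=(10, 4)) + 1
        dense[:, 2] = 0
        res = select_hvgs(_matrix(dense), n_top=4)
        assert res.residual_variance[2] == 0.0

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            select_hvgs(_matrix(np.zeros((4, 4), dtype=int)), n_top=2)

    def test_invariant_to_cell_and_gene_order(self, rng):
        dense = rng.poisson(2.0, size=(15, 8)) + rng.integers(0, 3, size=(15, 8))
        m = _matrix(dense)
        res = select_hvgs(m, n_top=3)
        perm_c = rng.permutation(15)
        perm_g = rng.permutation(8)
        m2 = ExpressionMatrix(
            values=sp.csr_matrix(dense[np.ix_(perm_c, perm_g)]),
            cell_ids=[f"c{i}" for i in perm_c],
            gene_ids=[f"g{j}" for j in perm_g],
        )
        res2 = select_hvgs(m2, n_top=3)
        assert set(res.gene_ids) == set(res2.gene_ids)

    def test_matches_scanpy_reference_selection(self):
        """Independent oracle: scanpy's analytic Pearson residual HVGs."""
        scanpy = pytest.importorskip("scanpy")
        cfg = SimConfig(n_cells=300, n_genes=400, group_probs=(0.25,) * 4,
                        de_prob=0.2, de_fac_loc=0.8, seed=5)
        m, _ = simulate_counts(cfg)
        mine = select_hvgs(m, n_top=80)
        ad = m.to_anndata()
        scanpy.experimental.pp.highly_variable_genes(ad, n_top_genes=80, flavor="pearson_residuals")
        theirs = set(ad.var_names[ad.var["highly_variable"]])
        assert set(mine.gene_ids) == theirs


class TestNormalizeLog:
    def test_forced_arithmetic(self):
        m = _matrix([[2, 0, 2], [1, 1, 2]])
        out = normalize_log(m, target_sum=1e4)
        row0 = out.values.toarray()[0]
        assert row0 == pytest.approx([np.log(5001), 0.0, np.log(5001)])

    def test_cell_already_at_target_sum_is_plain_log1p(self):
        m = _matrix([[4, 6]])
        out = normalize_log(m, target_sum=10)
        assert out.values.toarray()[0] == pytest.approx(np.log1p([4, 6]))

    def test_row_sums_conserved(self, rng):
        dense = rng.poisson(3.0, size=(25, 10)) + 1
        out = normalize_log(_matrix(dense), target_sum=1e4)
        back = np.expm1(out.values.toarray()).sum(axis=1)
        assert np.abs(back - 1e4).max() < 1e-6

    def test_zeros_stay_zero(self, rng):
        dense = rng.poisson(1.0, size=(10, 8))
        dense[:, 0] += 1  # no zero-total cells
        out = normalize_log(_matrix(dense), target_sum=100)
        assert np.array_equal(out.values.toarray() == 0, dense == 0)

    def test_invariant_to_uniform_cell_scaling(self):
        a = normalize_log(_matrix([[1, 2, 3]]), target_sum=100).values.toarray()
        b = normalize_log(_matrix([[3, 6, 9]]), target_sum=100).values.toarray()
        assert a == pytest.approx(b)

    def test_zero_total_cell_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            normalize_log(_matrix([[1, 1], [0, 0]]))


class TestStratifiedSplit:
    def test_single_label_80_10_10(self):
        labels = {f"c{i}": "T" for i in range(100)}
        split = stratified_split(labels, seed=0)
        assert split.counts() == {"train": 80, "validation": 10, "test": 10}

    def test_two_labels_each_40_5_5(self):
        labels = {f"a{i}": "A" for i in range(50)} | {f"b{i}": "B" for i in range(50)}
        split = stratified_split(labels, seed=0)
        for lab, prefix in (("A", "a"), ("B", "b")):
            ids = [f"{prefix}{i}" for i in range(50)]
            roles = [split.roles[c] for c in ids]
            assert roles.count("train") == 40
            assert roles.count("validation") == 5
            assert roles.count("test") == 5

    def test_deterministic_per_seed_and_seed_sensitive(self):
        labels = {f"c{i}": f"T{i % 4}" for i in range(1000)}
        s1 = stratified_split(labels, seed=3)
        s2 = stratified_split(labels, seed=3)
        s3 = stratified_split(labels, seed=4)
        assert s1.roles == s2.roles
        assert s1.roles != s3.roles

    def test_proportions_within_one_cell_of_8_1_1(self):
        labels = {f"c{i}": f"T{i % 3}" for i in range(97)}
        split = stratified_split(labels, seed=1)
        for t in ("T0", "T1", "T2"):
            ids = [c for c, l in labels.items() if l == t]
            n = len(ids)
            roles = [split.roles[c] for c in ids]
            assert abs(roles.count("validation") - n / 10) <= 1
            assert abs(roles.count("test") - n / 10) <= 1

    def test_small_label_warns(self):
        labels = {f"c{i}": "rare" if i < 5 else "common" for i in range(105)}
        with pytest.warns(UserWarning, match="rare"):
            stratified_split(labels, seed=0)

    def test_unlabeled_cells_rejected(self):
        from sclsc import MISSING_LABEL

        with pytest.raises(ValueError, match="labeled"):
            stratified_split({"c1": MISSING_LABEL, "c2": "T"}, seed=0)


class TestBatchSplit:
    def _data(self, n=200):
        batches = {f"c{i}": ("A" if i < n // 2 else "B") for i in range(n)}
        labels = {f"c{i}": f"T{i % 2}" for i in range(n)}
        return batches, labels

    def test_test_batch_held_out_and_train_split_9_1(self):
        batches, labels = self._data(200)
        split = batch_split(batches, labels, ["A"], ["B"], seed=0)
        assert all(split.roles[f"c{i}"] == "test" for i in range(100, 200))
        train_roles = [split.roles[f"c{i}"] for i in range(100)]
        assert train_roles.count("train") == 90
        assert train_roles.count("validation") == 10

    def test_empty_test_batches_rejected(self):
        batches, labels = self._data(20)
        with pytest.raises(ValueError):
            batch_split(batches, labels, ["A", "B"], [], seed=0)

    def test_unknown_batch_tag_rejected(self):
        batches, labels = self._data(20)
        with pytest.raises(ValueError, match="unknown"):
            batch_split(batches, labels, ["A", "Z"], ["B"], seed=0)

    def test_uncovered_batch_rejected(self):
        batches, labels = self._data(20)
        with pytest.raises(ValueError, match="not assigned"):
            batch_split(batches, labels, ["A"], [], seed=0)

    def test_label_proportions_in_train_vs_validation(self):
        batches, labels = self._data(400)
        split = batch_split(batches, labels, ["A"], ["B"], seed=0)
        for t in ("T0", "T1"):
            ids = [c for c in batches if batches[c] == "A" and labels[c] == t]
            roles = [split.roles[c] for c in ids]
            n = len(ids)
            assert abs(roles.count("validation") - n / 10) <= 1


class TestRemoveTypes:
    def _setup(self):
        labels = {f"c{i}": ("X" if i % 5 == 0 else f"T{i % 2}") for i in range(100)}
        dense = np.ones((100, 4), dtype=int)
        m = _matrix(dense)
        m.cell_meta["label"] = [labels[c] for c in m.cell_ids]
        split = stratified_split(labels, seed=0)
        return m, split

    def test_type_removed_from_train_val_kept_in_test(self):
        m, split = self._setup()
        m2, split2 = remove_types(m, split, ["X"])
        for c in m2.cell_ids:
            if split2.roles[c] in ("train", "validation"):
                assert m2.cell_meta.loc[c, "label"] != "X"
        test_labels = [m2.cell_meta.loc[c, "label"] for c in split2.ids_for("test")]
        assert "X" in test_labels

    def test_absent_type_is_warned_noop(self):
        m, split = self._setup()
        with pytest.warns(UserWarning, match="not present"):
            m2, split2 = remove_types(m, split, ["ZZZ"])
        assert m2.cell_ids == m.cell_ids
        assert split2.roles == split.roles

    def test_train_count_drops_by_removed_cells(self):
        m, split = self._setup()
        n_x_train = sum(
            1 for c in split.ids_for("train") if m.cell_meta.loc[c, "label"] == "X"
        )
        _, split2 = remove_types(m, split, ["X"])
        assert len(split2.ids_for("train")) == len(split.ids_for("train")) - n_x_train

    def test_emptying_train_set_rejected(self):
        labels = {f"c{i}": "X" for i in range(20)}
        m = _matrix(np.ones((20, 3), dtype=int))
        m.cell_meta["label"] = "X"
        split = stratified_split(labels, seed=0)
        with pytest.raises(ValueError, match="training set"):
            remove_types(m, split, ["X"])
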