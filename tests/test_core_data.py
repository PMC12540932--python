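import numpy as np
import pandas as pd
import pytest

from scexplain import core_data
from scexplain.core_data import (
    CellMatrix,
    EmptyResultError,
    QCThresholds,
    SchemaError,
    load_matrix,
    normalize_log,
    percent_expression,
    qc_filter,
    split_train_test,
    write_matrix,
)

from conftest import make_cell_matrix


class TestLoadWrite:
    def test_mtx_roundtrip_preserves_counts_and_metadata(self, tiny_matrix, tmp_path):
        write_matrix(tiny_matrix, tmp_path / "m")
        back = load_matrix(tmp_path / "m")
        np.testing.assert_array_equal(back.counts(), tiny_matrix.counts())
        assert list(back.gene_ids) == list(tiny_matrix.gene_ids)
        assert list(back.cell_ids) == list(tiny_matrix.cell_ids)
        pd.testing.assert_frame_equal(
            back.obs[list(core_data.REQUIRED_OBS)].astype(str),
            tiny_matrix.obs[list(core_data.REQUIRED_OBS)].astype(str))

    def test_triplet_fixture_shape(self, tmp_path):
        d = tmp_path / "m"
        d.mkdir()
        (d / "matrix.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n"
            "2 3 3\n1 1 5\n2 2 1\n1 3 2\n")  # genes x cells triplets
        (d / "features.tsv").write_text("gA\ngB\n")
        (d / "barcodes.tsv").write_text("c1\nc2\nc3\n")
        (d / "metadata.tsv").write_text(
            "cell_id\tsubject_id\tcondition\tcell_type\tdataset_id\n"
            "c1\ts1\tcase\tt\td\nc2\ts2\tcontrol\tt\td\nc3\ts1\tcase\tt\td\n")
        m = load_matrix(d)
        assert m.shape == (3, 2)
        assert m.counts()[0, 0] == 5 and m.counts()[2, 0] == 2

    def test_missing_condition_column_is_schema_error(self, tiny_matrix, tmp_path):
        write_matrix(tiny_matrix, tmp_path / "m")
        meta = pd.read_csv(tmp_path / "m" / "metadata.tsv", sep="\t", index_col=0)
        meta.drop(columns="condition").to_csv(tmp_path / "m" / "metadata.tsv", sep="\t")
        with pytest.raises(SchemaError, match="condition"):
            load_matrix(tmp_path / "m")

    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(SchemaError, match="duplicate gene"):
            make_cell_matrix(np.ones((2, 2), int), gene_ids=["g", "g"])


class TestQCFilter:
    def _matrix(self):
        # per-cell (umi, features, %mito, %ribo):
        # (1000,500,5,2) (300,100,5,2) (2000,800,12,2) (1500,600,5,11)
        # realized with 1000 gene columns: mito gene MT-1, ribo gene RPS1
        n_genes = 1000
        gene_ids = ["MT-1", "RPS1"] + [f"g{j}" for j in range(n_genes - 2)]
        rows = []
        for umi, nfeat, pmito, pribo in [(1000, 500, 5, 2), (300, 100, 5, 2),
                                         (2000, 800, 12, 2), (1500, 600, 5, 11)]:
            mito = int(round(umi * pmito / 100))
            ribo = int(round(umi * pribo / 100))
            rest = umi - mito - ribo
            row = np.zeros(n_genes, int)
            row[0], row[1] = mito, ribo
            body = nfeat - 2
            row[2:2 + body] = 1
            row[2] += rest - body
            rows.append(row)
        return make_cell_matrix(np.array(rows), gene_ids=gene_ids,
                                conditions=["case", "case", "control", "control"])

    def test_threshold_example_keeps_only_first_cell(self):
        m = self._matrix()
        t = QCThresholds(min_umi=650, min_features=200, max_features=None,
                         max_pct_mito=10, max_pct_ribo=10)
        out = qc_filter(m, t)
        assert list(out.cell_ids) == ["c0"]
        assert out.adata.uns["qc_report"]["removed_total"] == 3

    def test_extreme_thresholds_are_identity(self):
        m = self._matrix()
        out = qc_filter(m, QCThresholds(0, 0, None, 100, 100))
        assert list(out.cell_ids) == list(m.cell_ids)

    def test_matches_per_cell_brute_force(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 6, size=(50, 40))
        gene_ids = [f"MT-{j}" for j in range(4)] + [f"g{j}" for j in range(36)]
        m = make_cell_matrix(counts, gene_ids=gene_ids,
                             conditions=list(rng.choice(["case", "control"], 50)))
        t = QCThresholds(min_umi=40, min_features=10, max_features=35,
                         max_pct_mito=15, max_pct_ribo=100)
        kept = set(qc_filter(m, t).cell_ids)
        for i in range(50):
            row = counts[i]
            umi, nf = row.sum(), (row > 0).sum()
            pm = 100 * row[:4].sum() / umi if umi else 0
            expect = umi >= 40 and 10 <= nf <= 35 and pm <= 15
            assert (f"c{i}" in kept) == expect

    def test_idempotent(self):
        m = self._matrix()
        t = QCThresholds(min_umi=650, max_pct_mito=10, max_pct_ribo=10)
        once = qc_filter(m, t)
        twice = qc_filter(once, t)
        assert list(twice.cell_ids) == list(once.cell_ids)

    def test_all_cells_removed_raises(self):
        m = self._matrix()
        with pytest.raises(EmptyResultError):
            qc_filter(m, QCThresholds(min_umi=10**9))


class TestNormalizeLog:
    def test_depth_equalization(self):
        m = make_cell_matrix(np.array([[60, 40], [150, 50]]))
        out = normalize_log(m, scale_target=100)
        sums = np.expm1(out.lognorm()).sum(axis=1)
        np.testing.assert_allclose(sums, [100.0, 100.0])

    def test_single_cell_arithmetic(self):
        m = make_cell_matrix(np.array([[1, 3]]), conditions=["case"])
        out = normalize_log(m, scale_target=4)
        np.testing.assert_allclose(out.lognorm()[0], [np.log(2), np.log(4)])

    def test_preserves_shape_and_zero_pattern(self):
        rng = np.random.default_rng(0)
        m = make_cell_matrix(rng.integers(0, 3, size=(10, 8)))
        out = normalize_log(m, scale_target=1e4)
        L = out.lognorm()
        assert L.shape == m.shape
        np.testing.assert_array_equal(L == 0, m.counts() == 0)

    def test_zero_total_cell_warns_and_zeroes(self):
        m = make_cell_matrix(np.array([[0, 0], [2, 2]]))
        with pytest.warns(UserWarning, match="zero total"):
            out = normalize_log(m, scale_target=10)
        assert (out.lognorm()[0] == 0).all()

    def test_median_default_scales_to_median_depth(self):
        m = make_cell_matrix(np.array([[10, 10], [30, 30], [5, 15]]))
        out = normalize_log(m)  # median depth = 20
        np.testing.assert_allclose(np.expm1(out.lognorm()).sum(axis=1), 20.0)


class TestPercentExpression:
    def test_fractions(self):
        counts = np.zeros((20, 3), int)
        counts[:5, 0] = 2   # 25%
        counts[:, 2] = 1    # 100%
        m = make_cell_matrix(counts)
        np.testing.assert_allclose(
            percent_expression(m, ["g0", "g1", "g2"]), [25.0, 0.0, 100.0])

    def test_invariant_to_normalization_and_bounded(self, small_sim):
        m, _ = small_sim
        genes = list(m.gene_ids[:50])
        p = percent_expression(m, genes)
        assert np.all((p >= 0) & (p <= 100))
        p2 = percent_expression(normalize_log(m, 500), genes)
        np.testing.assert_array_equal(p, p2)

    def test_unknown_gene_raises(self, tiny_matrix):
        with pytest.raises(KeyError):
            percent_expression(tiny_matrix, ["nope"])


class TestSplit:
    def test_partition_and_determinism(self, small_sim):
        m, _ = small_sim
        tr1, te1 = split_train_test(m, 0.2, seed=5)
        tr2, te2 = split_train_test(m, 0.2, seed=5)
        assert list(tr1.cell_ids) == list(tr2.cell_ids)
        ids = set(tr1.cell_ids) | set(te1.cell_ids)
        assert ids == set(m.cell_ids)
        assert not set(tr1.cell_ids) & set(te1.cell_ids)
        assert abs(te1.n_cells - 0.2 * m.n_cells) <= 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_stratification_preserves_class_ratio(self, seed):
        m = make_cell_matrix(np.ones((100, 3), int),
                             conditions=["case"] * 50 + ["control"] * 50)
        tr, te = split_train_test(m, 0.2, seed=seed)
        for split, n in ((tr, 80), (te, 20)):
            counts = split.obs["condition"].value_counts()
            assert split.n_cells == n
            assert abs(counts["case"] - counts["control"]) <= 1

    def test_single_class_raises(self):
        m = make_cell_matrix(np.ones((10, 2), int), conditions=["case"] * 10)
        with pytest.raises(ValueError):
            split_train_test(m, 0.2, seed=0)
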