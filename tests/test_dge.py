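import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scexplain import core_data, synthetic
from scexplain.dge import (
    annotate_gene_set,
    log2fc,
    overlap_report,
    pan_dataset_overlap,
    prioritize,
    pseudobulk,
    significant_genes,
    wilcoxon_dge,
)

from conftest import make_cell_matrix


def _normalized(counts, **kw):
    return core_data.normalize_log(make_cell_matrix(counts, **kw), scale_target=100)


class TestLog2FC:
    def test_equal_means_zero(self):
        m = _normalized(np.array([[4, 4], [4, 4], [4, 4], [4, 4]]))
        np.testing.assert_allclose(log2fc(m, "t0"), 0.0, atol=1e-9)

    def test_doubled_case_mean_near_one(self):
        # equal library sizes so depth normalization preserves the 2x ratio
        counts = np.array([[40, 40, 20], [40, 40, 20], [20, 40, 40], [20, 40, 40]])
        m = _normalized(counts)
        fc = log2fc(m, "t0")
        assert fc["g0"] == pytest.approx(1.0, abs=0.05)
        assert abs(fc["g1"]) < 0.05

    def test_matches_hand_computed_ratio(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 12, size=(10, 3))
        m = _normalized(counts)
        fc = log2fc(m, "t0", pseudocount=1e-9)
        E = np.expm1(m.lognorm())
        case = m.labels() == "case"
        manual = np.log2((E[case].mean(0) + 1e-9) / (E[~case].mean(0) + 1e-9))
        np.testing.assert_allclose(fc.to_numpy(), manual)

    def test_absent_cell_type_raises(self, tiny_matrix):
        m = core_data.normalize_log(tiny_matrix, 10)
        with pytest.raises(ValueError):
            log2fc(m, "nope")


class TestWilcoxonDGE:
    def test_min_pct_filter_excludes_sparse_genes(self):
        counts = np.zeros((400, 2), int)
        counts[0, 0] = 1           # 0.5% of case cells
        counts[200, 0] = 1         # 0.5% of control cells
        counts[:, 1] = 3           # 100%
        m = _normalized(counts, conditions=["case"] * 200 + ["control"] * 200)
        out = wilcoxon_dge(m, "t0", min_pct=1.0)
        assert "g0" not in out.index and "g1" in out.index

    def test_identical_values_p_one(self):
        counts = np.tile([3, 5], (30, 1))
        m = _normalized(counts)
        out = wilcoxon_dge(m, "t0")
        assert (out["p"] == 1.0).all()

    def test_matches_exact_rank_sum_enumeration(self):
        # tiny two-group comparison vs exhaustive permutation of group labels
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 60, size=(10, 2))  # distinct-ish values
        while len(np.unique(counts[:, 0])) < 10 or len(np.unique(counts[:, 1])) < 10:
            counts = rng.integers(1, 60, size=(10, 2))
        m = _normalized(counts, conditions=["case"] * 5 + ["control"] * 5)
        out = wilcoxon_dge(m, "t0", min_pct=0.0)
        L = m.lognorm()
        for j, g in enumerate(["g0", "g1"]):
            vals = L[:, j]
            obs = stats.rankdata(vals)[:5].sum()
            null = [sum(sorted(stats.rankdata(vals)[list(c)]))
                    for c in itertools.combinations(range(10), 5)]
            null = np.array([stats.rankdata(vals)[list(c)].sum()
                             for c in itertools.combinations(range(10), 5)])
            mu = null.mean()
            p_exact = np.mean(np.abs(null - mu) >= abs(obs - mu) - 1e-12)
            assert out.loc[g, "p"] == pytest.approx(p_exact, abs=1e-9)

    def test_bonferroni_over_tested_genes(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 30, size=(40, 5))
        m = _normalized(counts)
        out = wilcoxon_dge(m, "t0", min_pct=0.0)
        np.testing.assert_allclose(out["p_adj"],
                                   np.minimum(1.0, out["p"] * len(out)))

    def test_null_p_values_uniform(self):
        # condition labels randomized at the cell level -> exchangeable null
        cfg = synthetic.SimulationConfig(
            n_case_subjects=3, n_control_subjects=3, cells_per_subject=50,
            n_genes=400, signal_genes={}, seed=3)
        m, _ = synthetic.simulate_counts(cfg)
        m = synthetic.randomize_labels(m, 1.0, seed=3)
        m = core_data.normalize_log(m)
        out = wilcoxon_dge(m, "DaNeurons", min_pct=1.0)
        ks = stats.kstest(out["p"], "uniform")
        assert ks.pvalue > 0.01


class TestPseudobulk:
    def test_two_cells_one_subject_sums(self):
        m = make_cell_matrix(np.array([[1, 2], [3, 4]]),
                             subjects=["s1", "s1"], conditions=["case", "case"])
        pb = pseudobulk(m, "t0")
        assert pb.loc["s1", "g0"] == 4 and pb.loc["s1", "g1"] == 6
        assert pb.loc["s1", "condition"] == "case"

    def test_one_cell_per_subject_identity(self, tiny_matrix):
        m = make_cell_matrix(np.arange(8).reshape(4, 2),
                             subjects=[f"s{i}" for i in range(4)])
        pb = pseudobulk(m, "t0")
        np.testing.assert_array_equal(
            pb[["g0", "g1"]].to_numpy(), np.arange(8).reshape(4, 2))

    def test_conserves_gene_totals(self, small_sim):
        m, _ = small_sim
        pb = pseudobulk(m, "DaNeurons")
        np.testing.assert_array_equal(
            pb.drop(columns="condition").sum(axis=0).to_numpy(),
            m.counts().sum(axis=0))


class TestOverlap:
    def test_jaccard_examples(self):
        assert pan_dataset_overlap({"a", "b", "c"}, {"b", "c", "d"}) == 0.5
        assert pan_dataset_overlap({"a"}, {"a"}) == 1.0
        assert pan_dataset_overlap({"a"}, {"b"}) == 0.0

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = set(rng.choice(50, rng.integers(1, 20), replace=False))
            b = set(rng.choice(50, rng.integers(1, 20), replace=False))
            j1, j2 = pan_dataset_overlap(a, b), pan_dataset_overlap(b, a)
            assert j1 == j2 and 0.0 <= j1 <= 1.0

    def test_per_set_proportions(self):
        rep = overlap_report({"a", "b"}, {"b", "c", "d"})
        assert rep["share_of_a"] == 0.5
        assert rep["share_of_b"] == pytest.approx(1 / 3)

    def test_empty_sets_error(self):
        with pytest.raises(ValueError):
            pan_dataset_overlap(set(), set())


class TestPrioritize:
    def _inputs(self):
        optimal = {"astro": ["gA", "gB", "gC", "gD"],
                   "micro": ["gB", "gX"], "oligo": ["gB"]}
        z = {"astro": pd.Series({"gA": 6.0, "gB": 2.5, "gC": 4.0, "gD": 6.0}),
             "micro": pd.Series({"gB": 2.2, "gX": 1.5}),
             "oligo": pd.Series({"gB": 2.1})}
        fc = {ct: pd.Series(0.3, index=pd.Index(genes))
              for ct, genes in optimal.items()}
        fc["astro"]["gB"] = -0.3
        return optimal, z, fc

    def test_rules(self):
        optimal, z, fc = self._inputs()
        out = prioritize(optimal, z, fc).set_index(["gene_id", "cell_type"])
        # gA: Z=6 > 5, |FC|=0.3 -> kept, single-cell-type
        assert out.loc[("gA", "astro"), "category"] == "single-cell-type"
        # gB: Z=2.5 in astro, in 3 sets, FC=-0.3 -> kept, multi
        assert out.loc[("gB", "astro"), "category"] == "multi-cell-type"
        # gC: Z=4, single set -> dropped
        assert ("gC", "astro") not in out.index
        # gX: Z=1.5 -> dropped
        assert ("gX", "micro") not in out.index

    def test_flagged_genes_dropped_unless_gwas(self):
        optimal, z, fc = self._inputs()
        ann = pd.DataFrame({
            "gene_id": ["gA", "gD"],
            "mitochondrial": [True, True],
            "ribosomal": [False, False], "sex_linked": [False, False],
            "non_coding": [False, False], "gwas_pd": [False, True],
        })
        out = prioritize(optimal, z, fc, ann)
        assert "gA" not in set(out["gene_id"])   # flagged, not GWAS
        assert "gD" in set(out["gene_id"])       # flagged but GWAS-retained

    def test_monotone_in_lfc_threshold(self):
        optimal, z, fc = self._inputs()
        loose = prioritize(optimal, z, fc, lfc_min=0.25)
        tight = prioritize(optimal, z, fc, lfc_min=0.5)
        assert set(map(tuple, tight[["gene_id", "cell_type"]].to_numpy())) <= \
            set(map(tuple, loose[["gene_id", "cell_type"]].to_numpy()))


class TestAnnotateAndSignificance:
    def test_join_semantics(self):
        genes = ["g1", "g2", "g3"]
        tables = {"gwas": pd.DataFrame({"gene_id": ["g1", "g3"],
                                        "p": [1e-9, 1e-7]})}
        out = annotate_gene_set(genes, tables)
        assert len(out) == 3
        assert out[out["gene_id"] == "g2"]["source"].isna().all()
        # empty table: pass-through
        out2 = annotate_gene_set(genes, {"x": pd.DataFrame(columns=["gene_id"])})
        assert len(out2) == 3 and out2["source"].isna().all()
        # duplicate annotation rows concatenate with source labels
        dup = {"a": tables["gwas"], "b": tables["gwas"]}
        out3 = annotate_gene_set(genes, dup)
        assert (out3["gene_id"] == "g1").sum() == 2

    def test_deg_rule(self):
        df = pd.DataFrame({
            "log2fc": [1.5, 0.5, -1.5, 2.0],
            "p_adj": [0.01, 0.01, 0.2, 0.04],
        }, index=["a", "b", "c", "d"])
        assert significant_genes(df) == {"a", "d"}
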