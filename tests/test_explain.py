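import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scexplain import core_data
from scexplain.classify import ClassifierSpec, run_pipeline
from scexplain.explain import (
    BackgroundStats,
    LimeConfig,
    aggregate_condition,
    aggregate_subject,
    explain_cell,
    explain_correct_case_cells,
    importance_correlation,
    importance_table,
    select_correct_case_cells,
    weight_and_zscore,
)

from conftest import make_cell_matrix


class SigmoidLinear:
    """Deterministic probabilistic classifier: P(case) = sigmoid(w.x + b)."""

    classes_ = np.array(["control", "case"], dtype=object)

    def __init__(self, w, b=0.0):
        self.w = np.asarray(w, dtype=float)
        self.b = b
        self.n_features_in_ = self.w.size

    def predict_proba(self, X):
        p = 1.0 / (1.0 + np.exp(-(np.asarray(X) @ self.w + self.b)))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return np.where(self.predict_proba(X)[:, 1] > 0.5, "case", "control")


def _background(rng, n=400, F=5, stds=None):
    X = rng.normal(0, 1, size=(n, F))
    if stds is not None:
        X *= np.asarray(stds)
    return X, BackgroundStats.from_matrix(X, [f"g{j}" for j in range(F)])


class TestExplainCell:
    def test_linear_model_signs_and_ranking(self):
        rng = np.random.default_rng(0)
        X, bg = _background(rng, F=2)
        model = SigmoidLinear([2.0, -1.0])
        cfg = LimeConfig(n_perturbations=3000, discretize=False, seed=0)
        e = explain_cell(model, np.array([0.1, 0.1]), bg, cfg)
        assert abs(e.importances[0]) > abs(e.importances[1])
        assert e.importances[0] > 0 and e.importances[1] < 0

    def test_zero_variance_feature_gets_zero_importance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, 3))
        X[:, 2] = 1.5  # constant feature
        bg = BackgroundStats.from_matrix(X, ["a", "b", "c"])
        model = SigmoidLinear([1.0, 1.0, 1.0])
        for disc in (True, False):
            cfg = LimeConfig(n_perturbations=500, discretize=disc, seed=1)
            e = explain_cell(model, np.array([0.0, 0.0, 1.5]), bg, cfg)
            assert e.importances[2] == pytest.approx(0.0, abs=1e-9)

    def test_same_seed_identical(self):
        rng = np.random.default_rng(2)
        X, bg = _background(rng)
        model = SigmoidLinear(np.arange(5) - 2.0)
        cfg = LimeConfig(n_perturbations=400, seed=7)
        x = X[0]
        e1 = explain_cell(model, x, bg, cfg)
        e2 = explain_cell(model, x, bg, cfg)
        np.testing.assert_array_equal(e1.importances, e2.importances)

    def test_constant_model_yields_zero_explanation(self):
        rng = np.random.default_rng(3)
        X, bg = _background(rng)

        class Flat(SigmoidLinear):
            def predict_proba(self, X):
                return np.tile([0.5, 0.5], (len(X), 1))

        with pytest.warns(UserWarning, match="constant"):
            e = explain_cell(Flat(np.zeros(5)), X[0], bg,
                             LimeConfig(n_perturbations=200, seed=0))
        assert (e.importances == 0).all()

    def test_linear_fidelity_rank_correlation(self):
        # spec invariant: rank corr(mean |explanation|, |beta|*scale) >= 0.9
        rng = np.random.default_rng(4)
        F = 20
        stds = rng.uniform(0.5, 2.0, size=F)
        X, bg = _background(rng, n=600, F=F, stds=stds)
        beta = rng.normal(0, 1, size=F)
        model = SigmoidLinear(beta * 0.3)
        cfg = LimeConfig(n_perturbations=5000, discretize=False, seed=4)
        mean_abs = np.mean(
            [np.abs(explain_cell(model, X[i], bg, cfg).importances)
             for i in range(10)], axis=0)
        rho = stats.spearmanr(mean_abs, np.abs(beta * 0.3) * stds).statistic
        assert rho >= 0.9


class TestSelectCells:
    def _eval(self):
        from scexplain.classify import ConfusionCounts, EvaluationResult
        cells = [f"c{i}" for i in range(6)]
        preds = np.array([["case", "control", "case", "control", "case", "case"]],
                         dtype=object)
        truth = np.array(["case", "case", "case", "control", "control", "case"],
                         dtype=object)
        meta = pd.DataFrame({
            "condition": truth,
            "subject_id": ["s1", "s1", "s2", "s3", "s3", "s2"],
        }, index=cells)
        res = EvaluationResult(
            confusions=[ConfusionCounts(1, 1, 1, 1)],
            balanced_accuracies=np.array([0.5]),
            predictions=preds, correct=preds == truth[None, :],
            cell_ids=cells)
        return res, meta

    def test_hand_built_table(self):
        res, meta = self._eval()
        out = select_correct_case_cells(res, meta)
        # case cells: c0,c1,c2,c5; correct predictions: c0,c2,c5 (c1 wrong)
        assert out[0] == ["c0", "c2", "c5"]

    def test_all_wrong_is_empty_with_warning(self):
        res, meta = self._eval()
        res.correct[:] = False
        with pytest.warns(UserWarning, match="no correctly classified"):
            out = select_correct_case_cells(res, meta)
        assert out[0] == []


class TestAggregation:
    def test_subject_mean_absolute(self):
        assert aggregate_subject(np.array([[0.2], [-0.4]]))[0] == pytest.approx(0.3)
        assert aggregate_subject(np.zeros((3, 2))).tolist() == [0.0, 0.0]
        np.testing.assert_allclose(aggregate_subject(np.array([[-0.7, 0.1]])),
                                   [0.7, 0.1])

    def test_condition_mean_equal_weighting(self):
        F = {"s1": np.array([0.3]), "s2": np.array([0.1])}
        assert aggregate_condition(F)[0] == pytest.approx(0.2)
        assert aggregate_condition({"s": np.array([0.5])})[0] == 0.5

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(8, 4))
        np.testing.assert_allclose(aggregate_subject(A),
                                   aggregate_subject(A[::-1]))
        vecs = [rng.random(4) for _ in range(5)]
        np.testing.assert_allclose(aggregate_condition(vecs),
                                   aggregate_condition(vecs[::-1]))


class TestWeightAndZscore:
    def test_normalized_percent_expression(self):
        t = weight_and_zscore(np.array([0.2, 0.2]), np.array([25.0, 75.0]),
                              ["a", "b"])
        np.testing.assert_allclose(t["N"], [0.25, 0.75])
        assert t.loc["a", "W"] == pytest.approx(0.25 * 0.2)

    def test_population_sigma_zscores(self):
        t = weight_and_zscore(np.array([1.0, 2.0, 3.0]),
                              np.array([100.0, 100.0, 100.0]), list("abc"))
        np.testing.assert_allclose(
            t["Z"], [-1.224744871391589, 0.0, 1.224744871391589], atol=1e-12)

    def test_invariants_sum_and_standardization(self):
        rng = np.random.default_rng(1)
        F = rng.exponential(0.1, 50)
        P = rng.uniform(0, 100, 50)
        t = weight_and_zscore(F, P, [f"g{i}" for i in range(50)])
        assert t["N"].sum() == pytest.approx(1.0, abs=1e-9)
        assert t["Z"].mean() == pytest.approx(0.0, abs=1e-9)
        assert t["Z"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)
        assert (t["F"] >= 0).all()

    def test_never_expressed_gene_flagged_with_zero_weight(self):
        t = weight_and_zscore(np.array([0.5, 0.5, 0.1]),
                              np.array([0.0, 50.0, 25.0]), list("abc"))
        assert bool(t.loc["a", "never_expressed"])
        assert t.loc["a", "W"] == 0.0

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(ValueError, match="sd"):
            weight_and_zscore(np.array([0.5, 0.5]), np.array([50.0, 50.0]),
                              ["a", "b"])


class TestImportanceCorrelation:
    def _table(self, z):
        return pd.DataFrame({"Z": z}, index=[f"g{i}" for i in range(len(z))])

    def test_identical_and_negated(self):
        a = self._table([1.0, -0.5, 2.0, 0.3])
        r, _ = importance_correlation(a, a)
        assert r == pytest.approx(1.0)
        b = self._table([-1.0, 0.5, -2.0, -0.3])
        r, _ = importance_correlation(a, b)
        assert r == pytest.approx(-1.0)

    def test_independent_tables_uncorrelated(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = self._table(rng.normal(size=1000))
            b = self._table(rng.normal(size=1000))
            r, _ = importance_correlation(a, b)
            hits += abs(r) < 0.1
        assert hits >= 9

    def test_too_few_shared_genes(self):
        a = self._table([1.0, 2.0])
        with pytest.raises(ValueError):
            importance_correlation(a, a)


class TestPipelineRecovery:
    def test_planted_genes_rank_high(self, small_sim):
        """End-to-end: most planted genes exceed importance Z = 1."""
        m, truth = small_sim
        spec = ClassifierSpec(family="lr", seed=7)
        genes = list(m.gene_ids)
        models, res, train, test = run_pipeline(m, genes, spec, seed=7)
        bg = BackgroundStats.from_matrix(train.lognorm(genes), genes)
        cfg = LimeConfig(n_perturbations=500, seed=7, max_cells_per_subject=10)
        tbl = importance_table(models, res, test.lognorm(genes), test.obs,
                               bg, cfg, m)
        assert tbl["N"].sum() == pytest.approx(1.0, abs=1e-9)
        assert tbl["Z"].mean() == pytest.approx(0.0, abs=1e-9)
        planted = truth.genes("DaNeurons")
        frac = (tbl.loc[planted, "Z"] > 1.0).mean()
        assert frac >= 0.7
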