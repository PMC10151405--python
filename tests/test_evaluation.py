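"""CV engines: reproducible paired splits, degenerate-case equalities,
win fractions, correlation report."""

import numpy as np
import pandas as pd
import pytest

from grainpred import McmcSpec, ModelSpec, OmicsMatrix, compute_kernel
from grainpred.evaluation import (CVDesign, CVResult, PredictorSet,
                                  benjamini_hochberg, correlation_report,
                                  pairwise_win_fraction, run_classification_cv,
                                  run_cross_condition, run_loso_cv,
                                  run_prediction_cv, run_subset_experiment)

from conftest import standardized_matrix

RF_SMALL = ModelSpec("random_forest",
                     grid={"n_estimators": [60], "max_features": ["sqrt"]})


def _shifted_pair(rng, n=60, p=12, shift=3.0):
    ids = np.array([f"L{i}" for i in range(n)])
    feats = np.array([f"m{j}" for j in range(p)])
    base = rng.standard_normal((n, p))
    hnt = rng.standard_normal((n, p))
    hnt[:, : p // 2] += shift
    return (OmicsMatrix(base, ids, feats, "metabolite"),
            OmicsMatrix(hnt, ids, feats, "metabolite"))


class TestSplits:
    def test_split_depends_only_on_seed_and_repeat(self):
        d1 = CVDesign(n_repeats=5, seed=3)
        d2 = CVDesign(n_repeats=99, seed=3)
        tr1, te1 = d1.split(50, 2)
        tr2, te2 = d2.split(50, 2)
        assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)
        assert len(tr1) == 40 and len(te1) == 10
        assert not np.intersect1d(tr1, te1).size

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            CVDesign(train_frac=1.0)
        with pytest.raises(ValueError):
            CVDesign(n_repeats=0)


class TestClassificationCV:
    def test_strong_shift_classified_and_result_shape(self):
        rng = np.random.default_rng(0)
        mc, mh = _shifted_pair(rng, shift=4.0)
        res = run_classification_cv(mc, mh, {"rf": RF_SMALL},
                                    CVDesign(n_repeats=4, seed=1))
        acc = res["rf"]["accuracy"]
        assert len(acc.per_repeat) == 4
        assert acc.mean > 0.9
        assert set(res["rf"]) == {"accuracy", "f1", "auc"}

    def test_tiny_condition_rejected(self):
        rng = np.random.default_rng(1)
        mc, mh = _shifted_pair(rng, n=4)
        with pytest.raises(ValueError):
            run_classification_cv(mc, mh, {"rf": RF_SMALL}, CVDesign(seed=0))

    def test_permuted_labels_centre_at_chance(self):
        """Metabolites with no condition signal: accuracy ~ 0.5."""
        rng = np.random.default_rng(2)
        mc, mh = _shifted_pair(rng, n=80, shift=0.0)
        res = run_classification_cv(mc, mh, {"rf": RF_SMALL},
                                    CVDesign(n_repeats=8, seed=2))
        assert res["rf"]["accuracy"].mean == pytest.approx(0.5, abs=0.12)


class TestSubsetExperiment:
    def test_full_size_subset_equals_full_profile_run(self):
        rng = np.random.default_rng(3)
        mc, mh = _shifted_pair(rng, p=8, shift=2.0)
        design = CVDesign(n_repeats=3, seed=4)
        full = run_classification_cv(mc, mh, {"rf": RF_SMALL}, design)
        sub = run_subset_experiment(mc, mh, {"rf": RF_SMALL}, design,
                                    sizes=(8,), n_resample=2)
        assert np.allclose(sub["accuracy"],
                           full["rf"]["accuracy"].mean)

    def test_oversized_subset_rejected(self):
        rng = np.random.default_rng(4)
        mc, mh = _shifted_pair(rng, p=8)
        with pytest.raises(ValueError):
            run_subset_experiment(mc, mh, {"rf": RF_SMALL}, CVDesign(seed=0),
                                  sizes=(9,))


class TestPredictionCV:
    def _pred_data(self, rng, n=60, h2=0.6):
        W = standardized_matrix(rng, n, 30)
        K = compute_kernel(W)
        L = np.linalg.cholesky(K.values + 1e-8 * np.eye(n))
        u = np.sqrt(h2) * (L @ rng.standard_normal(n))
        y = u + np.sqrt(1 - h2) * rng.standard_normal(n)
        Wm = standardized_matrix(rng, n, 15, "metabolite")
        pset = PredictorSet(metabolites=Wm, markers=W, G=K,
                            M=compute_kernel(Wm),
                            mcmc=McmcSpec(800, 300, 2))
        return y, pset

    def test_null_phenotype_predicts_nothing(self):
        rng = np.random.default_rng(5)
        _, pset = self._pred_data(rng)
        y = rng.standard_normal(60)
        res = run_prediction_cv(y, {"gblup": "gblup", "mols": "mols"},
                                pset, CVDesign(n_repeats=6, seed=5))
        for r in res.values():
            assert abs(r.mean) < 0.25

    def test_genetic_signal_predicted_by_gblup(self):
        rng = np.random.default_rng(6)
        y, pset = self._pred_data(rng)
        res = run_prediction_cv(y, {"gblup": "gblup"}, pset,
                                CVDesign(n_repeats=8, seed=6))
        assert res["gblup"].mean > 0.4

    def test_models_share_paired_splits(self):
        rng = np.random.default_rng(7)
        y, pset = self._pred_data(rng)
        r1 = run_prediction_cv(y, {"a": "mols"}, pset, CVDesign(n_repeats=4, seed=8))
        r2 = run_prediction_cv(y, {"b": "mols"}, pset, CVDesign(n_repeats=4, seed=8))
        assert np.allclose(r1["a"].per_repeat, r2["b"].per_repeat)


class TestCrossCondition:
    def test_identical_matrices_transfer_equals_within(self):
        rng = np.random.default_rng(9)
        Wm = standardized_matrix(rng, 50, 10, "metabolite")
        y = Wm.values @ rng.standard_normal(10) + rng.standard_normal(50)
        res = run_cross_condition(y, Wm, Wm, "mols", McmcSpec(400, 100, 2),
                                  CVDesign(n_repeats=4, seed=10))
        assert np.allclose(res["within"].per_repeat, res["transfer"].per_repeat)

    def test_shifted_source_degrades_transfer(self):
        rng = np.random.default_rng(10)
        n, p = 80, 10
        Wt = standardized_matrix(rng, n, p, "metabolite")
        y = Wt.values @ rng.standard_normal(p) * 0.6 + rng.standard_normal(n) * 0.5
        noise = rng.standard_normal((n, p))
        source = OmicsMatrix(0.5 * Wt.values + np.sqrt(0.75) * noise,
                             Wt.line_ids, Wt.feature_ids, "metabolite", False)
        source = OmicsMatrix((source.values - source.values.mean(0))
                             / source.values.std(0), Wt.line_ids,
                             Wt.feature_ids, "metabolite", True)
        res = run_cross_condition(y, source, Wt, "mols", McmcSpec(400, 100, 2),
                                  CVDesign(n_repeats=8, seed=11))
        assert res["transfer"].mean < res["within"].mean


class TestLoso:
    def test_duplicate_populations_predict_each_other(self):
        rng = np.random.default_rng(12)
        n = 40
        W = standardized_matrix(rng, n, 10, "metabolite")
        y = W.values @ rng.standard_normal(10)
        labels = np.array(["p1"] * (n // 2) + ["p2"] * (n // 2))
        pset = PredictorSet(metabolites=W)
        out = run_loso_cv(y, "mols", pset, labels)
        assert set(out["subpop"]) == {"p1", "p2"}
        assert (out["pearson"] > 0.9).all()

    def test_single_population_rejected(self):
        rng = np.random.default_rng(13)
        W = standardized_matrix(rng, 10, 3)
        with pytest.raises(ValueError):
            run_loso_cv(rng.standard_normal(10), "mols",
                        PredictorSet(metabolites=W), ["p1"] * 10)


class TestComparisons:
    def test_win_fraction_degenerate_cases(self):
        a = CVResult("a", "pearson", np.array([0.5, 0.6, 0.7]))
        b = CVResult("b", "pearson", np.array([0.5, 0.6, 0.7]))
        out = pairwise_win_fraction(a, b)
        assert out["win_fraction"] == 0.0 and out["tie_fraction"] == 1.0
        c = CVResult("c", "pearson", a.per_repeat + 0.01)
        assert pairwise_win_fraction(c, a)["win_fraction"] == 1.0

    def test_win_fraction_matches_brute_count(self):
        rng = np.random.default_rng(14)
        av, bv = rng.random(20), rng.random(20)
        out = pairwise_win_fraction(CVResult("a", "m", av), CVResult("b", "m", bv))
        assert out["win_fraction"] == pytest.approx(
            sum(x > y for x, y in zip(av, bv)) / 20)

    def test_unpaired_results_rejected(self):
        with pytest.raises(ValueError):
            pairwise_win_fraction(CVResult("a", "m", np.zeros(3)),
                                  CVResult("b", "m", np.zeros(4)))

    def test_benjamini_hochberg_monotone_and_bounded(self):
        p = np.array([0.001, 0.02, 0.04, 0.8])
        adj = benjamini_hochberg(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1).all()
        assert np.allclose(adj, [0.004, 0.04, 0.0533333333, 0.8])


class TestCorrelationReport:
    def test_duplicated_column_flagged_with_r_one(self):
        rng = np.random.default_rng(15)
        X = rng.standard_normal((50, 3))
        X[:, 1] = X[:, 0]
        mat = OmicsMatrix(X, np.array([f"L{i}" for i in range(50)]),
                          np.array(["a", "b", "c"]), "metabolite")
        out = correlation_report(mat, pd.DataFrame({"width": X[:, 2]}))
        pairs = out["metabolite_pairs"]
        assert len(pairs) == 1
        assert pairs["r"].iloc[0] == pytest.approx(1.0)

    def test_independent_columns_produce_no_flags(self):
        rng = np.random.default_rng(16)
        X = rng.standard_normal((190, 20))
        mat = OmicsMatrix(X, np.array([f"L{i}" for i in range(190)]),
                          np.array([f"m{j}" for j in range(20)]), "metabolite")
        out = correlation_report(mat, pd.DataFrame())
        assert out["metabolite_pairs"].empty

    def test_correlated_trait_flagged_with_direction(self):
        rng = np.random.default_rng(17)
        X = rng.standard_normal((100, 2))
        y = -X[:, 0] + 0.5 * rng.standard_normal(100)
        mat = OmicsMatrix(X, np.array([f"L{i}" for i in range(100)]),
                          np.array(["m0", "m1"]), "metabolite")
        out = correlation_report(mat, pd.DataFrame({"width": y}))
        mt = out["metabolite_trait"]
        assert ("m0" in set(mt["feature"])
                and mt[mt.feature == "m0"]["direction"].iloc[0] == "negative")
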