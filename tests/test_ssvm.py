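import numpy as np
import pandas as pd
import pytest

from conftest import make_clinical
from netprog.ssvm import (
    CVGrid,
    comparable_pairs,
    fit_ssvm,
    grid_search_cv,
    median_stratify,
    predict_risk_scores,
)
from netprog.survstats import concordance_index


def ranked_dataset(n=30, n_genes=5, seed=0, censor=0.3):
    """Expression with one informative gene inversely tied to survival."""
    rng = np.random.default_rng(seed)
    risk = rng.normal(size=n)
    X = pd.DataFrame(
        rng.normal(size=(n_genes, n)),
        index=[f"G{k}" for k in range(n_genes)],
        columns=[f"S{i:03d}" for i in range(n)],
    )
    X.loc["G0"] = risk + 0.1 * rng.normal(size=n)
    t = np.exp(-risk) * rng.exponential(1.0, size=n) + 0.01
    e = (rng.uniform(size=n) > censor).astype(int)
    if e.sum() < 2:
        e[:2] = 1
    clin = make_clinical(t, e)
    return X, clin


class TestComparablePairs:
    def test_all_events_full_enumeration(self):
        clin = make_clinical([1.0, 2.0, 3.0], [1, 1, 1])
        assert set(comparable_pairs(clin["time"], clin["event"])) == {
            (0, 1), (0, 2), (1, 2)
        }

    def test_censored_sample_forms_no_pair_as_earlier_member(self):
        clin = make_clinical([1.0, 2.0, 3.0], [1, 0, 1])
        assert set(comparable_pairs(clin["time"], clin["event"])) == {(0, 1), (0, 2)}

    def test_all_censored_empty(self):
        clin = make_clinical([1.0, 2.0], [0, 0])
        assert comparable_pairs(clin["time"], clin["event"]) == []


class TestFit:
    def test_separable_ranking_perfect_training_cindex(self):
        # single gene equal to negative survival time, no censoring
        n = 20
        t = np.linspace(1, 20, n)
        X = pd.DataFrame([-t], index=["G0"], columns=[f"S{i:03d}" for i in range(n)])
        clin = make_clinical(t, np.ones(n, dtype=int))
        model = fit_ssvm(X, clin, c=10.0, sigma=5.0)
        ci = concordance_index(model.train_scores, clin["time"], clin["event"])
        assert ci == 1.0

    def test_higher_score_means_higher_risk(self):
        X, clin = ranked_dataset(seed=1)
        model = fit_ssvm(X, clin, c=1.0, sigma=3.0)
        ci = concordance_index(model.train_scores, clin["time"], clin["event"])
        assert ci > 0.8  # oriented toward risk, not survival

    def test_no_comparable_pairs_errors(self):
        X = pd.DataFrame(np.eye(2), index=["G0", "G1"], columns=["S0", "S1"])
        clin = make_clinical([1.0, 2.0], [0, 0], prefix="S")
        clin.index = ["S0", "S1"]
        with pytest.raises(ValueError, match="comparable"):
            fit_ssvm(X, clin, c=1.0, sigma=1.0)

    def test_matches_sksurv_kernel_ranking_svm(self):
        # same objective family in scikit-survival: independent cross-check
        sksurv_svm = pytest.importorskip("sksurv.svm")
        from sksurv.util import Surv

        import warnings

        X, clin = ranked_dataset(n=40, seed=2)
        c, sigma = 1.0, 3.0
        model = fit_ssvm(X, clin, c=c, sigma=sigma)
        # sksurv objective is (1/2)||w||^2 + (alpha/2) * sum sq-hinge, so
        # alpha = 2c matches our pairwise cost
        ref = sksurv_svm.FastKernelSurvivalSVM(
            alpha=2.0 * c, rank_ratio=1.0, kernel="rbf",
            gamma=1.0 / (2 * sigma**2), max_iter=1000, tol=1e-9, random_state=0,
        )
        y = Surv.from_arrays(event=clin["event"].astype(bool), time=clin["time"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref.fit(X.to_numpy().T, y)
        ref_scores = ref.predict(X.to_numpy().T)
        ours = concordance_index(model.train_scores, clin["time"], clin["event"])
        theirs = concordance_index(ref_scores, clin["time"], clin["event"])
        assert ours == pytest.approx(theirs, abs=0.03)
        assert np.corrcoef(model.train_scores, ref_scores)[0, 1] > 0.99

    def test_serialization_round_trip(self, tmp_path):
        X, clin = ranked_dataset(seed=3)
        model = fit_ssvm(X, clin, c=1.0, sigma=2.0)
        p = tmp_path / "model.npz"
        model.to_npz(p)
        from netprog.ssvm import SSVMModel

        back = SSVMModel.from_npz(p)
        assert back.genes == model.genes
        scores = predict_risk_scores(back, X)
        assert np.allclose(scores.to_numpy(), model.train_scores, atol=1e-10)


class TestPredict:
    def test_training_scores_reproduced(self):
        X, clin = ranked_dataset(seed=4)
        model = fit_ssvm(X, clin, c=1.0, sigma=2.0)
        scores = predict_risk_scores(model, X)
        assert np.allclose(scores.to_numpy(), model.train_scores, atol=1e-10)

    def test_identical_samples_identical_scores(self):
        X, clin = ranked_dataset(seed=5)
        model = fit_ssvm(X, clin, c=1.0, sigma=2.0)
        X_test = pd.DataFrame(
            np.column_stack([X.iloc[:, 0], X.iloc[:, 0]]),
            index=X.index, columns=["T0", "T1"],
        )
        s = predict_risk_scores(model, X_test)
        assert s["T0"] == s["T1"]

    def test_all_zero_gene_leaves_scores_unchanged(self):
        # a gene that is 0 everywhere contributes nothing to kernel distances
        X, clin = ranked_dataset(seed=6)
        X_aug = pd.concat([X, pd.DataFrame(0.0, index=["GZ"], columns=X.columns)])
        m1 = fit_ssvm(X, clin, c=1.0, sigma=2.0)
        m2 = fit_ssvm(X_aug, clin, c=1.0, sigma=2.0)
        # exact in exact arithmetic; in practice limited by the solver's
        # stopping tolerance, not by any kernel-distance difference
        assert np.allclose(m1.train_scores, m2.train_scores, atol=1e-4)

    def test_missing_genes_imputed_with_warning(self):
        X, clin = ranked_dataset(seed=7)
        model = fit_ssvm(X, clin, c=1.0, sigma=2.0)
        with pytest.warns(UserWarning, match="imputed"):
            s = predict_risk_scores(model, X.drop(index=["G3"]))
        assert np.all(np.isfinite(s))

    def test_no_gene_overlap_errors(self):
        X, clin = ranked_dataset(seed=8)
        model = fit_ssvm(X, clin, c=1.0, sigma=2.0)
        bad = pd.DataFrame(np.zeros((2, 3)), index=["X1", "X2"],
                           columns=["T0", "T1", "T2"])
        with pytest.raises(ValueError, match="overlap"):
            predict_risk_scores(model, bad)


class TestMedianStratify:
    def test_even_split(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        g = median_stratify(s)
        assert list(g) == ["low-risk", "low-risk", "high-risk", "high-risk"]

    def test_odd_n_median_goes_low(self):
        g = median_stratify(pd.Series([1.0, 2.0, 3.0], index=list("abc")))
        assert g["b"] == "low-risk"
        assert g["c"] == "high-risk"

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        s = pd.Series(rng.normal(size=11), index=[f"s{i}" for i in range(11)])
        g1 = median_stratify(s)
        g2 = median_stratify(np.exp(3 * s))
        assert (g1 == g2).all()

    def test_constant_scores_error(self):
        with pytest.raises(ValueError):
            median_stratify(pd.Series([1.0, 1.0, 1.0]))


class TestGridSearch:
    def test_single_cell_grid_returns_that_cell(self):
        X, clin = ranked_dataset(n=40, seed=10)
        grid = CVGrid(c_values=(1.0,), sigma_values=(2.0,), folds=3, repeats=1)
        grid, model = grid_search_cv(X, clin, grid=grid, seed=0)
        assert grid.selected == (1.0, 2.0)
        assert (model.c, model.sigma) == (1.0, 2.0)

    def test_reproducible_given_seed(self):
        X, clin = ranked_dataset(n=40, seed=11)
        g = CVGrid(c_values=(0.1, 10.0), sigma_values=(1.0, 5.0), folds=3, repeats=2)
        g1, m1 = grid_search_cv(X, clin, grid=g, seed=5)
        g2, m2 = grid_search_cv(
            X, clin, grid=CVGrid(c_values=(0.1, 10.0), sigma_values=(1.0, 5.0),
                                 folds=3, repeats=2), seed=5)
        assert g1.selected == g2.selected
        assert np.array_equal(g1.mean_cindex, g2.mean_cindex)
        assert np.allclose(m1.alpha, m2.alpha)

    def test_tie_break_prefers_small_c_then_sigma(self):
        grid = CVGrid(c_values=(0.1, 10.0), sigma_values=(1.0, 5.0), folds=2, repeats=1)
        grid.mean_cindex = np.array([[0.6, 0.7], [0.7, 0.7]])
        # emulate the selection rule on a hand-built table
        best, sel = -np.inf, None
        for ci, c in enumerate(grid.c_values):
            for si, s in enumerate(grid.sigma_values):
                if grid.mean_cindex[ci, si] > best:
                    best, sel = grid.mean_cindex[ci, si], (c, s)
        assert sel == (0.1, 5.0)

    def test_full_grid_is_121_cells(self):
        grid = CVGrid()
        assert grid.n_cells == 121
        assert grid.c_values[0] == pytest.approx(1e-5)
        assert grid.c_values[-1] == pytest.approx(1e5)
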