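import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from oncoresponse.classifier import (
    COST_GRID_TINY,
    PredictionError,
    RankingResult,
    SelectionCandidate,
    TrainingError,
    apply_selection_rule,
    mutation_status_predictor,
    predict,
    preprocess_features,
    prune_correlated,
    select_model,
    svm_rfe_rank,
    train_weighted_linear_svm,
    tune_costs,
)
from oncoresponse.matrix import ExpressionMatrix


def svm_dual_oracle(X, y, c_resis, c_resp):
    """Independent reference solution of the class-weighted soft-margin
    linear SVM via its dual quadratic program (scipy SLSQP)."""
    X = np.asarray(X, float)
    s = np.where(np.asarray(y, bool), 1.0, -1.0)
    C = np.where(np.asarray(y, bool), c_resp, c_resis)
    n = len(s)
    Q = (s[:, None] * s[None, :]) * (X @ X.T)

    def neg_dual(a):
        return 0.5 * a @ Q @ a - a.sum()

    cons = [{"type": "eq", "fun": lambda a: a @ s}]
    bounds = [(0.0, Ci) for Ci in C]
    best = None
    for x0_scale in (0.1, 0.5, 0.9):
        res = minimize(neg_dual, x0_scale * C, bounds=bounds,
                       constraints=cons, method="SLSQP",
                       options={"maxiter": 2000, "ftol": 1e-14})
        if best is None or res.fun < best.fun:
            best = res
    a = best.x
    w = (a * s) @ X
    on_margin = (a > 1e-6 * C) & (a < C * (1 - 1e-6))
    if on_margin.any():
        b = float(np.mean(s[on_margin] - X[on_margin] @ w))
    else:
        b = None  # bias not identifiable (all multipliers at bounds)
    return w, b


class TestPreprocess:
    def test_unit_scale_and_idempotent_reapplication(self, tiny_matrix):
        X, scaler = preprocess_features(tiny_matrix, tiny_matrix.gene_ids)
        assert np.allclose(X.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(X.std(axis=0, ddof=1), 1.0)
        again = scaler.transform_log2(tiny_matrix.log2())
        pd.testing.assert_frame_equal(X, again)

    def test_constant_gene_dropped_with_warning(self):
        values = pd.DataFrame({f"s{i}": [5.0, float(i + 1)] for i in range(6)},
                              index=["flat", "ok"])
        m = ExpressionMatrix(values)
        with pytest.warns(UserWarning, match="flat"):
            X, scaler = preprocess_features(m, ["flat", "ok"])
        assert list(X.columns) == ["ok"]
        assert scaler.dropped == ["flat"]


class TestPruneCorrelated:
    def test_duplicate_gene_lower_mean_dropped(self):
        rng = np.random.default_rng(0)
        a = rng.normal(6.0, 1.0, 30)
        table = pd.DataFrame({"hi": a, "lo": a - 1.0})  # r = 1
        assert prune_correlated(table) == ["hi"]

    def test_uncorrelated_untouched(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.normal(size=(50, 4)),
                             columns=list("abcd"))
        assert prune_correlated(table) == list("abcd")

    def test_chain_follows_greedy_order_across_iterations(self):
        rng = np.random.default_rng(2)
        latent = rng.normal(0.0, 1.0, 200)
        a = 7.0 + latent
        b = 5.0 + latent + rng.normal(0.0, 0.25, 200)   # r(a,b) ~ 0.97
        c = 6.0 + latent + rng.normal(0.0, 0.55, 200)   # r(a,c) ~ 0.88
        table = pd.DataFrame({"A": a, "B": b, "C": c})
        corr = table.corr()
        assert corr.loc["A", "B"] > corr.loc["A", "C"] >= 0.8
        # iteration 1: (A,B) drops B, then (A,C) drops C -> only A survives
        assert prune_correlated(table) == ["A"]


class TestWeightedSvm:
    def test_two_point_analytic_solution(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([False, True])
        model = train_weighted_linear_svm(X, y, 100.0, 100.0)
        assert model.w[0] == pytest.approx(1.0, abs=1e-6)
        assert model.b == pytest.approx(0.0, abs=1e-6)

    def test_duplication_with_halved_costs_invariant(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 2))
        y = np.array([True] * 4 + [False] * 8)
        m1 = train_weighted_linear_svm(X, y, 0.4, 1.0)
        m2 = train_weighted_linear_svm(np.vstack([X, X]),
                                       np.concatenate([y, y]), 0.2, 0.5)
        assert np.allclose(m1.w, m2.w, atol=1e-4)
        assert m1.b == pytest.approx(m2.b, abs=1e-4)

    def test_raising_responder_cost_moves_boundary(self):
        # overlapping 1-D classes: higher responder cost pushes the
        # boundary toward the resistant side (more responder calls)
        X = np.array([[-2.0], [-1.0], [-0.5], [0.5], [1.0], [2.0]])
        y = np.array([False, False, True, False, True, True])
        lo = train_weighted_linear_svm(X, y, 1.0, 0.1)
        hi = train_weighted_linear_svm(X, y, 1.0, 10.0)
        thr_lo = -lo.b / lo.w[0]
        thr_hi = -hi.b / hi.w[0]
        assert thr_hi < thr_lo

    def test_single_class_rejected(self):
        with pytest.raises(TrainingError):
            train_weighted_linear_svm(np.zeros((4, 2)),
                                      np.ones(4, bool), 1.0, 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_qp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        X = rng.normal(size=(n, 2))
        y = np.zeros(n, bool)
        y[: max(1, n // 2)] = True
        c_resis, c_resp = rng.choice([0.3, 1.0, 3.0], 2)
        model = train_weighted_linear_svm(X, y, c_resis, c_resp)
        w_ref, b_ref = svm_dual_oracle(X, y, c_resis, c_resp)
        scale = max(np.linalg.norm(w_ref), 1.0)
        assert np.linalg.norm(model.w - w_ref) / scale < 1e-3
        if b_ref is not None:
            assert abs(model.b - b_ref) / max(abs(b_ref), 1.0) < 1e-3


class TestTuneCosts:
    def _separable(self, n=24, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([True] * (n // 3) + [False] * (n - n // 3))
        X = rng.normal(size=(n, 3)) + np.where(y, 4.0, -4.0)[:, None]
        return X, y

    def test_single_point_grid_returned(self):
        X, y = self._separable()
        res = tune_costs(X, y, grid=[(0.3, 0.5)], n_boot=5, seed=1)
        assert (res.c_resis, res.c_resp) == (0.3, 0.5)

    def test_separable_reaches_perfect_f1(self):
        X, y = self._separable()
        res = tune_costs(X, y, grid=COST_GRID_TINY, n_boot=10, seed=1)
        assert res.f1 == pytest.approx(1.0)

    def test_deterministic_under_seed(self):
        X, y = self._separable()
        r1 = tune_costs(X, y, grid=COST_GRID_TINY, n_boot=10, seed=9)
        r2 = tune_costs(X, y, grid=COST_GRID_TINY, n_boot=10, seed=9)
        assert (r1.c_resis, r1.c_resp, r1.f1) == (r2.c_resis, r2.c_resp, r2.f1)
        pd.testing.assert_frame_equal(r1.table, r2.table)


class TestRfeRanking:
    def _planted(self, seed):
        rng = np.random.default_rng(seed)
        y = np.array([True] * 14 + [False] * 34)
        X = rng.normal(size=(48, 10))
        X[:, :3] += np.where(y, 3.0, 0.0)[:, None]  # 3 informative features
        cols = [f"inf{i}" for i in range(3)] + [f"noise{i}" for i in range(7)]
        return pd.DataFrame(X, columns=cols), y

    def test_informative_features_rank_top(self):
        hits = 0
        for seed in range(5):
            X, y = self._planted(seed)
            ranking = svm_rfe_rank(X, y, grid=COST_GRID_TINY, n_boot=8,
                                   n_resample=15, seed=seed)
            if set(ranking.genes[:3]) == {"inf0", "inf1", "inf2"}:
                hits += 1
        assert hits >= 4

    def test_single_feature_trivial(self):
        X = pd.DataFrame({"only": [1.0, -1.0, 2.0, -2.0]})
        y = np.array([True, False, True, False])
        ranking = svm_rfe_rank(X, y, grid=[(1.0, 1.0)], n_boot=3, n_resample=3)
        assert ranking.genes == ["only"]

    def test_elimination_order_deterministic(self):
        X, y = self._planted(7)
        r1 = svm_rfe_rank(X, y, grid=COST_GRID_TINY, n_boot=5, n_resample=10,
                          seed=3)
        r2 = svm_rfe_rank(X, y, grid=COST_GRID_TINY, n_boot=5, n_resample=10,
                          seed=3)
        assert r1.genes == r2.genes
        assert r1.scores == r2.scores

    def test_ranking_is_permutation_of_input(self):
        X, y = self._planted(1)
        ranking = svm_rfe_rank(X, y, grid=[(0.1, 0.3)], n_boot=3, n_resample=5)
        assert sorted(ranking.genes) == sorted(X.columns)


class TestSelectionRule:
    def _cand(self, f1, sens, k=10, cr=0.05, cp=0.3):
        return SelectionCandidate(c_resis=cr, c_resp=cp, k=k, f1=f1,
                                  sensitivity=sens, specificity=0.8)

    def test_third_best_f1_wins_on_sensitivity(self):
        cands = [self._cand(0.90, 0.70, k=20), self._cand(0.89, 0.85, k=16),
                 self._cand(0.88, 0.80, k=12)]
        assert apply_selection_rule(cands, top_m=3).f1 == 0.89

    def test_identical_metrics_prefer_smaller_panel(self):
        cands = [self._cand(0.9, 0.8, k=16), self._cand(0.9, 0.8, k=4),
                 self._cand(0.9, 0.8, k=8)]
        assert apply_selection_rule(cands, top_m=3).k == 4

    def test_single_candidate_returned(self):
        only = self._cand(0.5, 0.5)
        assert apply_selection_rule([only], top_m=3) is only

    def test_select_model_end_to_end_separable(self):
        rng = np.random.default_rng(4)
        y = np.array([True] * 10 + [False] * 20)
        X = pd.DataFrame(rng.normal(size=(30, 6)),
                         columns=[f"g{i}" for i in range(6)])
        X["g0"] += np.where(y, 5.0, -5.0)
        ranking = RankingResult(genes=list(X.columns),
                                scores={g: 1.0 for g in X.columns})
        cand, model = select_model(ranking, X, y, grid=[(0.5, 0.5)],
                                   candidate_sizes=(1, 3), n_boot=8, seed=0)
        assert cand.f1 == pytest.approx(1.0)
        assert cand.k == 1  # ties resolved toward the smaller panel
        assert model.genes == ["g0"]


class TestPredict:
    def test_training_labels_reproduced_when_separable(self, default_cohort):
        _, matrix, _, _, truth = default_cohort
        genes = truth.informative_genes
        X, scaler = preprocess_features(matrix, genes)
        model = train_weighted_linear_svm(X, truth.labels.to_numpy(), 5.0, 5.0,
                                          genes=genes)
        model.scaler = scaler
        preds = predict(model, matrix)
        assert (preds["predicted_responder"]
                == truth.labels.to_numpy()).mean() >= 0.9

    def test_zero_decision_value_is_resistant(self):
        model = train_weighted_linear_svm(np.array([[-1.0], [1.0]]),
                                          np.array([False, True]), 10.0, 10.0)
        assert not model.predict_features(np.array([[0.0]]))[0]

    def test_missing_gene_named_in_error(self, default_cohort):
        _, matrix, _, _, truth = default_cohort
        genes = truth.informative_genes
        X, scaler = preprocess_features(matrix, genes)
        model = train_weighted_linear_svm(X, truth.labels.to_numpy(), 1.0, 1.0,
                                          genes=genes)
        model.scaler = scaler
        smaller = matrix.subset_genes([g for g in matrix.gene_ids
                                       if g != genes[0]])
        with pytest.raises(PredictionError, match=genes[0]):
            predict(model, smaller)


class TestMutationStatus:
    @pytest.mark.parametrize("gene,change,kras_mode,ras_raf_mode", [
        ("KRAS", "G12D", False, False),
        ("KRAS", "G13C", False, False),
        ("KRAS", "Q61H", True, False),
        ("KRAS", "A146T", True, False),
        ("NRAS", "G12S", True, False),
        ("NRAS", "Q22K", True, False),
        ("BRAF", "V600E", True, False),
        ("BRAF", "V600K", True, True),   # only V600E qualifies
        ("KRAS", "G60G", True, True),
        ("EGFR", "A864V", True, True),
    ])
    def test_truth_table(self, gene, change, kras_mode, ras_raf_mode):
        """Expected predicted-responder flag per mode (True = wild-type call)."""
        muts = pd.DataFrame([{"sample_id": "s1", "gene": gene,
                              "protein_change": change}])
        assert mutation_status_predictor(muts, ["s1"],
                                         "kras_codon12_13")["s1"] == kras_mode
        assert mutation_status_predictor(muts, ["s1"],
                                         "all_ras_raf")["s1"] == ras_raf_mode

    def test_all_wild_type_predicts_responder(self):
        muts = pd.DataFrame(columns=["sample_id", "gene", "protein_change"])
        out = mutation_status_predictor(muts, ["a", "b"], "all_ras_raf")
        assert out.all()

    def test_unparseable_change_warns_wild_type(self):
        muts = pd.DataFrame([{"sample_id": "s1", "gene": "KRAS",
                              "protein_change": "splice??"}])
        with pytest.warns(UserWarning, match="unparseable"):
            out = mutation_status_predictor(muts, ["s1"], "all_ras_raf")
        assert out["s1"]
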