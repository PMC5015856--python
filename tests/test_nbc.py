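import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.neighbors import NearestCentroid
from sklearn.svm import SVR

from nbclass import (
    RESISTANT,
    SENSITIVE,
    NBCClassifier,
    NBCModel,
    build_class_network,
    fit_nbc,
    fit_ridge_predictors,
    fit_svr_predictors,
)
from nbclass.errors import DomainError, TrainingError
from nbclass.evaluation import ConfusionMatrix23, balanced_accuracy
from nbclass.nbc import SVRPredictor

from conftest import random_class_expr


def bruteforce_edges(frame: pd.DataFrame, threshold: float) -> set:
    """Independent all-pairs correlation scan (scipy pearsonr)."""
    edges = set()
    for a, b in itertools.combinations(frame.columns, 2):
        x, y = frame[a].to_numpy(), frame[b].to_numpy()
        if x.std() == 0 or y.std() == 0:
            continue  # correlation with a constant vector is defined as 0
        if abs(stats.pearsonr(x, y)[0]) > threshold:
            edges.add(frozenset((a, b)))
    return edges


class TestBuildNetwork:
    def test_perfect_linear_pair_connected(self):
        frame = pd.DataFrame({"g1": [1.0, 2.0, 3.0], "g2": [2.0, 4.0, 6.0]})
        net = build_class_network(frame, 0.9)
        assert net.edges == {("g1", "g2")}

    def test_constant_gene_isolated(self):
        frame = pd.DataFrame(
            {"g1": [1.0, 2.0, 3.0], "g2": [2.0, 4.0, 6.0], "g3": [5.0, 5.0, 5.0]}
        )
        net = build_class_network(frame, 0.5)
        assert net.degree("g3") == 0
        assert net.edges == {("g1", "g2")}

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            frame = random_class_expr(rng, 12, 10)
            thr = float(rng.uniform(0.1, 0.9))
            net = build_class_network(frame, thr)
            assert {frozenset(e) for e in net.edges} == bruteforce_edges(frame, thr)

    def test_edge_monotonicity_in_threshold(self):
        rng = np.random.default_rng(6)
        frame = random_class_expr(rng, 15, 8)
        thresholds = [0.1, 0.3, 0.5, 0.7, 0.9]
        edge_sets = [set(build_class_network(frame, t).edges) for t in thresholds]
        for loose, strict in zip(edge_sets, edge_sets[1:]):
            assert strict <= loose

    def test_preconditions(self):
        frame = pd.DataFrame({"g1": [1.0, 2.0], "g2": [2.0, 1.0]})
        with pytest.raises(TrainingError):
            build_class_network(frame, 0.5)
        with pytest.raises(DomainError):
            build_class_network(random_class_expr(np.random.default_rng(0), 5, 3), 1.5)


class TestRidgePredictors:
    def test_recovers_exact_linear_relation(self):
        rng = np.random.default_rng(1)
        ej = rng.normal(size=30)
        frame = pd.DataFrame({"gj": ej, "gk": 2.0 * ej})
        net = fit_ridge_predictors(build_class_network(frame, 0.9), frame, lam=1e-9)
        assert net.predictors["gk"].coef[0] == pytest.approx(2.0, abs=1e-4)

    def test_heavy_shrinkage_limits_to_training_mean(self):
        rng = np.random.default_rng(2)
        ej = rng.normal(size=30)
        frame = pd.DataFrame({"gj": ej, "gk": 2.0 * ej + 5.0})
        net = fit_ridge_predictors(build_class_network(frame, 0.9), frame, lam=1e9)
        pred = net.predictors["gk"].predict(np.array([[10.0]]))[0]
        assert pred == pytest.approx(frame["gk"].mean(), abs=1e-3)

    def test_degree_zero_node_predicts_class_mean(self):
        frame = pd.DataFrame(
            {"g1": [1.0, 2.0, 3.0, 4.0], "g2": [5.0, 5.0, 5.0, 5.0]}
        )
        net = fit_ridge_predictors(build_class_network(frame, 0.9), frame)
        y = net.predict_expression(np.array([99.0, 99.0]))
        assert y[1] == pytest.approx(5.0)

    def test_prediction_is_local_to_neighbors(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=40)
        frame = pd.DataFrame(
            {
                "g1": z + 0.01 * rng.normal(size=40),
                "g2": z + 0.01 * rng.normal(size=40),
                "g3": rng.normal(size=40),
            }
        )
        net = fit_ridge_predictors(build_class_network(frame, 0.9), frame)
        assert net.neighbors("g1") == ["g2"]
        x = np.array([0.5, 0.5, 0.0])
        x_perturbed = x.copy()
        x_perturbed[2] = 100.0  # g3 is not a neighbor of g1
        assert net.predict_expression(x)[0] == net.predict_expression(x_perturbed)[0]


class TestSVRPredictors:
    @staticmethod
    def _sine_frame(n=60, seed=4):
        rng = np.random.default_rng(seed)
        ej = rng.uniform(-3, 3, size=n)
        return pd.DataFrame({"gj": ej, "gk": np.sin(ej) + 0.05 * rng.normal(size=n)})

    def test_nonlinear_relation_beats_ridge_on_training_mse(self):
        frame = self._sine_frame()
        net_s = fit_svr_predictors(build_class_network(frame, 0.1), frame, seed=0)
        net_r = fit_ridge_predictors(build_class_network(frame, 0.1), frame)
        X = frame.to_numpy()
        mse_svr = np.mean((net_s.predict_matrix(X)[:, 1] - frame["gk"]) ** 2)
        mse_ridge = np.mean((net_r.predict_matrix(X)[:, 1] - frame["gk"]) ** 2)
        assert mse_svr < mse_ridge

    def test_single_point_grid_used_without_search(self):
        frame = self._sine_frame(n=20)
        grid = {"C": (2.0,), "gamma": (0.5,), "epsilon": (0.1,)}
        net = fit_svr_predictors(build_class_network(frame, 0.1), frame, grid=grid)
        pred = net.predictors["gk"]
        assert (pred.C, pred.gamma, pred.epsilon) == (2.0, 0.5, 0.1)

    def test_grid_search_deterministic_under_seed(self):
        frame = self._sine_frame(n=30)
        nets = [
            fit_svr_predictors(build_class_network(frame, 0.1), frame, seed=9)
            for _ in range(2)
        ]
        p0, p1 = nets[0].predictors["gk"], nets[1].predictors["gk"]
        assert (p0.C, p0.gamma) == (p1.C, p1.gamma)
        assert np.array_equal(p0.dual_coef, p1.dual_coef)

    def test_dual_form_prediction_matches_sklearn(self):
        frame = self._sine_frame(n=40)
        A = frame[["gj"]].to_numpy()
        y = frame["gk"].to_numpy()
        sk = SVR(kernel="rbf", C=1.0, gamma=0.5, epsilon=0.1).fit(A, y)
        ours = SVRPredictor.fit(A, y, 1.0, 0.5, 0.1, neighbors=("gj",))
        grid = np.linspace(-3, 3, 25).reshape(-1, 1)
        assert ours.predict(grid) == pytest.approx(sk.predict(grid), abs=1e-10)


class TestClassify:
    @staticmethod
    def _fit(features, labels, **kw):
        return fit_nbc(features, labels, corr_threshold=0.7, **kw)

    def test_tie_resolves_to_resistant(self, small_two_class):
        _, labeled = small_two_class
        X, y = labeled.features, labeled.labels
        model = self._fit(X, y)
        symmetric = NBCModel(
            sensitive_net=model.sensitive_net,
            resistant_net=model.sensitive_net,  # identical networks force a tie
            feature_set=model.feature_set,
            predictor_kind="ridge",
        )
        res = symmetric.classify(X.iloc[0].to_numpy())
        assert res.mse_sensitive == res.mse_resistant
        assert res.predicted_class == RESISTANT

    def test_mse_equals_mean_per_gene_error(self, small_two_class):
        _, labeled = small_two_class
        model = self._fit(labeled.features, labeled.labels)
        res = model.classify(labeled.features.iloc[3].to_numpy())
        assert res.mse_sensitive == pytest.approx(
            res.per_gene_errors["eps_sensitive"].mean(), abs=1e-9
        )
        assert res.mse_resistant == pytest.approx(
            res.per_gene_errors["eps_resistant"].mean(), abs=1e-9
        )

    def test_label_swap_symmetry(self, small_two_class):
        """Swapping the training classes swaps every (non-tied) prediction."""
        _, labeled = small_two_class
        X, y = labeled.features, labeled.labels
        swapped = y.map({RESISTANT: SENSITIVE, SENSITIVE: RESISTANT})
        model = self._fit(X, y)
        model_sw = self._fit(X, swapped)
        flip = {RESISTANT: SENSITIVE, SENSITIVE: RESISTANT}
        for i in range(0, len(X), 7):
            a = model.classify(X.iloc[i].to_numpy())
            b = model_sw.classify(X.iloc[i].to_numpy())
            assert a.mse_sensitive == pytest.approx(b.mse_resistant, abs=1e-9)
            if a.mse_sensitive != a.mse_resistant:
                assert b.predicted_class == flip[a.predicted_class]

    def test_deterministic_given_fitted_model(self, small_two_class):
        _, labeled = small_two_class
        model = self._fit(labeled.features, labeled.labels)
        x = labeled.features.iloc[5].to_numpy()
        assert model.classify(x).mse_sensitive == model.classify(x).mse_sensitive


class TestModelSerialization:
    @pytest.mark.parametrize("predictor", ["ridge", "svr"])
    def test_round_trip_preserves_predictions(self, tmp_path, small_two_class, predictor):
        _, labeled = small_two_class
        kw = {}
        if predictor == "svr":
            kw["svr_grid"] = {"C": (1.0,), "gamma": (0.1,), "epsilon": (0.1,)}
        model = fit_nbc(
            labeled.features, labeled.labels, corr_threshold=0.7,
            predictor=predictor, **kw,
        )
        path = tmp_path / "model.json"
        model.save(path)
        back = NBCModel.load(path)
        assert back.genes == model.genes
        assert back.sensitive_net.edges == model.sensitive_net.edges
        X = labeled.features.to_numpy()
        np.testing.assert_array_equal(
            np.column_stack(back.mse_matrix(X)), np.column_stack(model.mse_matrix(X))
        )


class TestCorrelationSignalSeparation:
    def test_nbc_beats_mean_difference_baseline(self, recovery_labeled):
        """With identical marginals per gene, only the co-expression structure
        separates the classes: the network classifier recovers it while a
        class-centroid rule stays near chance."""
        X, y = recovery_labeled.features, recovery_labeled.labels
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(X))
        train, test = idx[: len(X) * 3 // 4], idx[len(X) * 3 // 4 :]

        nbc = NBCClassifier(corr_threshold=0.7, n_features=30, predictor="ridge")
        nbc.fit(X.iloc[train], y.iloc[train])
        cm = ConfusionMatrix23.from_predictions(
            y.iloc[test], nbc.predict(X.iloc[test])
        )
        nbc_bac = balanced_accuracy(cm)

        centroid = NearestCentroid().fit(X.iloc[train], y.iloc[train])
        cm_base = ConfusionMatrix23.from_predictions(
            y.iloc[test], centroid.predict(X.iloc[test])
        )
        base_bac = balanced_accuracy(cm_base)

        assert nbc_bac > 0.8
        assert abs(base_bac - 0.5) < 0.15
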