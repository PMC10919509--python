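import math

import numpy as np
import pytest

from nodulecad import classifiers as clf
from nodulecad import fixtures as fx
from nodulecad.candidate_detection import RuleDescriptors, RuleThresholds
from nodulecad.errors import NotFittedError, ValidationError
from oracles import newton_logistic


def make_descriptor(**overrides):
    base = dict(
        mean_intensity=0.8,
        intensity_variance=0.01,
        circularity=0.9,
        flatness=0.9,
        elongation=1.1,
        rectangularity=0.8,
    )
    base.update(overrides)
    return RuleDescriptors(**base)


class TestRBFKernel:
    def test_identical_points(self):
        assert clf.rbf_kernel(np.ones(3), np.ones(3), gamma=0.7) == 1.0

    def test_unit_distance_closed_form(self):
        x1, x2 = np.zeros(1), np.ones(1)
        assert clf.rbf_kernel(x1, x2, gamma=1.0) == pytest.approx(math.exp(-1))

    def test_symmetric(self, rng):
        for _ in range(5):
            a, b = rng.normal(size=4), rng.normal(size=4)
            assert clf.rbf_kernel(a, b, 0.3) == clf.rbf_kernel(b, a, 0.3)

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValidationError):
            clf.rbf_kernel(np.zeros(2), np.zeros(2), gamma=0.0)


class TestFitSVM:
    def test_two_point_symmetric_boundary(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([-1, 1])
        m = clf.fit_svm(X, y, C=1e6, standardize=False)
        assert m.predict(np.array([[-0.5]]))[0] == -1
        assert m.predict(np.array([[0.5]]))[0] == 1
        assert abs(m.estimator.decision_function([[0.0]])[0]) < 1e-6
        assert m.estimator.support_vectors_.shape[0] == 2

    def test_xor_with_rbf(self):
        X = np.array([[0.0, 0], [0, 1], [1, 0], [1, 1]])
        y = np.array([-1, 1, 1, -1])
        m = clf.fit_svm(X, y, gamma=2.0, C=1e3, standardize=False)
        assert np.array_equal(m.predict(X), y)

    def test_duplicate_points_same_decision(self, rng):
        # separable data with a margin and non-binding C: the solution is
        # unique, so duplicating every sample leaves the decision unchanged
        X = rng.normal(size=(40, 3))
        X = X[np.abs(X[:, 0]) > 0.3]
        y = np.where(X[:, 0] > 0, 1, -1)
        m1 = clf.fit_svm(X, y, gamma=0.5, C=1e6)
        m2 = clf.fit_svm(np.vstack([X, X]), np.concatenate([y, y]), gamma=0.5, C=1e6)
        grid = rng.normal(size=(50, 3))
        assert np.array_equal(m1.predict(grid), m2.predict(grid))

    def test_label_validation(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValidationError):
            clf.fit_svm(X, np.array([0, 1, 0, 1]))
        with pytest.raises(ValidationError):
            clf.fit_svm(X, np.array([1, 1, 1, 1]))

    def test_training_predictions_recorded(self, rng):
        X = rng.normal(size=(30, 2))
        y = np.where(X.sum(axis=1) > 0, 1, -1)
        m = clf.fit_svm(X, y, C=100.0)
        assert np.array_equal(m.train_predictions_, m.predict(X))


class TestHybrid:
    def _fitted(self, rng):
        X = rng.normal(size=(60, 3))
        y = np.where(X[:, 0] > 0, 1, -1)
        descs = [make_descriptor() for _ in range(60)]
        th = RuleThresholds(bounds={"elongation": (None, 3.0)})
        return clf.HybridRuleSVM(th).fit(X, y, descs), X

    def test_rule_rejected_bypasses_svm(self, rng):
        h, X = self._fitted(rng)
        h.svm._predict = None  # any SVM call would now raise
        labels, rationale = h.predict(
            X[:1], [make_descriptor(elongation=9.0)]
        )
        assert labels[0] == -1
        assert rationale == ["rule:elongation"]

    def test_rule_passing_goes_to_svm(self, rng):
        h, X = self._fitted(rng)
        labels, rationale = h.predict(X[:2], [make_descriptor()] * 2)
        assert rationale == ["svm", "svm"]
        assert set(labels) <= {-1, 1}

    def test_unfitted_raises(self):
        h = clf.HybridRuleSVM(RuleThresholds())
        with pytest.raises(NotFittedError):
            h.predict(np.zeros((1, 2)), [make_descriptor()])

    def test_descriptor_count_mismatch(self, rng):
        h, X = self._fitted(rng)
        with pytest.raises(ValidationError):
            h.predict(X[:3], [make_descriptor()])

    def test_rejected_scores_below_survivors(self, rng):
        h, X = self._fitted(rng)
        descs = [make_descriptor(), make_descriptor(elongation=9.0)]
        s = h.scores(X[:2], descs)
        assert s[1] < s[0]

    @pytest.mark.slow
    def test_hybrid_false_positives_never_exceed_plain_svm(self):
        """Paired over 10 phantom seeds: rules only remove positives."""
        from nodulecad.benchmark import COMPARISON_OVERRIDES
        from nodulecad.candidate_detection import default_rule_thresholds
        from nodulecad.pipeline import benchmark_features

        th = default_rule_thresholds()
        fp_h = fp_s = 0
        for seed in range(10):
            X, y, descs, si, _ = benchmark_features(
                seed, n_slices=6, spec_overrides=COMPARISON_OVERRIDES
            )
            tr, te = si < 4, si >= 4
            if np.unique(y[tr]).size < 2 or np.unique(y[te]).size < 2:
                continue
            svm = clf.SVMClassifier().fit(X[tr], y[tr])
            hyb = clf.HybridRuleSVM(th).fit(X[tr], y[tr])
            y_s = svm.predict(X[te])
            y_h, _ = hyb.predict(X[te], [d for d, m in zip(descs, te) if m])
            fp_s += int(np.sum((y[te] == -1) & (y_s == 1)))
            fp_h += int(np.sum((y[te] == -1) & (y_h == 1)))
        assert fp_h <= fp_s


class TestLogistic:
    def test_probability_closed_forms(self):
        m = clf.LRModel(alpha=0.0, beta=np.array([1.0]))
        assert clf.lr_probability(m, np.array([0.0])) == pytest.approx(0.5)
        assert clf.lr_probability(m, np.array([math.log(3)])) == pytest.approx(0.75)

    def test_probability_symmetry(self, rng):
        m = clf.LRModel(alpha=0.3, beta=rng.normal(size=3))
        x = rng.normal(size=3)
        z = m.alpha + m.beta @ x
        x_neg = (-z - m.alpha + m.beta @ x) * 0  # construct mirrored input below
        p = clf.lr_probability(m, x)
        m_neg = clf.LRModel(alpha=-m.alpha, beta=-m.beta)
        assert clf.lr_probability(m_neg, x) == pytest.approx(1 - p)

    def test_probability_stable_at_extremes(self):
        m = clf.LRModel(alpha=0.0, beta=np.array([1.0]))
        assert clf.lr_probability(m, np.array([700.0])) == pytest.approx(1.0)
        assert clf.lr_probability(m, np.array([-700.0])) == pytest.approx(0.0)

    def test_null_model_log_likelihood(self, rng):
        X = rng.normal(size=(37, 4))
        y = rng.integers(0, 2, 37)
        m = clf.LRModel(alpha=0.0, beta=np.zeros(4))
        assert clf.lr_log_likelihood(m, X, y) == pytest.approx(-37 * math.log(2))

    def test_log_likelihood_nonpositive_and_matches_brute_force(self, rng):
        X = rng.normal(size=(25, 3))
        y = rng.integers(0, 2, 25)
        m = clf.LRModel(alpha=0.2, beta=rng.normal(size=3))
        J = clf.lr_log_likelihood(m, X, y)
        assert J <= 0.0
        brute = 0.0
        for xi, yi in zip(X, y):
            p = clf.lr_probability(m, xi)
            brute += yi * math.log(p) + (1 - yi) * math.log(1 - p)
        assert J == pytest.approx(brute, abs=1e-10)

    def test_label_validation(self):
        m = clf.LRModel(alpha=0.0, beta=np.zeros(1))
        with pytest.raises(ValidationError):
            clf.lr_log_likelihood(m, np.zeros((2, 1)), np.array([1, 2]))


class TestPSO:
    def test_inertia_weight_endpoints(self):
        cfg = clf.PSOConfig(wmax=0.9, wmin=0.4, itermax=100)
        assert clf.inertia_weight(cfg, 0) == 0.9
        assert clf.inertia_weight(cfg, 100) == 0.4

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            clf.PSOConfig(wmax=0.3, wmin=0.4)
        with pytest.raises(ValidationError):
            clf.PSOConfig(itermax=0)
        with pytest.raises(ValidationError):
            clf.PSOConfig(c1=-1.0)

    def test_converged_single_particle_fixed_point(self):
        cfg = clf.PSOConfig(n_particles=1, seed=0)
        state = clf.SwarmState(
            x=np.array([[1.0, 2.0]]),
            v=np.zeros((1, 2)),
            pbest_x=np.array([[1.0, 2.0]]),
            pbest_f=np.array([0.0]),
            gbest_x=np.array([1.0, 2.0]),
            gbest_f=0.0,
        )
        rng = np.random.default_rng(0)
        new = clf.pso_step(state, cfg, lambda p: 0.0, rng)
        assert np.array_equal(new.x, state.x)
        assert np.array_equal(new.v, np.zeros((1, 2)))

    def test_iteration_cap_enforced(self):
        cfg = clf.PSOConfig(itermax=1)
        rng = np.random.default_rng(0)
        state = clf.init_swarm(2, cfg, lambda p: 0.0, rng)
        state = clf.pso_step(state, cfg, lambda p: 0.0, rng)
        with pytest.raises(ValidationError):
            clf.pso_step(state, cfg, lambda p: 0.0, rng)

    def test_gbest_monotone_every_step(self, rng):
        cfg = clf.PSOConfig(n_particles=10, itermax=30, seed=1)

        def sphere(p):
            return -float(np.sum((p - 0.5) ** 2))

        gen = np.random.default_rng(1)
        state = clf.init_swarm(3, cfg, sphere, gen)
        prev = state.gbest_f
        for _ in range(cfg.itermax):
            state = clf.pso_step(state, cfg, sphere, gen)
            assert state.gbest_f >= prev
            prev = state.gbest_f


class TestPSOLR:
    def _data(self, seed=0, n=500, alpha=0.0, beta=2.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 1))
        p = 1 / (1 + np.exp(-(alpha + beta * X[:, 0])))
        y = (rng.uniform(size=n) < p).astype(float)
        return X, y

    def test_recovers_known_coefficients(self):
        X, y = self._data(seed=3)
        model, _ = clf.fit_pso_lr(X, y, clf.PSOConfig(seed=7))
        a_mle, b_mle = newton_logistic(X, y)
        assert abs(model.beta[0] - b_mle[0]) <= 0.5
        assert abs(model.alpha - a_mle) <= 0.5

    def test_beats_null_model(self, rng):
        X = rng.normal(size=(60, 2))
        y = rng.integers(0, 2, 60).astype(float)
        model, history = clf.fit_pso_lr(X, y, clf.PSOConfig(itermax=20, seed=2))
        assert history[-1] >= -60 * math.log(2)

    def test_deterministic_under_seed(self):
        X, y = self._data(seed=5, n=100)
        cfg = clf.PSOConfig(itermax=25, seed=11)
        m1, h1 = clf.fit_pso_lr(X, y, cfg)
        m2, h2 = clf.fit_pso_lr(X, y, cfg)
        assert m1.alpha == m2.alpha
        assert np.array_equal(m1.beta, m2.beta)
        assert h1 == h2

    def test_history_monotone(self):
        X, y = self._data(seed=6, n=200)
        _, history = clf.fit_pso_lr(X, y, clf.PSOConfig(itermax=50, seed=1))
        assert all(b >= a for a, b in zip(history, history[1:]))

    def test_classifier_wrapper_accuracy(self):
        X, y = self._data(seed=8, n=400, beta=3.0)
        model = clf.PSOLRClassifier(clf.PSOConfig(seed=4)).fit(X[:300], y[:300])
        acc = float(np.mean(model.predict(X[300:]) == y[300:]))
        a_mle, b_mle = newton_logistic(X[:300], y[:300])
        p_mle = 1 / (1 + np.exp(-(a_mle + X[300:, 0] * b_mle[0])))
        acc_mle = float(np.mean((p_mle >= 0.5) == y[300:]))
        assert abs(acc - acc_mle) <= 0.02


class TestRandomForest:
    def test_single_unpruned_tree_memorizes(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.integers(0, 3, 30)
        m = clf.fit_random_forest(X, y, n_trees=1, bootstrap=False, seed=0)
        assert np.array_equal(m.predict(X), y)

    def test_prediction_is_plurality_vote(self, rng):
        X = rng.normal(size=(80, 3))
        y = (X[:, 0] > 0).astype(int)
        m = clf.fit_random_forest(X, y, n_trees=15, seed=1)
        grid = rng.normal(size=(30, 3))
        votes = np.stack(
            [t.predict(grid) for t in m.classifier.estimator.estimators_]
        ).astype(int)
        manual = []
        for col in votes.T:
            counts = np.bincount(col, minlength=2)
            manual.append(int(np.argmax(counts)))  # argmax = lowest-index tie-break
        assert np.array_equal(m.predict(grid), manual)

    def test_oob_close_to_holdout(self):
        params = [
            (np.array([0.0, 0]), np.eye(2)),
            (np.array([2.5, 0]), np.eye(2)),
            (np.array([0.0, 2.5]), np.eye(2)),
        ]
        X, y = fx.generate_feature_table(200, params, seed=21)
        Xt, yt = fx.generate_feature_table(200, params, seed=22)
        m = clf.fit_random_forest(X, y, n_trees=200, seed=2)
        holdout_err = float(np.mean(m.predict(Xt) != yt))
        assert abs(m.oob_error - holdout_err) <= 0.1

    def test_mtry_validation(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.integers(0, 2, 20)
        with pytest.raises(ValidationError):
            clf.fit_random_forest(X, y, mtry=4)


class TestBaselines:
    def test_nb_boundary_at_midpoint(self):
        rng = np.random.default_rng(0)
        X0 = rng.normal(0.0, 1.0, (500, 1))
        X1 = rng.normal(4.0, 1.0, (500, 1))
        X = np.vstack([X0, X1])
        y = np.array([0] * 500 + [1] * 500)
        m = clf.fit_baseline("naive_bayes", X, y, standardize=False)
        assert m.predict(np.array([[1.7]]))[0] == 0
        assert m.predict(np.array([[2.3]]))[0] == 1

    def test_knn_k1_memorizes(self, rng):
        X = rng.normal(size=(25, 2))
        y = rng.integers(0, 2, 25)
        m = clf.fit_baseline("knn", X, y, k=1)
        assert np.array_equal(m.predict(X), y)

    def test_knn_k_exceeds_n_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValidationError):
            clf.fit_baseline("knn", X, np.array([0, 1, 0, 1, 0]), k=7)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError):
            clf.fit_baseline("mlp", np.zeros((4, 2)), np.array([0, 1, 0, 1]))

    def test_common_interface_on_one_table(self):
        params = [(np.zeros(3), np.eye(3)), (np.full(3, 2.0), np.eye(3))]
        X, y = fx.generate_feature_table(50, params, seed=31)
        for kind in ("naive_bayes", "knn", "decision_tree", "svm"):
            model = clf.build_classifier(kind)
            model.fit(X, y)
            preds = model.predict(X)
            scores = model.scores(X)
            assert preds.shape == (100,)
            assert scores.shape == (100,)
            assert float(np.mean(preds == y)) > 0.9


class TestSerialization:
    def test_svm_round_trip(self, tmp_path, rng):
        X = rng.normal(size=(60, 3))
        y = np.where(X[:, 0] + X[:, 1] > 0, 1, -1)
        m = clf.fit_svm(X, y, gamma=0.3, C=2.0)
        path = tmp_path / "svm.json"
        clf.save_model(m, path)
        loaded = clf.load_model(path)
        grid = rng.normal(size=(40, 3))
        assert np.array_equal(loaded.predict(grid), m.predict(grid))
        assert np.allclose(loaded.scores(grid), m.scores(grid), atol=1e-9)

    def test_pso_lr_round_trip(self, tmp_path, rng):
        X = rng.normal(size=(100, 2))
        y = (X[:, 0] > 0).astype(int)
        m = clf.PSOLRClassifier(clf.PSOConfig(itermax=20, seed=0)).fit(X, y)
        path = tmp_path / "lr.json"
        clf.save_model(m, path)
        loaded = clf.load_model(path)
        assert np.array_equal(loaded.predict(X), m.predict(X))

    def test_hybrid_round_trip(self, tmp_path, rng):
        X = rng.normal(size=(60, 3))
        y = np.where(X[:, 0] > 0, 1, -1)
        th = RuleThresholds(bounds={"elongation": (None, 3.0)})
        m = clf.HybridRuleSVM(th).fit(X, y)
        path = tmp_path / "hyb.json"
        clf.save_model(m, path)
        loaded = clf.load_model(path)
        descs = [make_descriptor(), make_descriptor(elongation=9.0)]
        got, rationale = loaded.predict(X[:2], descs)
        want, rationale_w = m.predict(X[:2], descs)
        assert np.array_equal(got, want)
        assert rationale == rationale_w

    def test_forest_round_trip(self, tmp_path, rng):
        X = rng.normal(size=(40, 3))
        y = (X[:, 0] > 0).astype(int)
        m = clf.fit_random_forest(X, y, n_trees=20, seed=3)
        path = tmp_path / "rf.json"
        clf.save_model(m, path)
        loaded = clf.load_model(path)
        assert np.array_equal(loaded.predict(X), m.predict(X))
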