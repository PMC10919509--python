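"""The classifier bank.

* ``SVMClassifier`` — RBF-kernel soft-margin SVM (SMO dual solver via
  scikit-learn) behind a thin contract: standardization is learned at fit
  time and stored with the model, and the fitted decision function must
  reproduce the training predictions recorded at fit time.
* ``HybridRuleSVM`` — rule-based pruning first: any sample violating an
  active descriptor bound is classified non-nodule (-1) without consulting
  the SVM; survivors are scored by the SVM.
* ``fit_pso_lr`` — logistic regression whose parameters are found by
  particle-swarm search maximizing the Bernoulli log-likelihood, with a
  linearly decaying inertia weight w = wmax - (wmax-wmin)/itermax * iter.
* ``fit_random_forest`` — bootstrap-trained trees with a random feature
  subset per split, majority-vote prediction, out-of-bag error recorded.
* ``fit_baseline`` — Gaussian naive Bayes, KNN and CART baselines behind
  the same predict/score contract.
"""

from __future__ import annotations

import base64
import json
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .candidate_detection import RuleDescriptors, RuleThresholds
from .errors import NotFittedError, ValidationError

BASELINE_KINDS = ("naive_bayes", "knn", "decision_tree")


def rbf_kernel(x1: np.ndarray, x2: np.ndarray, gamma: float) -> float:
    """K(x1, x2) = exp(-gamma * ||x1 - x2||^2)."""
    if gamma <= 0:
        raise ValidationError("gamma must be > 0")
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    if x1.shape != x2.shape:
        raise ValidationError("inputs must share a dimension")
    return float(np.exp(-gamma * np.sum((x1 - x2) ** 2)))


class _Scaler:
    """Per-feature z-scoring learned on the training split only."""

    def __init__(self):
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "_Scaler":
        X = np.asarray(X, float)
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        self.scale_ = scale
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise NotFittedError("scaler not fitted")
        return (np.asarray(X, float) - self.mean_) / self.scale_


class TrainedClassifier:
    """Common fit/predict/scores contract for the whole bank."""

    kind: str = "base"

    def __init__(self, standardize: bool = True):
        self.standardize = standardize
        self.scaler = _Scaler()
        self.classes_: np.ndarray | None = None
        self.train_predictions_: np.ndarray | None = None

    # subclasses implement _fit(Xs, y) and _predict(Xs), _scores(Xs)
    def fit(self, X: np.ndarray, y: np.ndarray) -> "TrainedClassifier":
        X = np.asarray(X, float)
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValidationError("training data must contain at least 2 classes")
        Xs = self.scaler.fit(X).transform(X) if self.standardize else X
        self._fit(Xs, y)
        self.classes_ = np.unique(y)
        self.train_predictions_ = self._predict(Xs)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        Xs = self.scaler.transform(X) if self.standardize else np.asarray(X, float)
        return self._predict(Xs)

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Continuous score; for binary problems, larger = the larger class
        label. Used for ROC curves."""
        self._check_fitted()
        Xs = self.scaler.transform(X) if self.standardize else np.asarray(X, float)
        return self._scores(Xs)

    def _check_fitted(self):
        if self.classes_ is None:
            raise NotFittedError(f"{self.kind} classifier is not fitted")

    def _fit(self, Xs, y):  # pragma: no cover - abstract
        raise NotImplementedError

    def _predict(self, Xs):  # pragma: no cover - abstract
        raise NotImplementedError

    def _scores(self, Xs):
        proba = self._proba(Xs)
        return proba[:, -1]

    def _proba(self, Xs):  # pragma: no cover - abstract
        raise NotImplementedError


class _SklearnWrapper(TrainedClassifier):
    def __init__(self, estimator, kind: str, standardize: bool = True):
        super().__init__(standardize=standardize)
        self.estimator = estimator
        self.kind = kind

    def _fit(self, Xs, y):
        self.estimator.fit(Xs, y)

    def _predict(self, Xs):
        return self.estimator.predict(Xs)

    def _proba(self, Xs):
        return self.estimator.predict_proba(Xs)

    def _scores(self, Xs):
        if hasattr(self.estimator, "decision_function"):
            s = self.estimator.decision_function(Xs)
            if s.ndim == 1:
                return s
        return self.estimator.predict_proba(Xs)[:, -1]


class SVMClassifier(_SklearnWrapper):
    """RBF-kernel soft-margin SVM with stored standardization."""

    def __init__(self, gamma: float | str = "scale", C: float = 1.0, standardize: bool = True):
        if isinstance(gamma, (int, float)) and gamma <= 0:
            raise ValidationError("gamma must be > 0")
        if C <= 0:
            raise ValidationError("C must be > 0")
        super().__init__(
            SVC(kernel="rbf", gamma=gamma, C=C, tol=1e-3),
            kind="svm",
            standardize=standardize,
        )
        self.gamma = gamma
        self.C = C


def fit_svm(
    X: np.ndarray,
    y: np.ndarray,
    gamma: float | str = "scale",
    C: float = 1.0,
    standardize: bool = True,
) -> SVMClassifier:
    """Fit the detection SVM; labels must be in {+1, -1}, both present."""
    y = np.asarray(y)
    labs = set(np.unique(y).tolist())
    if not labs <= {-1, 1}:
        raise ValidationError("fit_svm requires labels in {+1, -1}")
    if len(labs) < 2:
        raise ValidationError("both classes must be present")
    return SVMClassifier(gamma=gamma, C=C, standardize=standardize).fit(X, y)


def tune_svm(
    X: np.ndarray,
    y: np.ndarray,
    gammas=(0.01, 0.1, 1.0),
    Cs=(0.1, 1.0, 10.0),
    k: int = 5,
    seed: int = 0,
) -> SVMClassifier:
    """Grid-search gamma and C by stratified k-fold cross-validation."""
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(X, float)
    y = np.asarray(y)
    best, best_acc = None, -1.0
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for g in gammas:
        for C in Cs:
            accs = []
            for tr, te in skf.split(X, y):
                m = SVMClassifier(gamma=g, C=C).fit(X[tr], y[tr])
                accs.append(float(np.mean(m.predict(X[te]) == y[te])))
            acc = float(np.mean(accs))
            if acc > best_acc:
                best_acc, best = acc, (g, C)
    return SVMClassifier(gamma=best[0], C=best[1]).fit(X, y)


class HybridRuleSVM:
    """Rules first, SVM for the survivors.

    Samples whose descriptors violate any active bound are classified -1
    (non-nodule) without consulting the SVM; the rationale records which
    stage decided ("rule:<name>" or "svm").
    """

    kind = "hybrid"

    def __init__(self, thresholds: RuleThresholds, gamma: float | str = "scale", C: float = 1.0):
        self.thresholds = thresholds
        self.svm = SVMClassifier(gamma=gamma, C=C)
        self._fitted = False

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        descriptors: list[RuleDescriptors] | None = None,
    ) -> "HybridRuleSVM":
        X = np.asarray(X, float)
        y = np.asarray(y)
        if descriptors is not None:
            keep = np.array(
                [not self.thresholds.violations(d) for d in descriptors], bool
            )
            # train the SVM on the rule-surviving subset when it still
            # carries both classes; otherwise fall back to the full set
            if keep.any() and np.unique(y[keep]).size == 2:
                X, y = X[keep], y[keep]
        self.svm.fit(X, y)
        self._fitted = True
        return self

    def predict(
        self, X: np.ndarray, descriptors: list[RuleDescriptors]
    ) -> tuple[np.ndarray, list[str]]:
        if not self._fitted:
            raise NotFittedError("hybrid model is not fitted")
        X = np.asarray(X, float)
        if len(descriptors) != X.shape[0]:
            raise ValidationError("one descriptor block per sample required")
        labels = np.empty(X.shape[0], dtype=int)
        rationale: list[str] = []
        survivors = []
        for i, d in enumerate(descriptors):
            viol = self.thresholds.violations(d)
            if viol:
                labels[i] = -1
                rationale.append(f"rule:{viol[0]}")
            else:
                survivors.append(i)
                rationale.append("svm")
        if survivors:
            labels[survivors] = self.svm.predict(X[survivors])
        return labels, rationale

    def scores(self, X: np.ndarray, descriptors: list[RuleDescriptors]) -> np.ndarray:
        """SVM margin for survivors; rule-rejected samples get a score below
        every survivor's."""
        if not self._fitted:
            raise NotFittedError("hybrid model is not fitted")
        X = np.asarray(X, float)
        s = self.svm.scores(X)
        rejected = np.array(
            [bool(self.thresholds.violations(d)) for d in descriptors], bool
        )
        if rejected.any():
            floor = s.min() - 1.0 if (~rejected).any() else 0.0
            s = s.copy()
            s[rejected] = floor
        return s


def predict_hybrid(
    h: HybridRuleSVM, X: np.ndarray, descriptors: list[RuleDescriptors]
) -> tuple[np.ndarray, list[str]]:
    return h.predict(X, descriptors)


# ---------------------------------------------------------------------------
# PSO-optimized logistic regression
# ---------------------------------------------------------------------------


@dataclass
class LRModel:
    """Logistic model p = sigma(alpha + beta . x)."""

    alpha: float
    beta: np.ndarray

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, float))

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate([[self.alpha], self.beta])


def _linear_predictor(m: LRModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, float))
    return m.alpha + X @ m.beta


def lr_probability(m: LRModel, x: np.ndarray) -> np.ndarray | float:
    """p = e^z / (1 + e^z) with z = alpha + beta.x, numerically stable."""
    z = _linear_predictor(m, x)
    # stable logistic: exp of a non-positive argument only
    p = np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)), np.exp(z) / (1.0 + np.exp(z)))
    return float(p[0]) if p.size == 1 and np.asarray(x).ndim == 1 else p


def lr_log_likelihood(m: LRModel, X: np.ndarray, y: np.ndarray) -> float:
    """J(theta) = sum_i [ y_i z_i - ln(1 + e^{z_i}) ], y in {0, 1}."""
    y = np.asarray(y, float)
    if not set(np.unique(y).tolist()) <= {0.0, 1.0}:
        raise ValidationError("labels must be in {0, 1}")
    z = _linear_predictor(m, X)
    return float(np.sum(y * z - np.logaddexp(0.0, z)))


@dataclass(frozen=True)
class PSOConfig:
    n_particles: int = 30
    c1: float = 2.0
    c2: float = 2.0
    wmax: float = 0.9
    wmin: float = 0.4
    itermax: int = 100
    velocity_clamp: float = 1.0
    init_range: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if not (self.wmax >= self.wmin > 0):
            raise ValidationError("need wmax >= wmin > 0")
        if self.itermax < 1:
            raise ValidationError("itermax must be >= 1")
        if self.c1 < 0 or self.c2 < 0:
            raise ValidationError("c1, c2 must be >= 0")
        if self.n_particles < 1:
            raise ValidationError("need at least one particle")
        if self.velocity_clamp <= 0:
            raise ValidationError("velocity clamp must be > 0")


def inertia_weight(cfg: PSOConfig, iteration: int) -> float:
    """Linearly decaying inertia: wmax at iter 0, wmin at iter = itermax."""
    return cfg.wmax - (cfg.wmax - cfg.wmin) / cfg.itermax * iteration


@dataclass
class SwarmState:
    x: np.ndarray        # (n_particles, dim) positions
    v: np.ndarray        # velocities
    pbest_x: np.ndarray
    pbest_f: np.ndarray
    gbest_x: np.ndarray
    gbest_f: float
    iteration: int = 0


def init_swarm(dim: int, cfg: PSOConfig, fitness, rng: np.random.Generator) -> SwarmState:
    x = rng.uniform(-cfg.init_range, cfg.init_range, size=(cfg.n_particles, dim))
    x[0] = 0.0  # the null model is always represented in the initial swarm
    v = rng.uniform(-cfg.velocity_clamp, cfg.velocity_clamp, size=x.shape) * 0.1
    f = np.array([fitness(p) for p in x])
    g = int(np.argmax(f))
    return SwarmState(
        x=x,
        v=v,
        pbest_x=x.copy(),
        pbest_f=f.copy(),
        gbest_x=x[g].copy(),
        gbest_f=float(f[g]),
    )


def pso_step(
    state: SwarmState, cfg: PSOConfig, fitness, rng: np.random.Generator
) -> SwarmState:
    """One synchronous swarm update (velocity, position, bests)."""
    if state.iteration >= cfg.itermax:
        raise ValidationError("iteration cap reached")
    w = inertia_weight(cfg, state.iteration)
    shape = state.x.shape
    r1 = rng.uniform(size=shape)
    r2 = rng.uniform(size=shape)
    v = (
        w * state.v
        + cfg.c1 * r1 * (state.pbest_x - state.x)
        + cfg.c2 * r2 * (state.gbest_x - state.x)
    )
    v = np.clip(v, -cfg.velocity_clamp, cfg.velocity_clamp)
    x = state.x + v
    f = np.array([fitness(p) for p in x])
    improved = f > state.pbest_f
    pbest_x = np.where(improved[:, None], x, state.pbest_x)
    pbest_f = np.where(improved, f, state.pbest_f)
    g = int(np.argmax(pbest_f))
    gbest_f = float(pbest_f[g])
    gbest_x = pbest_x[g].copy() if gbest_f > state.gbest_f else state.gbest_x
    return SwarmState(
        x=x,
        v=v,
        pbest_x=pbest_x,
        pbest_f=pbest_f,
        gbest_x=gbest_x,
        gbest_f=max(gbest_f, state.gbest_f),
        iteration=state.iteration + 1,
    )


def fit_pso_lr(
    X: np.ndarray, y: np.ndarray, cfg: PSOConfig = PSOConfig()
) -> tuple[LRModel, list[float]]:
    """Swarm-search (alpha, beta) maximizing the log-likelihood.

    Returns the global-best model and the per-iteration global-best fitness
    trace (monotone non-decreasing by construction).
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    if not set(np.unique(y).tolist()) <= {0.0, 1.0}:
        raise ValidationError("labels must be in {0, 1}")
    rng = np.random.default_rng(cfg.seed)

    def fitness(theta: np.ndarray) -> float:
        return lr_log_likelihood(LRModel(alpha=theta[0], beta=theta[1:]), X, y)

    state = init_swarm(X.shape[1] + 1, cfg, fitness, rng)
    history = [state.gbest_f]
    for _ in range(cfg.itermax):
        state = pso_step(state, cfg, fitness, rng)
        history.append(state.gbest_f)
    theta = state.gbest_x
    return LRModel(alpha=float(theta[0]), beta=theta[1:]), history


class PSOLRClassifier(TrainedClassifier):
    """PSO-LR behind the common bank contract (labels coded {0, 1})."""

    kind = "pso_lr"

    def __init__(self, cfg: PSOConfig = PSOConfig(), standardize: bool = True):
        super().__init__(standardize=standardize)
        self.cfg = cfg
        self.model: LRModel | None = None
        self.history: list[float] = []
        self._label_map: dict[int, object] = {}

    def _fit(self, Xs, y):
        classes = np.unique(y)
        if classes.size != 2:
            raise ValidationError("PSO-LR is a binary classifier")
        y01 = (y == classes[1]).astype(float)
        self._label_map = {0: classes[0], 1: classes[1]}
        self.model, self.history = fit_pso_lr(Xs, y01, self.cfg)

    def _predict(self, Xs):
        p = np.atleast_1d(lr_probability(self.model, Xs))
        idx = (p >= 0.5).astype(int)
        return np.array([self._label_map[i] for i in idx])

    def _scores(self, Xs):
        return np.atleast_1d(lr_probability(self.model, Xs))


# ---------------------------------------------------------------------------
# Random forest and baselines
# ---------------------------------------------------------------------------


@dataclass
class ForestModel:
    classifier: "_SklearnWrapper"
    n_trees: int
    mtry: int | None
    oob_error: float  # the generalization-error estimate; NaN if unavailable

    def predict(self, X):
        return self.classifier.predict(X)

    def scores(self, X):
        return self.classifier.scores(X)


def fit_random_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 100,
    max_depth: int | None = None,
    mtry: int | None = None,
    seed: int = 0,
    bootstrap: bool = True,
) -> ForestModel:
    """Bootstrap forest with Gini splits and majority-vote prediction.

    Ties are broken toward the lowest class index. The out-of-bag error is
    NaN when it cannot be estimated (no bootstrap, or too few trees for
    every sample to be out of bag at least once).
    """
    X = np.asarray(X, float)
    if n_trees < 1:
        raise ValidationError("n_trees must be >= 1")
    if mtry is not None and not (1 <= mtry <= X.shape[1]):
        raise ValidationError("mtry must lie in [1, n_features]")
    want_oob = bootstrap and n_trees >= 10
    est = RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=max_depth,
        max_features=mtry if mtry is not None else "sqrt",
        criterion="gini",
        bootstrap=bootstrap,
        oob_score=want_oob,
        random_state=seed,
    )
    wrapper = _SklearnWrapper(est, kind="random_forest")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sparse-OOB warning at small n
        wrapper.fit(X, y)
    oob_error = float(1.0 - est.oob_score_) if want_oob and hasattr(est, "oob_score_") else float("nan")
    return ForestModel(
        classifier=wrapper, n_trees=n_trees, mtry=mtry, oob_error=oob_error
    )


def fit_baseline(
    kind: str, X: np.ndarray, y: np.ndarray, standardize: bool = True, **params
) -> TrainedClassifier:
    """Gaussian NB / KNN / CART behind the common contract."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    if kind == "naive_bayes":
        est = GaussianNB()
    elif kind == "knn":
        k = int(params.pop("k", 5))
        if k > X.shape[0]:
            raise ValidationError("k must not exceed the sample count")
        est = KNeighborsClassifier(n_neighbors=k)
    elif kind == "decision_tree":
        est = DecisionTreeClassifier(
            random_state=int(params.pop("seed", 0)),
            max_depth=params.pop("max_depth", None),
        )
    else:
        raise ValidationError(f"unknown baseline kind {kind!r}")
    return _SklearnWrapper(est, kind=kind, standardize=standardize).fit(X, y)


def build_classifier(kind: str, **params):
    """Factory used by the evaluation harness and the CLI."""
    if kind == "svm":
        return SVMClassifier(
            gamma=params.get("gamma", "scale"), C=params.get("C", 1.0)
        )
    if kind == "pso_lr":
        cfg = params.get("cfg") or PSOConfig(
            **{k: v for k, v in params.items() if k in PSOConfig.__dataclass_fields__}
        )
        return PSOLRClassifier(cfg=cfg)
    if kind in BASELINE_KINDS:

        class _Deferred(TrainedClassifier):
            kind_ = kind

            def __init__(self):
                super().__init__(standardize=True)
                self.kind = kind
                self.inner: TrainedClassifier | None = None

            def _fit(self, Xs, y):
                # outer wrapper already standardized
                self.inner = fit_baseline(kind, Xs, y, standardize=False, **params)

            def _predict(self, Xs):
                return self.inner.predict(Xs)

            def _scores(self, Xs):
                return self.inner.scores(Xs)

        return _Deferred()
    if kind == "random_forest":

        class _RF(TrainedClassifier):
            def __init__(self):
                super().__init__(standardize=False)
                self.kind = "random_forest"
                self.forest: ForestModel | None = None

            def _fit(self, Xs, y):
                self.forest = fit_random_forest(
                    Xs,
                    y,
                    n_trees=params.get("n_trees", 100),
                    max_depth=params.get("max_depth"),
                    mtry=params.get("mtry"),
                    seed=params.get("seed", 0),
                )

            def _predict(self, Xs):
                # inner wrapper owns the standardization (outer is passthrough)
                return self.forest.predict(Xs)

            def _scores(self, Xs):
                return self.forest.scores(Xs)

        return _RF()
    raise ValidationError(f"unknown classifier kind {kind!r}")


# ---------------------------------------------------------------------------
# JSON model container
# ---------------------------------------------------------------------------

_CONTAINER_VERSION = 1


def save_model(model, path: str | Path) -> None:
    """Serialize a fitted model to a versioned JSON container."""
    payload: dict = {"version": _CONTAINER_VERSION}
    if isinstance(model, SVMClassifier):
        est: SVC = model.estimator
        payload.update(
            kind="svm",
            gamma=float(est._gamma),
            C=model.C,
            support_vectors=est.support_vectors_.tolist(),
            dual_coef=est.dual_coef_.tolist(),
            intercept=est.intercept_.tolist(),
            classes=np.asarray(model.classes_).tolist(),
            scaler_mean=model.scaler.mean_.tolist(),
            scaler_scale=model.scaler.scale_.tolist(),
        )
    elif isinstance(model, PSOLRClassifier):
        payload.update(
            kind="pso_lr",
            alpha=model.model.alpha,
            beta=model.model.beta.tolist(),
            classes=np.asarray(model.classes_).tolist(),
            scaler_mean=model.scaler.mean_.tolist(),
            scaler_scale=model.scaler.scale_.tolist(),
        )
    elif isinstance(model, HybridRuleSVM):
        import tempfile

        with tempfile.NamedTemporaryFile(suffix=".json") as tmp:
            save_model(model.svm, tmp.name)
            svm_payload = json.loads(Path(tmp.name).read_text())
        payload.update(
            kind="hybrid",
            thresholds={k: list(v) for k, v in model.thresholds.bounds.items()},
            svm=svm_payload,
        )
    else:
        # forest / baselines: opaque but text-safe
        payload.update(
            kind=getattr(model, "kind", type(model).__name__),
            pickled=base64.b64encode(pickle.dumps(model)).decode("ascii"),
        )
    Path(path).write_text(json.dumps(payload))


class _LoadedSVM:
    """Decision function rebuilt from serialized support vectors."""

    kind = "svm"

    def __init__(self, payload: dict):
        self.sv = np.asarray(payload["support_vectors"], float)
        self.dual = np.asarray(payload["dual_coef"], float)[0]
        self.b = float(payload["intercept"][0])
        self.gamma = float(payload["gamma"])
        self.classes_ = np.asarray(payload["classes"])
        self.mean = np.asarray(payload["scaler_mean"], float)
        self.scale = np.asarray(payload["scaler_scale"], float)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.atleast_2d(np.asarray(X, float)) - self.mean) / self.scale
        d2 = ((Xs[:, None, :] - self.sv[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-self.gamma * d2) @ self.dual + self.b

    def scores(self, X: np.ndarray) -> np.ndarray:
        return self.decision_function(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


class _LoadedPSOLR:
    kind = "pso_lr"

    def __init__(self, payload: dict):
        self.model = LRModel(alpha=payload["alpha"], beta=np.asarray(payload["beta"]))
        self.classes_ = np.asarray(payload["classes"])
        self.mean = np.asarray(payload["scaler_mean"], float)
        self.scale = np.asarray(payload["scaler_scale"], float)

    def scores(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.atleast_2d(np.asarray(X, float)) - self.mean) / self.scale
        return np.atleast_1d(lr_probability(self.model, Xs))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[(self.scores(X) >= 0.5).astype(int)]


class _LoadedHybrid:
    kind = "hybrid"

    def __init__(self, payload: dict):
        self.thresholds = RuleThresholds(
            bounds={k: tuple(v) for k, v in payload["thresholds"].items()}
        )
        self.svm = _LoadedSVM(payload["svm"])

    def predict(self, X: np.ndarray, descriptors: list[RuleDescriptors]):
        X = np.atleast_2d(np.asarray(X, float))
        labels = np.empty(X.shape[0], dtype=int)
        rationale = []
        survivors = []
        for i, d in enumerate(descriptors):
            viol = self.thresholds.violations(d)
            if viol:
                labels[i] = -1
                rationale.append(f"rule:{viol[0]}")
            else:
                survivors.append(i)
                rationale.append("svm")
        if survivors:
            labels[survivors] = self.svm.predict(X[survivors]).astype(int)
        return labels, rationale


def load_model(path: str | Path):
    payload = json.loads(Path(path).read_text())
    if payload.get("version") != _CONTAINER_VERSION:
        raise ValidationError("unsupported model container version")
    kind = payload["kind"]
    if kind == "svm":
        return _LoadedSVM(payload)
    if kind == "pso_lr":
        return _LoadedPSOLR(payload)
    if kind == "hybrid":
        return _LoadedHybrid(payload)
    return pickle.loads(base64.b64decode(payload["pickled"]))
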