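"""The four classifiers with a common fit/predict/score contract.

KNN and SVM wrap scikit-learn estimators.  The random forest wraps
scikit-learn's RandomForestClassifier, adding per-tree out-of-bag (OOB)
bookkeeping so that OOB *permutation* importance — the mean decrease in OOB
classification accuracy when a feature's values are permuted — can be
computed exactly; this is the importance measure that drives recursive
feature elimination for KNN, RF and SVM alike.  The nearest shrunken
centroid (NSC / PAM-style) classifier is implemented here in full.

Scores returned by every classifier are real-valued with larger values more
case-like, and thresholding a score at its decision boundary reproduces the
predicted label exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .datasets import CASE, CONTROL, LabeledDataset

CLASSIFIER_KINDS = ("knn", "nsc", "rf", "svm")


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier kind plus the simulation study's hyperparameters.

    ``prior_policy='equal'`` reweights the classes during training for the
    NSC (via the prior term of the discriminant) and RF (via tree class
    weights) only; KNN and SVM are never reweighted.
    """

    kind: str
    knn_k: int = 5
    rf_trees: int = 500
    nsc_n_thresholds: int = 30
    svm_c: float = 1.0
    prior_policy: str = "empirical"

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.knn_k < 1 or self.knn_k % 2 == 0:
            raise ValueError("knn_k must be odd and >= 1")
        if self.rf_trees < 1:
            raise ValueError("rf_trees must be >= 1")
        if self.nsc_n_thresholds < 2:
            raise ValueError("nsc_n_thresholds must be >= 2")
        if self.prior_policy not in ("empirical", "equal"):
            raise ValueError(f"unknown prior_policy {self.prior_policy!r}")


def _binary(y: np.ndarray) -> np.ndarray:
    """Map CASE/CONTROL labels to 1/0."""
    return (np.asarray(y) == CASE).astype(np.int64)


def _labels(case_mask: np.ndarray) -> np.ndarray:
    return np.where(case_mask, CASE, CONTROL)


def _check_train(train: LabeledDataset) -> None:
    y = _binary(train.y)
    if y.sum() < 2 or (len(y) - y.sum()) < 2:
        raise ValueError("training set needs >= 2 samples in each class")


# ---------------------------------------------------------------------------
# Bagged-tree random forest with OOB permutation importance
# ---------------------------------------------------------------------------

@njit(cache=False)
def _tree_votes(cl, cr, feat, thr, leaf, X):
    n = X.shape[0]
    out = np.empty(n, np.int64)
    for i in range(n):
        node = 0
        while cl[node] != -1:
            node = cl[node] if X[i, feat[node]] <= thr[node] else cr[node]
        out[i] = leaf[node]
    return out


@njit(cache=False)
def _oob_correct(cl, cr, feat, thr, leaf, Xo, yo):
    n = Xo.shape[0]
    correct = 0
    for i in range(n):
        node = 0
        while cl[node] != -1:
            node = cl[node] if Xo[i, feat[node]] <= thr[node] else cr[node]
        if leaf[node] == yo[i]:
            correct += 1
    return correct


@njit(cache=False)
def _oob_correct_permuted(cl, cr, feat, thr, leaf, Xo, yo, f, order):
    """OOB correct count when feature ``f`` takes the values of a permutation."""
    n = Xo.shape[0]
    correct = 0
    for i in range(n):
        node = 0
        xf = Xo[order[i], f]
        while cl[node] != -1:
            fn = feat[node]
            v = xf if fn == f else Xo[i, fn]
            node = cl[node] if v <= thr[node] else cr[node]
        if leaf[node] == yo[i]:
            correct += 1
    return correct


class _Forest:
    """Random forest (fully grown CART trees on bootstrap samples, mtry =
    ceil(sqrt(p))) with out-of-bag permutation importance.

    Tree growing is scikit-learn's RandomForestClassifier; this wrapper adds
    the per-tree OOB bookkeeping and the permutation-importance traversal
    that the sklearn forest does not expose.
    """

    def __init__(self, n_trees: int, seed: int, equal_priors: bool = False):
        self.n_trees = n_trees
        self.seed = seed
        self.equal_priors = equal_priors
        self._trees: list[tuple] = []
        self._oob: list[np.ndarray] = []

    def fit(self, X: np.ndarray, y01: np.ndarray) -> "_Forest":
        X = np.ascontiguousarray(X, dtype=np.float32)
        n, p = X.shape
        counts = np.bincount(y01, minlength=2)
        # balanced classes make equal and empirical priors identical; skip
        # the weighted code path so the equivalence holds exactly
        reweight = self.equal_priors and counts[0] != counts[1]
        rf = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=int(np.ceil(np.sqrt(p))),
            class_weight="balanced" if reweight else None,
            random_state=self.seed % (2**31),
            n_jobs=1,
        )
        rf.fit(X, y01)
        all_idx = np.arange(n)
        self._trees = []
        self._oob = []
        for est, sampled in zip(rf.estimators_, rf.estimators_samples_):
            t = est.tree_
            leaf = est.classes_[
                np.argmax(t.value[:, 0, :], axis=1)
            ].astype(np.int64)
            self._trees.append(
                (t.children_left.copy(), t.children_right.copy(),
                 t.feature.copy(), t.threshold.copy(), leaf)
            )
            mask = np.ones(n, dtype=bool)
            mask[sampled] = False
            self._oob.append(all_idx[mask])
        return self

    def case_fraction(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees voting 'case' (class 1) per sample."""
        X = np.ascontiguousarray(X, dtype=np.float64)
        votes = np.zeros(X.shape[0])
        for cl, cr, feat, thr, leaf in self._trees:
            votes += _tree_votes(cl, cr, feat, thr, leaf, X)
        return votes / len(self._trees)

    def oob_permutation_importance(
        self, X: np.ndarray, y01: np.ndarray, seed: int
    ) -> np.ndarray:
        """Mean decrease in OOB accuracy per feature, averaged over trees.

        Features unused by a tree cannot change its predictions, so only the
        split features of each tree are permuted.  Negative values are kept
        as-is.
        """
        X = np.ascontiguousarray(X, dtype=np.float64)
        rng = np.random.default_rng(seed)
        imp = np.zeros(X.shape[1])
        for (cl, cr, feat, thr, leaf), oob in zip(self._trees, self._oob):
            if len(oob) == 0:
                continue
            Xo = np.ascontiguousarray(X[oob])
            yo = y01[oob]
            n_oob = len(oob)
            base = _oob_correct(cl, cr, feat, thr, leaf, Xo, yo)
            for f in np.unique(feat[feat >= 0]):
                order = rng.permutation(n_oob)
                c = _oob_correct_permuted(
                    cl, cr, feat, thr, leaf, Xo, yo, int(f), order
                )
                imp[f] += (base - c) / n_oob
        return imp / len(self._trees)


def fit_forest(train: LabeledDataset, spec: ClassifierSpec, seed: int = 0) -> _Forest:
    _check_train(train)
    forest = _Forest(
        spec.rf_trees, seed, equal_priors=(spec.prior_policy == "equal")
    )
    return forest.fit(train.X, _binary(train.y))


def rf_permutation_importance(
    train: LabeledDataset, spec: ClassifierSpec, seed: int = 0
) -> np.ndarray:
    """OOB permutation importance of each feature from a random-forest fit.

    Used for feature ranking regardless of ``spec.kind`` (RFE for KNN, RF and
    SVM all rank by a forest's importance).  Deterministic given ``seed``.
    """
    forest = fit_forest(train, spec, seed)
    return forest.oob_permutation_importance(train.X, _binary(train.y), seed + 1)


def rank_features(importance: np.ndarray) -> np.ndarray:
    """Feature indices from most to least important; ties keep lower index first."""
    return np.argsort(-np.asarray(importance), kind="stable")


# ---------------------------------------------------------------------------
# Nearest shrunken centroid (PAM-style)
# ---------------------------------------------------------------------------

@dataclass
class ShrunkenCentroidModel:
    """Soft-thresholded diagonal nearest-centroid discriminant.

    Standardized centroid differences d_ik = (xbar_ik - xbar_i) /
    (m_k (s_i + s0)) are soft-thresholded at Delta; a test point is assigned
    to the class minimizing sum_i (x_i - xbar'_ik)^2 / (s_i + s0)^2
    - 2 log pi_k.  Class order in all stacked arrays is (control, case).
    """

    overall_centroid: np.ndarray
    class_centroids: np.ndarray      # 2 x p, rows (control, case)
    pooled_sd: np.ndarray
    s0: float
    m_k: np.ndarray
    d: np.ndarray                    # 2 x p standardized differences
    threshold: float
    d_shrunk: np.ndarray
    priors: np.ndarray

    @property
    def shrunken_centroids(self) -> np.ndarray:
        sw = self.pooled_sd + self.s0
        return self.overall_centroid + self.m_k[:, None] * sw * self.d_shrunk

    def active_features(self) -> np.ndarray:
        """Indices with a nonzero shrunken difference in at least one class."""
        return np.where(np.any(self.d_shrunk != 0.0, axis=0))[0]

    def discriminants(self, X: np.ndarray) -> np.ndarray:
        """n x 2 array of class discriminant scores (smaller = closer)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        sw = self.pooled_sd + self.s0
        cent = self.shrunken_centroids
        disc = np.empty((X.shape[0], 2))
        for k in range(2):
            z = (X - cent[k]) / sw
            disc[:, k] = np.einsum("ij,ij->i", z, z) - 2.0 * np.log(self.priors[k])
        return disc

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Case-vs-control discriminant difference; > 0 predicts case."""
        disc = self.discriminants(X)
        return disc[:, 0] - disc[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return _labels(self.decision_scores(X) >= 0)


def _nsc_statistics(X: np.ndarray, y01: np.ndarray):
    n, p = X.shape
    nk = np.array([(y01 == 0).sum(), (y01 == 1).sum()])
    xbar = X.mean(axis=0)
    cent = np.vstack([X[y01 == 0].mean(axis=0), X[y01 == 1].mean(axis=0)])
    ss = np.zeros(p)
    for k in (0, 1):
        diff = X[y01 == k] - cent[k]
        ss += np.einsum("ij,ij->j", diff, diff)
    s = np.sqrt(ss / (n - 2))
    s0 = float(np.median(s))
    m_k = np.sqrt(1.0 / nk - 1.0 / n)
    d = (cent - xbar) / (m_k[:, None] * (s + s0))
    return xbar, cent, s, s0, m_k, d, nk


def soft_threshold(d: np.ndarray, delta_threshold: float) -> np.ndarray:
    return np.sign(d) * np.maximum(np.abs(d) - delta_threshold, 0.0)


def nsc_fit(
    train: LabeledDataset,
    delta_threshold: float = 0.0,
    prior_policy: str = "empirical",
) -> ShrunkenCentroidModel:
    """Fit the shrunken-centroid model at one shrinkage threshold.

    The fudge constant s0 (median of the pooled within-class sds) keeps the
    standardization finite for zero-variance features.
    """
    if delta_threshold < 0:
        raise ValueError("delta_threshold must be >= 0")
    _check_train(train)
    y01 = _binary(train.y)
    xbar, cent, s, s0, m_k, d, nk = _nsc_statistics(train.X, y01)
    if prior_policy == "equal":
        priors = np.array([0.5, 0.5])
    else:
        priors = nk / nk.sum()
    return ShrunkenCentroidModel(
        overall_centroid=xbar,
        class_centroids=cent,
        pooled_sd=s,
        s0=s0,
        m_k=m_k,
        d=d,
        threshold=float(delta_threshold),
        d_shrunk=soft_threshold(d, delta_threshold),
        priors=priors,
    )


def nsc_threshold_grid(train: LabeledDataset, n_thresholds: int = 30) -> np.ndarray:
    """Equally spaced shrinkage thresholds from 0 to max |d_ik|."""
    y01 = _binary(train.y)
    *_, d, _ = _nsc_statistics(train.X, y01)
    return np.linspace(0.0, float(np.abs(d).max()), n_thresholds)


# ---------------------------------------------------------------------------
# Common contract
# ---------------------------------------------------------------------------

def _svm_gamma(X: np.ndarray, rng: np.random.Generator, max_pairs: int = 200) -> float:
    """Median heuristic: 1 / median squared pairwise distance of a subsample."""
    n = X.shape[0]
    idx = rng.choice(n, size=min(n, max_pairs), replace=False)
    S = X[idx]
    sq = np.sum(S * S, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (S @ S.T)
    d2 = d2[np.triu_indices_from(d2, k=1)]
    med = float(np.median(d2[d2 > 0])) if np.any(d2 > 0) else 1.0
    return 1.0 / med


def fit_predict_score(
    spec: ClassifierSpec,
    train: LabeledDataset,
    test_X: np.ndarray,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Train ``spec`` on ``train`` and score ``test_X``.

    Returns (labels, scores); scores are continuous with larger values more
    case-like (KNN: case-neighbor fraction; NSC: discriminant difference;
    RF: case vote fraction; SVM: signed decision value).
    """
    _check_train(train)
    test_X = np.atleast_2d(np.asarray(test_X, dtype=float))
    if test_X.shape[1] != train.n_features:
        raise ValueError(
            f"test has {test_X.shape[1]} features, train has {train.n_features}"
        )
    y01 = _binary(train.y)

    if spec.kind == "knn":
        knn = KNeighborsClassifier(n_neighbors=spec.knn_k)
        knn.fit(train.X, y01)
        scores = knn.predict_proba(test_X)[:, list(knn.classes_).index(1)]
        return _labels(scores >= 0.5), scores

    if spec.kind == "nsc":
        model = nsc_fit(train, 0.0, spec.prior_policy)
        scores = model.decision_scores(test_X)
        return _labels(scores >= 0), scores

    if spec.kind == "rf":
        forest = fit_forest(train, spec, seed)
        scores = forest.case_fraction(test_X)
        return _labels(scores >= 0.5), scores

    # svm: RBF kernel, bandwidth estimated from the data, C fixed
    rng = np.random.default_rng(seed)
    gamma = _svm_gamma(train.X, rng)
    svm = SVC(C=spec.svm_c, kernel="rbf", gamma=gamma)
    svm.fit(train.X, y01)
    dec = svm.decision_function(test_X)
    scores = dec if svm.classes_[1] == 1 else -dec
    return _labels(scores >= 0), scores
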