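"""Scikit-learn style estimators over the mining / selection / SVM stack.

``SubgraphFeatureExtractor`` is a transformer whose samples are uncertain
networks: ``fit`` mines each group's frequent subgraphs and selects the
discriminative ones, ``transform`` evaluates them as per-subject feature
columns.  ``RbfSvmGridClassifier`` is the grid-searched RBF-kernel SVM used
downstream.  Both compose with :class:`sklearn.pipeline.Pipeline`, which is
exactly how the nested cross-validation protocol is implemented.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC, _libsvm
from sklearn.utils.validation import check_is_fitted

from .build import certain_to_uncertain, threshold_by_sparsity
from .features import presence_features, probability_features
from .graph import Cohort, UncertainNetwork
from .mining import MiningConfig, mine_unfepg
from .selection import SelectionConfig, select_discriminative

__all__ = ["SubgraphFeatureExtractor", "RbfSvmGridClassifier"]


class SubgraphFeatureExtractor(TransformerMixin, BaseEstimator):
    """Mine frequent subgraphs per group, select discriminative ones, and
    expose them as subject-level features.

    Parameters
    ----------
    minsup : float, default 0.25
        Expected-support threshold for frequent-subgraph mining.
    top_k : int, default 15
        Discriminative patterns kept per group.
    growth_mode : {'increasing', 'exhaustive'}, default 'increasing'
        Pattern-growth mode of the miner.
    score : {'confidence', 'frequency_difference'}, default 'confidence'
        Discriminative score function; frequency difference is the natural
        choice for the binarized arm.
    sparsity : float or None, default None
        When set, every network is binarized by rank thresholding at this
        sparsity before mining, and ``transform`` produces binary presence
        features; when None, mining and features use the probabilistic
        networks directly.
    max_pattern_edges : int or None, default None
        Optional cap on mined pattern size.

    Attributes
    ----------
    frequent_pos_, frequent_neg_ : list of FrequentSubgraph
        Per-group mining results.
    discriminative_ : list of DiscriminativeSubgraph
        The selected patterns with scores and ranks.
    feature_patterns_ : list of SubgraphPattern
        Column patterns of the transformed matrix, in selection order.
    """

    def __init__(
        self,
        minsup: float = 0.25,
        top_k: int = 15,
        growth_mode: str = "increasing",
        score: str = "confidence",
        sparsity: float | None = None,
        max_pattern_edges: int | None = None,
    ):
        self.minsup = minsup
        self.top_k = top_k
        self.growth_mode = growth_mode
        self.score = score
        self.sparsity = sparsity
        self.max_pattern_edges = max_pattern_edges

    def _as_mining_networks(self, X) -> list[UncertainNetwork]:
        nets = list(X)
        if not nets:
            raise ValueError("at least one network is required")
        if not all(isinstance(n, UncertainNetwork) for n in nets):
            raise TypeError("samples must be UncertainNetwork instances")
        if self.sparsity is None:
            return nets
        return [
            certain_to_uncertain(threshold_by_sparsity(n, self.sparsity)) for n in nets
        ]

    def fit(self, X, y):
        y = np.asarray(y, dtype=int)
        nets = self._as_mining_networks(X)
        if len(y) != len(nets):
            raise ValueError("one label per network is required")
        cohort = Cohort(nets, y)
        mcfg = MiningConfig(
            minsup=self.minsup,
            growth_mode=self.growth_mode,
            max_pattern_edges=self.max_pattern_edges,
        )
        self.frequent_pos_ = mine_unfepg(cohort.positives, mcfg)
        self.frequent_neg_ = mine_unfepg(cohort.negatives, mcfg)
        self.discriminative_ = select_discriminative(
            self.frequent_pos_,
            self.frequent_neg_,
            cohort,
            SelectionConfig(top_k=self.top_k, score=self.score),
        )
        self.feature_patterns_ = [d.pattern for d in self.discriminative_]
        self.n_features_out_ = len(self.feature_patterns_)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "feature_patterns_")
        nets = list(X)
        if self.sparsity is not None:
            certain = [threshold_by_sparsity(n, self.sparsity) for n in nets]
            return presence_features(self.feature_patterns_, certain).values
        return probability_features(self.feature_patterns_, nets).values

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "feature_patterns_")
        return np.asarray([f"subgraph_{i}" for i in range(self.n_features_out_)])


class RbfSvmGridClassifier(ClassifierMixin, BaseEstimator):
    """RBF-kernel SVM with a power-of-two (c, g) grid search.

    The penalty factor ``C`` ranges over ``2^-5 .. 2^5`` and the kernel
    parameter ``gamma`` over ``2^-8 .. 2^2`` (step 1 in the exponent); the
    grid point maximizing mean inner-CV accuracy on the training data is
    selected, ties broken toward smaller C then smaller gamma.
    """

    def __init__(
        self,
        c_exponents: tuple = tuple(range(-5, 6)),
        g_exponents: tuple = tuple(range(-8, 3)),
        inner_folds: int = 3,
        random_state: int | None = None,
    ):
        self.c_exponents = c_exponents
        self.g_exponents = g_exponents
        self.inner_folds = inner_folds
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data must contain both classes")
        _libsvm.set_verbosity_wrap(0)
        c_values = [2.0**e for e in sorted(self.c_exponents)]
        g_values = [2.0**e for e in sorted(self.g_exponents)]
        inner = StratifiedKFold(
            n_splits=self.inner_folds, shuffle=True, random_state=self.random_state
        )
        splits = list(inner.split(X, y))
        # Precompute one squared-distance matrix; each gamma's RBF kernel is a
        # cheap elementwise transform of it, and inner-CV fits then run on
        # precomputed kernel submatrices.
        d2 = cdist(X, X, "sqeuclidean")
        # Inner-CV scoring runs on libsvm's low-level binding with precomputed
        # kernels: one squared-distance matrix is shared by all gammas and the
        # per-estimator wrapper overhead (dominant at this sample size) is
        # avoided.  Labels are encoded to sorted class indices exactly as the
        # SVC wrapper does, so selected parameters match a GridSearchCV over
        # SVC(kernel='rbf') point for point.
        y01 = np.asarray(y == classes[-1], dtype=np.float64)
        n_correct = np.zeros((len(c_values), len(g_values)))
        n_total = sum(len(te) for _, te in splits)
        for gj, g in enumerate(g_values):
            K = np.exp(-g * d2)
            for tr, te in splits:
                K_tr = np.ascontiguousarray(K[np.ix_(tr, tr)])
                K_te = np.ascontiguousarray(K[np.ix_(te, tr)])
                y_tr, y_te = y01[tr], y01[te]
                for ci, c in enumerate(c_values):
                    m = _libsvm.fit(
                        K_tr, y_tr, svm_type=0, kernel="precomputed", C=c
                    )
                    pred = _libsvm.predict(
                        K_te, m[0], m[1], m[2], m[3], m[4], m[5], m[6],
                        svm_type=0, kernel="precomputed",
                    )
                    n_correct[ci, gj] += np.sum(pred == y_te)
        # argmax with ties broken toward smaller c, then smaller gamma
        best_ci, best_gj = 0, 0
        for ci in range(len(c_values)):
            for gj in range(len(g_values)):
                if n_correct[ci, gj] > n_correct[best_ci, best_gj]:
                    best_ci, best_gj = ci, gj
        self.classes_ = classes
        self.best_c_ = float(c_values[best_ci])
        self.best_g_ = float(g_values[best_gj])
        self.best_score_ = float(n_correct[best_ci, best_gj] / n_total)
        self.best_estimator_ = SVC(
            kernel="rbf", C=self.best_c_, gamma=self.best_g_
        ).fit(X, y)
        return self

    def predict(self, X):
        check_is_fitted(self, "best_estimator_")
        return self.best_estimator_.predict(np.asarray(X, dtype=float))

    def decision_function(self, X):
        check_is_fitted(self, "best_estimator_")
        return self.best_estimator_.decision_function(np.asarray(X, dtype=float))
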