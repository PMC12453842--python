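"""Wrapper fitness: KNN cross-validated accuracy plus a sparsity reward.

The fitness of a binary feature mask is

    fitness = Acc + w * (1 - L_s / L_t)

where ``Acc`` is the stratified 10-fold cross-validated KNN accuracy using
only the masked columns, ``L_s`` the selected count, ``L_t`` the size of the
search space, and ``w`` in [0, 1] weights the reward for small subsets.

The fold assignment is drawn once per :class:`FitnessContext` and reused for
every mask, so within a run the fitness is a pure, memoized function of the
mask — which is what makes an exhaustive-enumeration optimum well defined for
small problems.

The KNN itself is a compact vectorized implementation with deterministic
tie rules: vote ties go to the nearest neighbour's class, and distance ties
to the lower training-sample index (stable sort).  A per-feature
squared-difference cache turns each mask evaluation into a sum over selected
slices, which is what keeps thousands of wrapper evaluations cheap.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .data import FeatureMatrix

__all__ = ["FitnessValue", "FitnessContext", "make_context",
           "knn_cv_accuracy", "fitness"]

logger = logging.getLogger(__name__)

# above this many float64 entries the pairwise cache is skipped and distances
# are recomputed per mask (same result, more compute, less memory)
_CACHE_LIMIT = 60_000_000


class FitnessValue:
    """Accuracy component, sparsity reward, and their total."""

    __slots__ = ("acc", "penalty_reward", "total", "L_s", "L_t")

    def __init__(self, acc: float, w: float, L_s: int, L_t: int):
        self.acc = float(acc)
        self.L_s = int(L_s)
        self.L_t = int(L_t)
        self.penalty_reward = w * (1.0 - L_s / L_t)
        self.total = self.acc + self.penalty_reward

    def __repr__(self) -> str:
        return (f"FitnessValue(total={self.total:.4f}, acc={self.acc:.4f}, "
                f"L_s={self.L_s}/{self.L_t})")


class FitnessContext:
    """Fixed training data, fold assignment, KNN settings, and a mask cache.

    Parameters
    ----------
    values, labels
        Training data restricted to the pre-screened features (z-scored).
    w
        Sparsity-reward weight in [0, 1].
    k_neighbors
        KNN neighbour count.
    cv_folds
        Requested fold count; reduced (and logged) if the smallest class has
        fewer members.
    seed
        Seeds the stratified fold assignment.
    """

    def __init__(self, values: np.ndarray, labels: np.ndarray,
                 w: float = 0.2, k_neighbors: int = 5,
                 cv_folds: int = 10, seed: int = 0):
        values = np.asarray(values, dtype=float)
        labels = np.asarray(labels, dtype=int)
        if not 0.0 <= w <= 1.0:
            raise ValueError("w must be in [0, 1]")
        if k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if values.shape[1] < 1:
            raise ValueError("search space is empty")
        min_class = int(np.bincount(labels).min())
        n_folds = min(cv_folds, min_class, values.shape[0])
        if n_folds < cv_folds:
            logger.info("reducing CV folds from %d to %d (smallest class has "
                        "%d members)", cv_folds, n_folds, min_class)
        if n_folds < 2:
            raise ValueError("cannot form at least 2 CV folds")
        self.values = values
        self.labels = labels
        self.w = float(w)
        self.k_neighbors = int(k_neighbors)
        self.n_folds = int(n_folds)
        self.seed = int(seed)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        self.folds = [(tr.copy(), te.copy())
                      for tr, te in skf.split(values, labels)]
        self.n_classes = int(labels.max()) + 1
        self._cache: dict[bytes, FitnessValue] = {}
        self._sq: np.ndarray | None = None
        m, lt = values.shape
        self._use_cache = lt * m * m <= _CACHE_LIMIT

    @property
    def L_t(self) -> int:
        return self.values.shape[1]

    def _sq_diffs(self) -> np.ndarray:
        """(L_t, M, M) per-feature squared differences, built lazily."""
        if self._sq is None:
            x = self.values.T  # (L_t, M)
            d = x[:, :, None] - x[:, None, :]
            self._sq = d * d
        return self._sq

    def pairwise_sq(self, mask: np.ndarray) -> np.ndarray:
        """(M, M) squared Euclidean distances over the masked columns."""
        if self._use_cache:
            sq = self._sq_diffs()
            return np.tensordot(mask.astype(float), sq, axes=(0, 0))
        xm = self.values[:, mask]
        g = xm @ xm.T
        nrm = np.diag(g)
        d = nrm[:, None] + nrm[None, :] - 2.0 * g
        np.maximum(d, 0.0, out=d)
        return d


def make_context(data: FeatureMatrix, retained, w: float = 0.2,
                 k_neighbors: int = 5, cv_folds: int = 10,
                 seed: int = 0) -> FitnessContext:
    """Build a fitness context on the columns given by ``retained``
    (boolean mask or index array) of a normalized FeatureMatrix."""
    idx = np.asarray(retained)
    if idx.dtype == bool:
        idx = np.flatnonzero(idx)
    if idx.size == 0:
        raise ValueError("retained feature set is empty")
    return FitnessContext(data.values[:, idx], data.labels, w=w,
                          k_neighbors=k_neighbors, cv_folds=cv_folds,
                          seed=seed)


def _knn_predict(dist: np.ndarray, train_labels: np.ndarray, k: int,
                 n_classes: int) -> np.ndarray:
    """Majority vote over the k nearest columns of ``dist`` (rows = queries).

    Distance ties resolve to the lower training index (stable sort); vote
    ties resolve to the class of the nearest neighbour among the tied
    classes.
    """
    k = min(k, train_labels.size)
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    neigh = train_labels[order]                      # (R, k) by distance rank
    onehot = neigh[:, :, None] == np.arange(n_classes)[None, None, :]
    counts = onehot.sum(axis=1)                      # (R, K)
    # first occurrence rank of each class among the neighbours (k if absent)
    ranks = np.arange(k)[None, :, None]
    first = np.where(onehot, ranks, k).min(axis=1)   # (R, K)
    # primary key: vote count; secondary: earlier first occurrence
    score = counts * (k + 1) + (k - first)
    return np.argmax(score, axis=1)


def knn_cv_accuracy(ctx: FitnessContext, mask: np.ndarray) -> float:
    """Mean over the fixed folds of held-out KNN accuracy on masked columns."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (ctx.L_t,):
        raise ValueError("mask length must equal the search-space size")
    if not mask.any():
        raise ValueError("mask selects no features")
    d2 = ctx.pairwise_sq(mask)
    accs = []
    for tr, te in ctx.folds:
        pred = _knn_predict(d2[np.ix_(te, tr)], ctx.labels[tr],
                            ctx.k_neighbors, ctx.n_classes)
        accs.append(float(np.mean(pred == ctx.labels[te])))
    return float(np.mean(accs))


def fitness(ctx: FitnessContext, mask: np.ndarray) -> FitnessValue:
    """Memoized fitness of a mask: ``acc + w * (1 - L_s/L_t)``."""
    mask = np.asarray(mask, dtype=bool)
    key = mask.tobytes()
    hit = ctx._cache.get(key)
    if hit is not None:
        return hit
    acc = knn_cv_accuracy(ctx, mask)
    value = FitnessValue(acc, ctx.w, int(mask.sum()), ctx.L_t)
    ctx._cache[key] = value
    return value
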