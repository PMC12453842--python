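"""Stage 1: elastic-net regression pre-screening.

Features with negligible association to the class labels are removed before
the wrapper search by fitting an elastic-net regression and keeping the
features with nonzero coefficients.  The loss minimized is

    (1/2m) * sum_m (y_m - yhat_m)^2
        + lam * ( alpha * sum_n |beta_n| + (1 - alpha)/2 * sum_n beta_n^2 )

with ``alpha`` the l1/l2 mixing coefficient in [0, 1] and ``lam`` the overall
regularization strength — exactly the objective sklearn's ``ElasticNet``
minimizes, which therefore stands behind :func:`fit_elastic_net`.

Two response encodings for the ordered severity grades are supported:
``"ordinal"`` regresses directly on the numeric codes 0..K-1 (the default —
the grades are ordered severities), ``"one-vs-rest"`` fits one indicator
regression per class and retains a feature if any per-class coefficient is
nonzero.  Hyperparameters may be fixed (the reference operating point is
alpha=0.7, lam=0.00178) or chosen on a grid by 5-fold cross-validation,
maximizing mean held-out performance with ties broken toward the stronger
penalty (larger lam, then larger alpha).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold, StratifiedKFold

from .data import FeatureMatrix

__all__ = ["ENConfig", "ENResult", "en_loss", "fit_elastic_net",
           "select_hyperparameters", "prescreen",
           "DEFAULT_ALPHA_GRID", "default_lam_grid"]

#: l1-ratio candidates for cross-validated selection.
DEFAULT_ALPHA_GRID = (0.1, 0.5, 0.7, 0.9, 0.95, 0.99, 1.0)

#: Coefficient magnitude above which a feature counts as retained.
NONZERO_TOL = 1e-8


def default_lam_grid() -> np.ndarray:
    """50 log-spaced regularization strengths spanning 1e-5 .. 1e2."""
    return np.logspace(-5, 2, 50)


@dataclass
class ENConfig:
    """Elastic-net pre-screening configuration.

    With ``search=False`` the fixed ``(alpha, lam)`` pair is used; with
    ``search=True`` the grids are scanned by ``cv_folds``-fold CV.
    """

    alpha: float = 0.7
    lam: float = 0.00178
    search: bool = False
    alpha_grid: tuple[float, ...] | None = None
    lam_grid: tuple[float, ...] | None = None
    cv_folds: int = 5
    max_iter: int = 10000
    tol: float = 1e-4
    response_mode: str = "ordinal"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.response_mode not in ("ordinal", "one-vs-rest"):
            raise ValueError("response_mode must be 'ordinal' or 'one-vs-rest'")

    def grids(self) -> tuple[np.ndarray, np.ndarray]:
        a = np.asarray(self.alpha_grid if self.alpha_grid is not None
                       else DEFAULT_ALPHA_GRID, dtype=float)
        l = np.asarray(self.lam_grid if self.lam_grid is not None
                       else default_lam_grid(), dtype=float)
        if a.size == 0 or l.size == 0:
            raise ValueError("hyperparameter grids must be non-empty")
        return a, l


@dataclass
class ENResult:
    """Fitted coefficients and the retained feature set.

    ``coefficients`` has shape ``(N,)`` in ordinal mode, ``(K, N)`` in
    one-vs-rest mode.  ``L_t`` is the retained count — the size of the
    wrapper search space.
    """

    coefficients: np.ndarray
    intercept: np.ndarray
    alpha: float
    lam: float
    retained_mask: np.ndarray
    retained_names: list[str] = field(default_factory=list)

    @property
    def L_t(self) -> int:
        return int(self.retained_mask.sum())

    @property
    def retained_indices(self) -> np.ndarray:
        return np.flatnonzero(self.retained_mask)


def en_loss(X, y, beta, intercept, alpha, lam) -> float:
    """Elastic-net objective: half mean squared error plus the mixed penalty."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))
            and np.all(np.isfinite(beta)) and np.isfinite(intercept)):
        raise ValueError("non-finite inputs")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    m = X.shape[0]
    resid = y - (X @ beta + intercept)
    mse_half = float(resid @ resid) / (2.0 * m)
    penalty = lam * (alpha * np.abs(beta).sum()
                     + 0.5 * (1.0 - alpha) * float(beta @ beta))
    return mse_half + penalty


def fit_elastic_net(X, y, alpha: float, lam: float,
                    max_iter: int = 10000, tol: float = 1e-4,
                    strict: bool = True):
    """Minimize the elastic-net loss; returns ``(beta, intercept)``.

    With ``strict`` (the default) raises ``RuntimeError`` carrying the
    iteration count if coordinate descent does not converge within
    ``max_iter``; hyperparameter CV uses ``strict=False`` so extreme grid
    points score with their approximate solution instead of aborting the
    scan.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam == 0.0:
        # unpenalized least squares (closed form via lstsq)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        intercept = float(y.mean() - X.mean(axis=0) @ beta)
        return beta, intercept
    model = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=True,
                       max_iter=max_iter, tol=tol)
    with warnings.catch_warnings():
        if strict:
            warnings.simplefilter("error", ConvergenceWarning)
        else:
            warnings.simplefilter("ignore", ConvergenceWarning)
        try:
            model.fit(X, y)
        except ConvergenceWarning as exc:
            raise RuntimeError(
                f"elastic net did not converge within {max_iter} iterations"
            ) from exc
    return model.coef_.copy(), float(model.intercept_)


def _responses(labels: np.ndarray, mode: str) -> np.ndarray:
    """Response matrix, one column per regression problem."""
    if mode == "ordinal":
        return labels.astype(float)[:, None]
    classes = np.unique(labels)
    return (labels[:, None] == classes[None, :]).astype(float)


def _fit_all(X, labels, alpha, lam, config):
    ys = _responses(labels, config.response_mode)
    coefs, intercepts = [], []
    for j in range(ys.shape[1]):
        beta, b0 = fit_elastic_net(X, ys[:, j], alpha, lam,
                                   config.max_iter, config.tol)
        coefs.append(beta)
        intercepts.append(b0)
    coef = np.asarray(coefs)
    if config.response_mode == "ordinal":
        coef = coef[0]
    return coef, np.asarray(intercepts)


def _cv_score(X, labels, alpha, lam, config, seed) -> float:
    """Mean held-out performance: negative squared error (ordinal) or
    accuracy (one-vs-rest)."""
    if config.response_mode == "ordinal":
        splitter = KFold(config.cv_folds, shuffle=True, random_state=seed)
        strata = None
    else:
        splitter = StratifiedKFold(config.cv_folds, shuffle=True,
                                   random_state=seed)
        strata = labels
        counts = np.bincount(labels)
        if counts.min() < config.cv_folds:
            raise ValueError(
                "a class has fewer members than cv_folds; cannot stratify")
    scores = []
    for tr, te in splitter.split(X, strata):
        if config.response_mode == "ordinal":
            beta, b0 = fit_elastic_net(X[tr], labels[tr].astype(float),
                                       alpha, lam, config.max_iter,
                                       config.tol, strict=False)
            resid = labels[te].astype(float) - (X[te] @ beta + b0)
            scores.append(-float(np.mean(resid ** 2)))
        else:
            classes = np.unique(labels)
            preds = np.column_stack([
                X[te] @ beta + b0
                for beta, b0 in (fit_elastic_net(
                    X[tr], (labels[tr] == c).astype(float), alpha, lam,
                    config.max_iter, config.tol, strict=False)
                    for c in classes)
            ])
            pred_labels = classes[np.argmax(preds, axis=1)]
            scores.append(float(np.mean(pred_labels == labels[te])))
    return float(np.mean(scores))


def select_hyperparameters(X, labels, config: ENConfig,
                           seed: int) -> tuple[float, float]:
    """Grid search maximizing mean held-out performance over ``cv_folds``
    folds; ties broken toward larger lam, then larger alpha."""
    alpha_grid, lam_grid = config.grids()
    best = None
    for alpha in alpha_grid:
        for lam in lam_grid:
            score = _cv_score(X, labels, float(alpha), float(lam), config, seed)
            key = (score, float(lam), float(alpha))
            if best is None or key > best[0]:
                best = (key, float(alpha), float(lam))
    return best[1], best[2]


def prescreen(data: FeatureMatrix, config: ENConfig | None = None,
              seed: int = 0) -> ENResult:
    """Run elastic-net pre-screening on a (normalized) feature table.

    Returns the fitted coefficients and the retained mask; the wrapper
    search space downstream is exactly the retained indices.  Raises if no
    feature survives (advice: reduce ``lam``).
    """
    config = config or ENConfig()
    if data.n_classes < 2:
        raise ValueError("need at least 2 classes for supervised screening")
    X = data.values
    if config.search:
        alpha, lam = select_hyperparameters(X, data.labels, config, seed)
    else:
        alpha, lam = config.alpha, config.lam
    coef, intercept = _fit_all(X, data.labels, alpha, lam, config)
    mags = np.abs(coef) if coef.ndim == 1 else np.abs(coef).max(axis=0)
    retained = mags > NONZERO_TOL
    if not retained.any():
        raise ValueError(
            f"no features retained at lam={lam:g}; reduce lam")
    return ENResult(
        coefficients=coef,
        intercept=intercept,
        alpha=alpha,
        lam=lam,
        retained_mask=retained,
        retained_names=[data.feature_names[i] for i in np.flatnonzero(retained)],
    )
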