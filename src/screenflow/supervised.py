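"""Class-balanced supervised learning with precision/recall evaluation.

The binomial GLM is fitted by iteratively reweighted least squares with each
iteration streaming X'WX and X'Wz as partition-wise reductions, so it scales
to chunked tables of any length. Random forests and gradient boosting operate
on an in-memory materialization of the balanced subsample (balancing already
downsamples to the minority class; a row cap guards memory) and are backed by
scikit-learn estimators.

Every fitter balances the classes by downsampling before fitting, and
metrics are reported on the full balanced data; predicted class is
probability >= 0.5 (natural for balanced classes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier

from .chunked import ChunkedTable, balanced_downsample, standardize
from .errors import DataError

logger = logging.getLogger(__name__)

DEFAULT_N_TREES = 20
DEFAULT_SUBSAMPLE_RATE = 0.25
DEFAULT_LEARNING_RATE = 0.1
FOREST_MAX_DEPTH = 8
GBM_MAX_DEPTH = 3
TREE_ROW_CAP = 1_000_000
SEPARATION_BOUND = 30.0


@dataclass
class RegressionResult:
    method: str
    precision: float
    recall: float
    balanced_n: int                     # rows per class after downsampling
    seed: int = 0
    coefficients: np.ndarray | None = None      # GLM: (p+1,), intercept first
    std_errors: np.ndarray | None = None
    feature_names: list[str] = field(default_factory=list)
    n_trees: int | None = None
    subsample_rate: float | None = None
    converged: bool = True
    separation_warning: bool = False
    feature_importances: np.ndarray | None = None
    scores: np.ndarray | None = None    # fitted P(y=1) on the balanced rows
    y_true: np.ndarray | None = None
    model: object | None = None


def evaluate(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """Precision and recall with positive class = 1.

    An undefined ratio (empty denominator) is reported as 0 with a warning.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    if tp + fp == 0:
        logger.warning("no positive predictions: precision undefined, using 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        logger.warning("no positive truths: recall undefined, using 0")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    return precision, recall


def _check_binary(y: np.ndarray, response: str) -> None:
    vals = np.unique(y)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise DataError(
            f"response {response!r} must be coded 0/1, found values {vals}"
        )


def _balance(table: ChunkedTable, response: str, balance: bool, seed: int
             ) -> tuple[ChunkedTable, int]:
    if balance:
        table = balanced_downsample(table, response, seed)
    y = table.column(response)
    n_pos = int((y == 1).sum())
    return table, (n_pos if balance else min(n_pos, int((y == 0).sum())))


# ---------------------------------------------------------------------------
# GLM via streaming IRLS
# ---------------------------------------------------------------------------


def fit_glm(
    table: ChunkedTable,
    response: str,
    family: str = "binomial",
    max_iter: int = 50,
    tol: float = 1e-8,
    balance: bool = True,
    standardize_features: bool = True,
    seed: int = 0,
) -> RegressionResult:
    """Generalized linear model by iteratively reweighted least squares.

    Features are standardized before fitting and coefficients reported on the
    standardized scale. Each IRLS iteration streams the weighted normal
    equations; the (p+1)-dimensional system is solved densely. Divergent
    coefficients (|beta| > 30 on standardized features) raise a perfect-
    separation warning flag; a singular system falls back to a 1e-8 ridge.
    """
    if family not in ("binomial", "gaussian"):
        raise DataError(f"unknown family {family!r}")
    feat_names = [c for c in table.column_names if c != response]
    if len(feat_names) == len(table.column_names):
        raise DataError(f"response column {response!r} not in table")

    if family == "binomial":
        _check_binary(table.column(response), response)
        table, balanced_n = _balance(table, response, balance, seed)
    else:
        balance = False
        balanced_n = table.n_rows

    y_col = table.column(response)
    feats = table.select(feat_names) if feat_names else None
    if feats is not None and standardize_features:
        feats = standardize(feats, with_std=True)
    p = len(feat_names)
    n = table.n_rows

    def design_blocks():
        if feats is None:
            start = 0
            for _ in range(1):
                yield np.ones((n, 1)), y_col
            return
        start = 0
        for block in feats.iter_partitions():
            r = block.shape[0]
            yield np.column_stack([np.ones(r), block]), y_col[start : start + r]
            start += r

    beta = np.zeros(p + 1)
    converged = False
    if family == "gaussian":
        xtx = np.zeros((p + 1, p + 1))
        xty = np.zeros(p + 1)
        for xb, yb in design_blocks():
            xtx += xb.T @ xb
            xty += xb.T @ yb
        beta = _solve(xtx, xty)
        converged = True
    else:
        for _ in range(max_iter):
            xtwx = np.zeros((p + 1, p + 1))
            xtwz = np.zeros(p + 1)
            for xb, yb in design_blocks():
                eta = xb @ beta
                mu = expit(eta)
                w = np.maximum(mu * (1.0 - mu), 1e-10)
                z = eta + (yb - mu) / w
                xw = xb * w[:, None]
                xtwx += xw.T @ xb
                xtwz += xw.T @ z
            beta_new = _solve(xtwx, xtwz)
            delta = float(np.max(np.abs(beta_new - beta)))
            beta = beta_new
            if delta < tol:
                converged = True
                break
        if not converged:
            logger.warning("glm irls did not converge in %d iterations",
                           max_iter)

    separation = bool(np.any(np.abs(beta) > SEPARATION_BOUND))
    if separation:
        logger.warning("possible perfect separation: max |beta| = %g",
                       float(np.max(np.abs(beta))))

    # observed information for standard errors (binomial) / residual-based (gaussian)
    xtwx = np.zeros((p + 1, p + 1))
    scores = np.empty(n)
    start = 0
    rss = 0.0
    for xb, yb in design_blocks():
        eta = xb @ beta
        if family == "binomial":
            mu = expit(eta)
            w = np.maximum(mu * (1.0 - mu), 1e-10)
            xtwx += (xb * w[:, None]).T @ xb
        else:
            mu = eta
            xtwx += xb.T @ xb
            rss += float(((yb - mu) ** 2).sum())
        scores[start : start + xb.shape[0]] = mu
        start += xb.shape[0]
    cov = np.linalg.inv(xtwx + 1e-12 * np.eye(p + 1))
    if family == "gaussian":
        cov = cov * (rss / max(n - p - 1, 1))
    std_errors = np.sqrt(np.clip(np.diag(cov), 0, None))

    if family == "binomial":
        y_pred = (scores >= 0.5).astype(int)
        precision, recall = evaluate(y_col, y_pred)
    else:
        precision = recall = float("nan")
    return RegressionResult(
        method="glm",
        precision=precision,
        recall=recall,
        balanced_n=balanced_n,
        seed=seed,
        coefficients=beta,
        std_errors=std_errors,
        feature_names=["intercept"] + feat_names,
        converged=converged,
        separation_warning=separation,
        scores=scores,
        y_true=y_col,
    )


def _solve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(a, b)
    except np.linalg.LinAlgError:
        logger.warning("singular system in irls; applying 1e-8 ridge")
        return np.linalg.solve(a + 1e-8 * np.eye(a.shape[0]), b)


# ---------------------------------------------------------------------------
# Tree ensembles
# ---------------------------------------------------------------------------


def _materialize_xy(table: ChunkedTable, response: str
                    ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    feat_names = [c for c in table.column_names if c != response]
    if len(feat_names) == len(table.column_names):
        raise DataError(f"response column {response!r} not in table")
    if table.n_rows > TREE_ROW_CAP:
        raise DataError(
            f"balanced table has {table.n_rows} rows, above the in-memory "
            f"tree cap of {TREE_ROW_CAP}; reduce the input"
        )
    x = table.select(feat_names).materialize()
    y = table.column(response).astype(int)
    return x, y, feat_names


def fit_forest(
    table: ChunkedTable,
    response: str,
    n_trees: int = DEFAULT_N_TREES,
    subsample_rate: float = DEFAULT_SUBSAMPLE_RATE,
    max_depth: int = FOREST_MAX_DEPTH,
    seed: int = 0,
    balance: bool = True,
) -> RegressionResult:
    """Random forest: ``n_trees`` Gini trees, sqrt(p) feature subsampling at
    each split, each tree grown on a seeded row subsample of the stated rate
    (rate 1.0 uses the full sample), majority vote."""
    if not 0 < subsample_rate <= 1:
        raise DataError(f"subsample_rate must be in (0, 1]: {subsample_rate}")
    _check_binary(table.column(response), response)
    table, balanced_n = _balance(table, response, balance, seed)
    x, y, feat_names = _materialize_xy(table, response)
    model = RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=max_depth,
        max_features="sqrt",
        criterion="gini",
        bootstrap=subsample_rate < 1.0,
        max_samples=subsample_rate if subsample_rate < 1.0 else None,
        random_state=seed,
        n_jobs=1,
    )
    model.fit(x, y)
    scores = model.predict_proba(x)[:, list(model.classes_).index(1)]
    precision, recall = evaluate(y, (scores >= 0.5).astype(int))
    return RegressionResult(
        method="forest",
        precision=precision,
        recall=recall,
        balanced_n=balanced_n,
        seed=seed,
        feature_names=feat_names,
        n_trees=len(model.estimators_),
        subsample_rate=subsample_rate,
        feature_importances=model.feature_importances_,
        scores=scores,
        y_true=y.astype(float),
        model=model,
    )


def fit_gbm(
    table: ChunkedTable,
    response: str,
    n_trees: int = DEFAULT_N_TREES,
    subsample_rate: float = DEFAULT_SUBSAMPLE_RATE,
    learning_rate: float = DEFAULT_LEARNING_RATE,
    max_depth: int = GBM_MAX_DEPTH,
    seed: int = 0,
    balance: bool = True,
) -> RegressionResult:
    """Gradient boosting: stagewise shallow regression trees on the logistic
    gradient, each stage on a seeded subsample of the stated rate; prediction
    by the accumulated score thresholded at 0 (probability 0.5)."""
    if not 0 < subsample_rate <= 1:
        raise DataError(f"subsample_rate must be in (0, 1]: {subsample_rate}")
    _check_binary(table.column(response), response)
    table, balanced_n = _balance(table, response, balance, seed)
    x, y, feat_names = _materialize_xy(table, response)
    model = GradientBoostingClassifier(
        n_estimators=n_trees,
        subsample=subsample_rate,
        learning_rate=learning_rate,
        max_depth=max_depth,
        random_state=seed,
    )
    model.fit(x, y)
    scores = model.predict_proba(x)[:, list(model.classes_).index(1)]
    precision, recall = evaluate(y, (scores >= 0.5).astype(int))
    return RegressionResult(
        method="gbm",
        precision=precision,
        recall=recall,
        balanced_n=balanced_n,
        seed=seed,
        feature_names=feat_names,
        n_trees=model.n_estimators_,
        subsample_rate=subsample_rate,
        feature_importances=model.feature_importances_,
        scores=scores,
        y_true=y.astype(float),
        model=model,
    )
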