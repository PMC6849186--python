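"""Scalable dimension reduction over chunked tables.

All five methods consume a :class:`~screenflow.chunked.ChunkedTable` through
streaming map-reduce passes, so they apply unchanged to tables far larger
than memory:

* **PCA** — eigendecomposition of the streamed covariance matrix.
* **Factor analysis** — EM for the linear-Gaussian factor model
  ``x = W z + eps`` with diagonal noise. The E-step reductions depend on the
  data only through the sample covariance, so after a single data pass the EM
  iterations run entirely in feature space.
* **Kernel PCA** — Gaussian-kernel PCA approximated by a randomized
  trigonometric (Fourier-type) feature map; an exact n-by-n kernel matrix
  would contradict the chunked computation model.
* **ICA** — fixed-point negentropy maximization with the log-cosh contrast,
  per-iteration expectations reduced partition-wise, symmetric decorrelation
  each step.
* **LDA** — between/within-class scatter accumulated in one streaming pass,
  then a dense generalized eigenproblem in feature space.

Sign convention: every loading / unmixing column is flipped so its
largest-magnitude entry is positive, making outputs comparable across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .chunked import ChunkedTable, MomentAccumulator, column_moments
from .errors import DataError

logger = logging.getLogger(__name__)

DEFAULT_MAX_ITER = 100
DEFAULT_TOL = 1e-4
FA_PSI_FLOOR = 1e-6
LDA_RIDGE = 1e-6


@dataclass
class DimRedResult:
    """Fitted dimension reduction with transformed scores.

    ``loadings`` has one column per component; rows index input features
    (for kpca: the randomized feature map's dimensions). ``explained`` is the
    per-component diagnostic: eigenvalues/variance shares for PCA/kPCA/LDA,
    the log-likelihood trace for FA, unit placeholders for ICA.
    """

    method: str
    loadings: np.ndarray
    transformed: ChunkedTable
    explained: np.ndarray
    n_components: int
    converged: bool = True
    extra: dict = field(default_factory=dict)


@dataclass
class FactorModel:
    """Linear-Gaussian factor model ``x = W z + eps``, diagonal noise Psi."""

    loadings: np.ndarray          # (p, k)
    psi: np.ndarray               # (p,) positive noise variances
    mean: np.ndarray              # (p,)
    loglik_trace: list[float]
    converged: bool


def _fix_signs(m: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    m = np.array(m, copy=True)
    for j in range(m.shape[1]):
        i = int(np.argmax(np.abs(m[:, j])))
        if m[i, j] < 0:
            m[:, j] = -m[:, j]
    return m


def _project(table: ChunkedTable, mean: np.ndarray, basis: np.ndarray,
             names: list[str]) -> ChunkedTable:
    """Stream ``(X - mean) @ basis`` preserving the partitioning."""
    return ChunkedTable(
        names, [(b - mean) @ basis for b in table.iter_partitions()]
    )


def _component_names(method: str, k: int) -> list[str]:
    return [f"{method}_{j + 1}" for j in range(k)]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def fit_pca(table: ChunkedTable, k: int) -> DimRedResult:
    """Principal component analysis from the streamed covariance.

    Components are ordered by descending eigenvalue; scores are the centered
    data projected on the top-k eigenvectors.
    """
    p = table.n_columns
    if k > p:
        raise DataError(f"k={k} exceeds the {p} available features")
    acc = column_moments(table)
    if acc.n < 2:
        raise DataError("pca needs at least 2 rows")
    eigvals, eigvecs = scipy.linalg.eigh(acc.covariance)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = _fix_signs(eigvecs[:, order])
    loadings = eigvecs[:, :k]
    total = eigvals.sum()
    shares = eigvals / total if total > 0 else np.zeros_like(eigvals)
    transformed = _project(
        table, acc.mean, loadings, _component_names("pca", k)
    )
    return DimRedResult(
        method="pca",
        loadings=loadings,
        transformed=transformed,
        explained=eigvals[:k],
        n_components=k,
        extra={
            "mean": acc.mean,
            "eigenvalues": eigvals,
            "variance_shares": shares[:k],
            "all_variance_shares": shares,
        },
    )


# ---------------------------------------------------------------------------
# Factor analysis
# ---------------------------------------------------------------------------


def _fa_loglik(S: np.ndarray, W: np.ndarray, psi: np.ndarray, n: int) -> float:
    p = S.shape[0]
    sigma = W @ W.T + np.diag(psi)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return -np.inf
    tr = np.trace(np.linalg.solve(sigma, S))
    return -0.5 * n * (p * np.log(2 * np.pi) + logdet + tr)


def fit_factor_analysis(
    table: ChunkedTable,
    k: int,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> tuple[FactorModel, DimRedResult]:
    """EM for the factor model; stops when the log-likelihood gain < tol.

    Initialization: W from PCA loadings scaled by sqrt(eigenvalues), Psi from
    the residual variances. Psi is floored at 1e-6 to avoid Heywood collapse.
    Returns the model together with a result whose transformed table holds
    the posterior mean factors E[z | x].
    """
    p = table.n_columns
    if k >= p:
        raise DataError(f"factor analysis requires k < n_features ({k} >= {p})")
    acc = column_moments(table)
    n, mean = acc.n, acc.mean
    S = acc.covariance

    eigvals, eigvecs = scipy.linalg.eigh(S)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = np.clip(eigvals[order], 0, None), eigvecs[:, order]
    W = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    psi = np.maximum(np.diag(S) - np.sum(W**2, axis=1), FA_PSI_FLOOR)

    trace = [_fa_loglik(S, W, psi, n)]
    converged = False
    for _ in range(max_iter):
        # E-step in feature space: beta = G W^T Psi^-1, G = (I + W^T Psi^-1 W)^-1
        wp = W / psi[:, None]                       # Psi^-1 W, (p, k)
        G = np.linalg.inv(np.eye(k) + W.T @ wp)
        beta = G @ wp.T                             # (k, p)
        Ezz = G + beta @ S @ beta.T                 # E[z z^T] / n
        W = np.linalg.solve(Ezz.T, (S @ beta.T).T).T
        psi = np.maximum(np.diag(S - W @ (beta @ S)), FA_PSI_FLOOR)
        trace.append(_fa_loglik(S, W, psi, n))
        if trace[-1] - trace[-2] < tol:
            converged = True
            break
    if not converged:
        logger.warning("factor analysis did not converge in %d iterations",
                       max_iter)

    W = _fix_signs(W)
    wp = W / psi[:, None]
    beta = np.linalg.inv(np.eye(k) + W.T @ wp) @ wp.T
    transformed = _project(
        table, mean, beta.T, _component_names("fa", k)
    )
    model = FactorModel(W, psi, mean, trace, converged)
    result = DimRedResult(
        method="fa",
        loadings=W,
        transformed=transformed,
        explained=np.asarray(trace),
        n_components=k,
        converged=converged,
        extra={"psi": psi, "mean": mean},
    )
    return model, result


# ---------------------------------------------------------------------------
# Kernel PCA via randomized trigonometric features
# ---------------------------------------------------------------------------


def fourier_feature_map(
    p: int, n_fourier: int, gamma: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the random map for the Gaussian kernel exp(-gamma ||x-y||^2).

    Returns frequencies ``omega`` (p, n_fourier) sampled from the kernel's
    spectral distribution N(0, 2*gamma I) and phases ``b`` ~ U[0, 2*pi).
    """
    if gamma <= 0:
        raise DataError(f"gamma must be positive, got {gamma}")
    rng = np.random.default_rng(seed)
    omega = rng.normal(0.0, np.sqrt(2.0 * gamma), size=(p, n_fourier))
    b = rng.uniform(0.0, 2.0 * np.pi, size=n_fourier)
    return omega, b


def apply_feature_map(
    x: np.ndarray, omega: np.ndarray, b: np.ndarray
) -> np.ndarray:
    """z(x) = sqrt(2/D) cos(x omega + b); E[z(x)^T z(y)] is the kernel."""
    d = omega.shape[1]
    return np.sqrt(2.0 / d) * np.cos(np.asarray(x) @ omega + b)


def fit_kpca(
    table: ChunkedTable,
    k: int,
    n_fourier: int = 200,
    gamma: float | None = None,
    seed: int = 0,
) -> DimRedResult:
    """Approximate Gaussian-kernel PCA.

    Maps each partition through a seeded randomized trigonometric feature
    map of dimension ``n_fourier``, then runs streaming PCA in feature
    space; the transformed table holds the top-k feature-space scores.
    ``gamma`` defaults to 1/n_features.
    """
    p = table.n_columns
    if gamma is None:
        gamma = 1.0 / p
    if n_fourier < k:
        raise DataError(f"n_fourier={n_fourier} must be >= k={k}")
    omega, b = fourier_feature_map(p, n_fourier, gamma, seed)
    feature_table = ChunkedTable(
        [f"rff_{j}" for j in range(n_fourier)],
        [apply_feature_map(block, omega, b) for block in table.iter_partitions()],
    )
    inner = fit_pca(feature_table, k)
    transformed = ChunkedTable(
        _component_names("kpca", k), inner.transformed.partitions
    )
    return DimRedResult(
        method="kpca",
        loadings=inner.loadings,
        transformed=transformed,
        explained=inner.explained,
        n_components=k,
        extra={
            "omega": omega, "phases": b, "gamma": gamma,
            "feature_mean": inner.extra["mean"],
            "variance_shares": inner.extra["variance_shares"],
        },
    )


# ---------------------------------------------------------------------------
# ICA
# ---------------------------------------------------------------------------


def _sym_decorrelate(w: np.ndarray) -> np.ndarray:
    """W <- (W W^T)^(-1/2) W, making the rows orthonormal."""
    vals, vecs = scipy.linalg.eigh(w @ w.T)
    vals = np.clip(vals, 1e-12, None)
    return (vecs * (1.0 / np.sqrt(vals))) @ vecs.T @ w


def fit_ica(
    table: ChunkedTable,
    k: int,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int = 0,
) -> DimRedResult:
    """Fixed-point ICA with the log-cosh contrast over chunked data.

    The data are whitened to k dimensions via streaming PCA; the fixed-point
    update's expectations E[g(w x) x^T] and E[g'(w x)] are accumulated per
    partition and reduced, and the unmixing rows are re-orthonormalized by
    symmetric decorrelation each step.
    """
    p = table.n_columns
    if k > p:
        raise DataError(f"k={k} exceeds the {p} available features")
    acc = column_moments(table)
    n, mean = acc.n, acc.mean
    eigvals, eigvecs = scipy.linalg.eigh(acc.covariance)
    order = np.argsort(eigvals)[::-1][:k]
    eigvals = eigvals[order]
    if np.any(eigvals <= 1e-12):
        raise DataError("data covariance is rank-deficient; reduce k")
    whiten = eigvecs[:, order] / np.sqrt(eigvals)      # (p, k)

    rng = np.random.default_rng(seed)
    W = _sym_decorrelate(rng.normal(size=(k, k)))
    converged = False
    for _ in range(max_iter):
        # streamed expectations of the log-cosh contrast derivative
        exT = np.zeros((k, k))
        eg = np.zeros(k)
        for block in table.iter_partitions():
            xw = (block - mean) @ whiten               # whitened rows
            s = xw @ W.T
            g = np.tanh(s)
            exT += g.T @ xw
            eg += (1.0 - g**2).sum(axis=0)
        W_new = _sym_decorrelate(exT / n - (eg / n)[:, None] * W)
        delta = float(np.max(np.abs(np.abs(np.einsum("ij,ij->i", W_new, W)) - 1)))
        W = W_new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("ica did not converge in %d iterations", max_iter)

    unmixing = W @ whiten.T                            # (k, p), on raw scale
    unmixing = _fix_signs(unmixing.T).T
    transformed = _project(
        table, mean, unmixing.T, _component_names("ica", k)
    )
    return DimRedResult(
        method="ica",
        loadings=unmixing.T,
        transformed=transformed,
        explained=np.ones(k),
        n_components=k,
        converged=converged,
        extra={"whitening": whiten, "mean": mean, "unmixing": unmixing},
    )


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------


def fit_lda(table: ChunkedTable, label: str, k: int) -> DimRedResult:
    """Fisher discriminant projections maximizing between/within scatter.

    Per-class counts, sums and the total cross-product matrix are accumulated
    in one streaming pass; the discriminant directions solve the generalized
    eigenproblem S_b v = lambda S_w v. A singular within-class scatter is
    ridge-regularized by 1e-6 * trace / n_features.
    """
    feat_names = [c for c in table.column_names if c != label]
    if len(feat_names) == len(table.column_names):
        raise DataError(f"label column {label!r} not in table")
    li = table.column_names.index(label)
    fi = [table.column_names.index(c) for c in feat_names]
    p = len(feat_names)

    total = MomentAccumulator.empty(p)
    by_class: dict[float, tuple[int, np.ndarray]] = {}
    for block in table.iter_partitions():
        x = block[:, fi]
        y = block[:, li]
        total = total.merge(MomentAccumulator.from_partition(x))
        for value in np.unique(y):
            rows = x[y == value]
            n_c, s_c = by_class.get(float(value), (0, np.zeros(p)))
            by_class[float(value)] = (n_c + rows.shape[0], s_c + rows.sum(axis=0))

    classes = sorted(by_class)
    C = len(classes)
    if C < 2:
        raise DataError("lda needs at least 2 classes")
    if k > C - 1:
        raise DataError(f"k={k} exceeds the discriminant rank C-1={C - 1}")

    n = total.n
    grand_mean = total.mean
    Sw = total.sum_xxT.copy()
    Sb = np.zeros((p, p))
    for value in classes:
        n_c, s_c = by_class[value]
        mu_c = s_c / n_c
        Sw -= n_c * np.outer(mu_c, mu_c)
        d = mu_c - grand_mean
        Sb += n_c * np.outer(d, d)

    try:
        eigvals, eigvecs = scipy.linalg.eigh(Sb, Sw)
    except scipy.linalg.LinAlgError:
        ridge = LDA_RIDGE * np.trace(Sw) / p
        logger.warning("within-class scatter singular; adding ridge %g", ridge)
        eigvals, eigvecs = scipy.linalg.eigh(Sb, Sw + ridge * np.eye(p))
    order = np.argsort(eigvals)[::-1][:k]
    directions = _fix_signs(eigvecs[:, order])

    features_only = table.select(feat_names)
    transformed = _project(
        features_only, grand_mean, directions, _component_names("lda", k)
    )
    return DimRedResult(
        method="lda",
        loadings=directions,
        transformed=transformed,
        explained=eigvals[order],
        n_components=k,
        extra={
            "classes": np.asarray(classes),
            "class_means": np.vstack([by_class[c][1] / by_class[c][0]
                                      for c in classes]),
            "grand_mean": grand_mean,
            "feature_names": feat_names,
        },
    )
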