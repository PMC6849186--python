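"""k-means and Gaussian-mixture clustering over chunked tables.

Both fitters stream: assignments/responsibilities and the sufficient
statistics for the center/parameter updates are accumulated per partition and
reduced, so memory stays at one row block plus O(K * n_columns) state.
``sweep_and_select`` fits every requested center count and adjudicates the
sweep by BIC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .chunked import ChunkedTable, column_moments
from .errors import DataError

logger = logging.getLogger(__name__)

GMM_VAR_FLOOR = 1e-6
GMM_WEIGHT_FLOOR = 1e-8


@dataclass
class KMeansFit:
    K: int
    centers: np.ndarray                 # (K, p)
    assignments: np.ndarray             # (n,) int in [0, K)
    objective: float                    # within-cluster SSE at convergence
    objective_trace: list[float]
    counts: np.ndarray                  # (K,)
    n_iter: int
    converged: bool
    bic: float = np.nan
    n_params: int = 0
    seed: int = 0


@dataclass
class GMMFit:
    K: int
    means: np.ndarray                   # (K, p)
    variances: np.ndarray               # (K, p) diagonal covariances
    weights: np.ndarray                 # (K,), sums to 1
    assignments: np.ndarray             # (n,) argmax responsibility
    loglik: float
    loglik_trace: list[float]
    n_iter: int
    converged: bool
    bic: float = np.nan
    n_params: int = 0
    seed: int = 0


@dataclass
class ClusteringResult:
    method: str
    per_K_fits: dict[int, object] = field(default_factory=dict)
    best_K: int = 0
    seed: int = 0

    @property
    def selection_table(self) -> list[tuple[int, float, float]]:
        """(K, objective, BIC) rows for every fitted center count."""
        rows = []
        for K in sorted(self.per_K_fits):
            fit = self.per_K_fits[K]
            obj = fit.objective if isinstance(fit, KMeansFit) else fit.loglik
            rows.append((K, float(obj), float(fit.bic)))
        return rows


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------


def _closest_sq_dist(block: np.ndarray, centers: np.ndarray) -> np.ndarray:
    d2 = (
        (block**2).sum(axis=1)[:, None]
        - 2.0 * block @ centers.T
        + (centers**2).sum(axis=1)[None, :]
    )
    return np.clip(d2.min(axis=1), 0.0, None)


def _kmeanspp_init(table: ChunkedTable, K: int, rng: np.random.Generator
                   ) -> np.ndarray:
    """Careful seeding: each new center sampled with probability proportional
    to its squared distance from the nearest existing center.

    Implemented with two streaming passes per center (total mass, then an
    inverse-CDF walk), keeping memory independent of n_rows.
    """
    n = table.n_rows
    first = int(rng.integers(n))
    centers = [_row_at(table, first)]
    for _ in range(1, K):
        total = 0.0
        for block in table.iter_partitions():
            total += _closest_sq_dist(block, np.vstack(centers)).sum()
        if total <= 0:           # all points coincide with a center
            centers.append(centers[0].copy())
            continue
        u = rng.uniform(0.0, total)
        acc = 0.0
        chosen = None
        for block in table.iter_partitions():
            d2 = _closest_sq_dist(block, np.vstack(centers))
            c = acc + np.cumsum(d2)
            hit = np.searchsorted(c, u, side="right")
            if hit < d2.size:
                chosen = block[hit].copy()
                break
            acc = c[-1]
        if chosen is None:       # numerical edge: u == total
            chosen = block[-1].copy()
        centers.append(chosen)
    return np.vstack(centers)


def _row_at(table: ChunkedTable, index: int) -> np.ndarray:
    start = 0
    for block in table.iter_partitions():
        if index < start + block.shape[0]:
            return block[index - start].copy()
        start += block.shape[0]
    raise IndexError(index)


def _farthest_row(table: ChunkedTable, centers: np.ndarray) -> np.ndarray:
    best, best_d = None, -1.0
    for block in table.iter_partitions():
        d2 = _closest_sq_dist(block, centers)
        i = int(np.argmax(d2))
        if d2[i] > best_d:
            best_d, best = float(d2[i]), block[i].copy()
    return best


def fit_kmeans(
    table: ChunkedTable,
    K: int,
    max_iter: int = 100,
    seed: int = 0,
) -> KMeansFit:
    """Lloyd's algorithm with distance-proportional (k-means++) seeding.

    Stops when the assignments stabilize or after ``max_iter`` rounds. An
    empty cluster is re-seeded from the point farthest from all centers.
    """
    n, p = table.n_rows, table.n_columns
    if K > n:
        raise DataError(f"K={K} exceeds n_rows={n}")
    rng = np.random.default_rng(seed)
    centers = _kmeanspp_init(table, K, rng)

    assignments = np.full(n, -1, dtype=int)
    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        sums = np.zeros((K, p))
        counts = np.zeros(K, dtype=int)
        sse = 0.0
        new_assign = np.empty(n, dtype=int)
        start = 0
        for block in table.iter_partitions():
            d2 = (
                (block**2).sum(axis=1)[:, None]
                - 2.0 * block @ centers.T
                + (centers**2).sum(axis=1)[None, :]
            )
            lab = np.argmin(d2, axis=1)
            sse += float(np.clip(d2[np.arange(block.shape[0]), lab], 0, None).sum())
            np.add.at(sums, lab, block)
            np.add.at(counts, lab, 1)
            new_assign[start : start + block.shape[0]] = lab
            start += block.shape[0]
        trace.append(sse)

        empty = np.flatnonzero(counts == 0)
        if empty.size:
            logger.info("re-seeding %d empty cluster(s)", empty.size)
            for j in empty:
                centers[j] = _farthest_row(table, centers)
            assignments = new_assign
            continue
        if np.array_equal(new_assign, assignments):
            converged = True
            assignments = new_assign
            break
        assignments = new_assign
        centers = sums / counts[:, None]

    counts = np.bincount(assignments, minlength=K)
    # final centers consistent with the final assignments
    if counts.min() > 0:
        sums = np.zeros((K, p))
        start = 0
        for block in table.iter_partitions():
            lab = assignments[start : start + block.shape[0]]
            np.add.at(sums, lab, block)
            start += block.shape[0]
        centers = sums / counts[:, None]
    return KMeansFit(
        K=K,
        centers=centers,
        assignments=assignments,
        objective=trace[-1],
        objective_trace=trace,
        counts=counts,
        n_iter=n_iter,
        converged=converged,
        seed=seed,
    )


def kmeans_bic(fit: KMeansFit, n: int, p: int) -> tuple[float, int]:
    """Spherical-Gaussian surrogate BIC for a k-means fit.

    Uses the classification likelihood with a shared spherical variance and
    mixing-proportion terms n_k * log(n_k / n); parameter count is
    K*p centers + (K-1) proportions + 1 variance.
    """
    K = fit.K
    sigma2 = max(fit.objective / (p * max(n - K, 1)), 1e-300)
    counts = fit.counts[fit.counts > 0]
    ll = (
        float((counts * np.log(counts / n)).sum())
        - 0.5 * n * p * np.log(2.0 * np.pi * sigma2)
        - 0.5 * p * (n - K)
    )
    n_params = K * p + K
    return -2.0 * ll + n_params * np.log(n), n_params


# ---------------------------------------------------------------------------
# Gaussian mixtures (diagonal covariance)
# ---------------------------------------------------------------------------


def _gmm_log_prob(block: np.ndarray, means: np.ndarray, variances: np.ndarray,
                  weights: np.ndarray) -> np.ndarray:
    """Per-row, per-component weighted log density; (rows, K)."""
    lp = np.empty((block.shape[0], means.shape[0]))
    for j in range(means.shape[0]):
        d = block - means[j]
        lp[:, j] = (
            np.log(weights[j])
            - 0.5 * np.sum(np.log(2.0 * np.pi * variances[j]))
            - 0.5 * np.sum(d * d / variances[j], axis=1)
        )
    return lp


def fit_gmm(
    table: ChunkedTable,
    K: int,
    max_iter: int = 100,
    tol: float = 1e-4,
    seed: int = 0,
) -> GMMFit:
    """EM for a diagonal-covariance Gaussian mixture.

    Initialized from a k-means fit; responsibilities and the weighted sums
    for the M-step are accumulated per partition. Stops when the
    log-likelihood gain drops below ``tol``.
    """
    n, p = table.n_rows, table.n_columns
    if K > n:
        raise DataError(f"K={K} exceeds n_rows={n}")
    if n <= K * p:
        logger.warning(
            "n_rows=%d <= K*p=%d: covariance estimates may be unstable",
            n, K * p,
        )
    km = fit_kmeans(table, K, max_iter=25, seed=seed)
    means = km.centers.copy()
    global_var = np.maximum(column_moments(table).variances, GMM_VAR_FLOOR)
    variances = np.tile(global_var, (K, 1))
    # per-cluster variances from the k-means partition where estimable
    start = 0
    ssq = np.zeros((K, p))
    for block in table.iter_partitions():
        lab = km.assignments[start : start + block.shape[0]]
        np.add.at(ssq, lab, (block - means[lab]) ** 2)
        start += block.shape[0]
    ok = km.counts > 1
    variances[ok] = np.maximum(ssq[ok] / km.counts[ok, None], GMM_VAR_FLOOR)
    weights = np.maximum(km.counts / n, GMM_WEIGHT_FLOOR)
    weights /= weights.sum()

    rng = np.random.default_rng(seed)
    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        nk = np.zeros(K)
        sx = np.zeros((K, p))
        sxx = np.zeros((K, p))
        ll = 0.0
        for block in table.iter_partitions():
            lp = _gmm_log_prob(block, means, variances, weights)
            norm = logsumexp(lp, axis=1)
            ll += float(norm.sum())
            r = np.exp(lp - norm[:, None])
            nk += r.sum(axis=0)
            sx += r.T @ block
            sxx += r.T @ (block**2)
        trace.append(ll)

        degenerate = np.flatnonzero(nk / n < GMM_WEIGHT_FLOOR)
        if degenerate.size:
            logger.info("re-initializing %d degenerate component(s)",
                        degenerate.size)
            for j in degenerate:
                means[j] = _row_at(table, int(rng.integers(n)))
                variances[j] = global_var
                nk[j] = 1.0
        keep = np.setdiff1d(np.arange(K), degenerate)
        weights = np.maximum(nk / nk.sum(), GMM_WEIGHT_FLOOR)
        weights /= weights.sum()
        means[keep] = sx[keep] / nk[keep, None]
        variances[keep] = np.maximum(
            sxx[keep] / nk[keep, None] - means[keep] ** 2, GMM_VAR_FLOOR
        )
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            converged = True
            break
    if not converged:
        logger.warning("gmm did not converge in %d iterations", max_iter)

    # final E-step for assignments and the reported log-likelihood
    assignments = np.empty(n, dtype=int)
    ll = 0.0
    start = 0
    for block in table.iter_partitions():
        lp = _gmm_log_prob(block, means, variances, weights)
        ll += float(logsumexp(lp, axis=1).sum())
        assignments[start : start + block.shape[0]] = np.argmax(lp, axis=1)
        start += block.shape[0]
    trace.append(ll)
    return GMMFit(
        K=K,
        means=means,
        variances=variances,
        weights=weights,
        assignments=assignments,
        loglik=ll,
        loglik_trace=trace,
        n_iter=n_iter,
        converged=converged,
        seed=seed,
    )


def gmm_bic(fit: GMMFit, n: int, p: int) -> tuple[float, int]:
    """BIC = -2 loglik + n_params * log(n) with diagonal covariances."""
    n_params = (fit.K - 1) + 2 * fit.K * p
    return -2.0 * fit.loglik + n_params * np.log(n), n_params


# ---------------------------------------------------------------------------
# Sweep + model selection
# ---------------------------------------------------------------------------


def sweep_and_select(
    table: ChunkedTable,
    method: str,
    n_centers: list[int],
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> ClusteringResult:
    """Fit every K in ``n_centers``; pick best_K by minimum BIC (ties ->
    smaller K). All fits are retained in the result."""
    if not n_centers:
        raise DataError("n_centers must be nonempty")
    if method not in ("kmeans", "gmm"):
        raise DataError(f"unknown clustering method {method!r}")
    n, p = table.n_rows, table.n_columns
    result = ClusteringResult(method=method, seed=seed)
    for K in n_centers:
        if method == "kmeans":
            fit = fit_kmeans(table, K, max_iter=max_iter, seed=seed)
            fit.bic, fit.n_params = kmeans_bic(fit, n, p)
        else:
            fit = fit_gmm(table, K, max_iter=max_iter, tol=tol, seed=seed)
            fit.bic, fit.n_params = gmm_bic(fit, n, p)
        result.per_K_fits[K] = fit
    best_K, best_bic = None, np.inf
    for K in sorted(result.per_K_fits):
        bic = result.per_K_fits[K].bic
        if bic < best_bic:
            best_K, best_bic = K, bic
    result.best_K = best_K
    return result
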