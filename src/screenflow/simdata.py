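"""Synthetic single-cell screen fixtures with known ground truth.

The generator emulates an image-based RNAi infection screen: each row is one
cell, described by 43 numeric image features (cell/nucleus geometry,
perinuclear texture, local neighborhood crowding, staining intensities) plus
a binary infection label. Features are block-correlated Gaussians on the
standardized scale; the label follows a logistic model whose nonzero
coefficients put positive weight on cell area (+0.21) and cell perimeter
(+0.18) and negative weight on the neighbor count (-0.11) — large cells in
sparse neighborhoods are more often infected. The intercept is solved
numerically to hit a target infection prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .chunked import DEFAULT_CHUNK_ROWS, ChunkedTable
from .errors import DataError

# 43 image features in four correlation blocks
CELL_GEOMETRY = [
    "cell_area", "cell_perimeter", "cell_eccentricity", "cell_solidity",
    "cell_extent", "cell_major_axis", "cell_minor_axis", "cell_orientation",
    "cell_roundness", "cell_compactness",
]
NUCLEUS_GEOMETRY = [
    "nucleus_area", "nucleus_perimeter", "nucleus_eccentricity",
    "nucleus_solidity", "nucleus_extent", "nucleus_major_axis",
    "nucleus_minor_axis", "nucleus_roundness", "nucleus_intensity_mean",
    "nucleus_intensity_sd",
]
PERINUCLEAR = [
    "peri_area", "peri_intensity_mean", "peri_intensity_sd",
    "peri_texture_contrast", "peri_texture_entropy", "peri_granularity",
    "peri_ring_width", "peri_signal_ratio",
]
NEIGHBORHOOD = [
    "n_neighbors", "neighbor_density", "dist_nearest_neighbor",
    "dist_mean_neighbors", "local_cell_count_30px", "local_cell_count_60px",
    "crowding_index", "boundary_distance",
]
INTENSITY = [
    "cell_intensity_mean", "cell_intensity_sd", "cell_texture_contrast",
    "bg_intensity_mean", "bg_intensity_sd", "focus_score",
    "illumination_score",
]
FEATURE_NAMES: list[str] = (
    CELL_GEOMETRY + NUCLEUS_GEOMETRY + PERINUCLEAR + NEIGHBORHOOD + INTENSITY
)
assert len(FEATURE_NAMES) == 43

RESPONSE_NAME = "is_infected"

DEFAULT_COEFFICIENTS = {
    "cell_area": 0.21,
    "cell_perimeter": 0.18,
    "n_neighbors": -0.11,
}

# within-block equicorrelation; blocks are independent of each other
_BLOCK_RHO = {
    "geometry": ( CELL_GEOMETRY + NUCLEUS_GEOMETRY, 0.5),
    "perinuclear": (PERINUCLEAR, 0.3),
    "neighborhood": (NEIGHBORHOOD, 0.4),
    "intensity": (INTENSITY, 0.0),
}


@dataclass
class SimulationTruth:
    """Ground-truth parameters behind one generated screen."""

    n_cells: int
    seed: int
    prevalence: float
    coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    n_features: int = 43
    intercept: float = 0.0
    covariance: np.ndarray | None = None

    @property
    def beta(self) -> np.ndarray:
        return np.array(
            [self.coefficients.get(c, 0.0) for c in FEATURE_NAMES]
        )


def feature_covariance() -> np.ndarray:
    """Block-equicorrelated covariance on the standardized feature scale."""
    p = len(FEATURE_NAMES)
    cov = np.eye(p)
    index = {c: i for i, c in enumerate(FEATURE_NAMES)}
    for names, rho in _BLOCK_RHO.values():
        idx = [index[c] for c in names]
        for a in idx:
            for b in idx:
                if a != b:
                    cov[a, b] = rho
    return cov


def _solve_intercept(beta: np.ndarray, cov: np.ndarray, prevalence: float
                     ) -> float:
    """Intercept b with E[sigmoid(b + beta'x)] = prevalence, x ~ N(0, cov).

    The linear predictor is N(0, s^2); the expectation is evaluated by
    Gauss-Hermite quadrature and the intercept by root bracketing.
    """
    s = float(np.sqrt(beta @ cov @ beta))
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    weights = weights / weights.sum()

    def mean_prob(b: float) -> float:
        return float(weights @ (1.0 / (1.0 + np.exp(-(b + s * nodes)))))

    lo, hi = -20.0, 20.0
    if not mean_prob(lo) < prevalence < mean_prob(hi):
        raise DataError(
            f"target prevalence {prevalence} unreachable with |intercept| <= 20"
        )
    return float(brentq(lambda b: mean_prob(b) - prevalence, lo, hi))


def simulate_screen(
    n_cells: int,
    prevalence: float = 0.3,
    seed: int = 0,
    coefficients: dict[str, float] | None = None,
    outdir: str | Path | None = None,
    chunk_rows: int = DEFAULT_CHUNK_ROWS,
) -> tuple[ChunkedTable, SimulationTruth]:
    """Generate a screen-like table of 43 features plus an infection label.

    When ``outdir`` is given, writes ``single_cell_samples.tsv`` (features +
    is_infected) and ``feature_columns.tsv`` (one feature name per line),
    both fully determined by ``seed``.
    """
    if n_cells < 1:
        raise DataError("n_cells must be >= 1")
    truth = SimulationTruth(
        n_cells=n_cells,
        seed=seed,
        prevalence=prevalence,
        coefficients=dict(coefficients or DEFAULT_COEFFICIENTS),
    )
    unknown = set(truth.coefficients) - set(FEATURE_NAMES)
    if unknown:
        raise DataError(f"coefficients name unknown features: {sorted(unknown)}")
    cov = feature_covariance()
    truth.covariance = cov
    truth.intercept = _solve_intercept(truth.beta, cov, prevalence)

    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(cov)
    x = rng.standard_normal((n_cells, len(FEATURE_NAMES))) @ chol.T
    eta = truth.intercept + x @ truth.beta
    prob = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.uniform(size=n_cells) < prob).astype(float)

    table = ChunkedTable.from_array(
        np.column_stack([x, y]), FEATURE_NAMES + [RESPONSE_NAME], chunk_rows
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.write_tsv(outdir / "single_cell_samples.tsv")
        (outdir / "feature_columns.tsv").write_text(
            "\n".join(FEATURE_NAMES) + "\n"
        )
    return table, truth


def simulate_factors(
    n: int,
    p: int,
    k: int,
    noise: float = 0.1,
    seed: int = 0,
    sources: str = "normal",
    chunk_rows: int = DEFAULT_CHUNK_ROWS,
) -> tuple[ChunkedTable, np.ndarray, np.ndarray]:
    """Latent-factor data x = W z + eps with known loadings.

    ``sources`` is "normal" (factor-analysis/PCA recovery) or "uniform"
    (non-Gaussian, unit-variance, for ICA blind-source recovery; excess
    kurtosis -1.2). Returns (table, true W (p, k), true sources (n, k)).
    """
    if k >= p:
        raise DataError(f"simulate_factors requires k < p ({k} >= {p})")
    if noise <= 0:
        raise DataError("noise must be positive")
    rng = np.random.default_rng(seed)
    w = rng.normal(size=(p, k))
    if sources == "normal":
        z = rng.standard_normal((n, k))
    elif sources == "uniform":
        z = rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=(n, k))
    else:
        raise DataError(f"unknown sources kind {sources!r}")
    x = z @ w.T + rng.normal(scale=noise, size=(n, p))
    names = [f"feature_{j + 1}" for j in range(p)]
    return ChunkedTable.from_array(x, names, chunk_rows), w, z


def simulate_blobs(
    n: int,
    centers: np.ndarray,
    spread: float = 1.0,
    weights: np.ndarray | None = None,
    seed: int = 0,
    chunk_rows: int = DEFAULT_CHUNK_ROWS,
) -> tuple[ChunkedTable, np.ndarray]:
    """Spherical Gaussian blobs for clustering recovery tests.

    Returns (table, true component labels)."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    K, p = centers.shape
    rng = np.random.default_rng(seed)
    if weights is None:
        weights = np.full(K, 1.0 / K)
    labels = rng.choice(K, size=n, p=np.asarray(weights) / np.sum(weights))
    x = centers[labels] + rng.normal(scale=spread, size=(n, p))
    names = [f"x_{j + 1}" for j in range(p)]
    return ChunkedTable.from_array(x, names, chunk_rows), labels
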