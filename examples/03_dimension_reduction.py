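"""Streaming dimension reduction: PCA, factor analysis, ICA, LDA.

All methods consume the table one partition at a time, so the same code
path handles tables that do not fit in memory.
"""

import numpy as np

from screenflow import (
    ChunkedTable,
    fit_factor_analysis, fit_ica, fit_lda, fit_pca,
    simulate_factors, simulate_screen, standardize,
)

# PCA and FA on latent-factor data with 2 true factors
table, true_w, _ = simulate_factors(n=2000, p=6, k=2, noise=0.1, seed=3)
pca = fit_pca(standardize(table), 2)
print("pca variance shares of the top 2 components:",
      np.round(pca.extra["variance_shares"], 3))

model, _ = fit_factor_analysis(table, 2, max_iter=200)
fitted_cov = model.loadings @ model.loadings.T + np.diag(model.psi)
true_cov = true_w @ true_w.T + 0.01 * np.eye(6)
rel = np.linalg.norm(fitted_cov - true_cov) / np.linalg.norm(true_cov)
print(f"fa covariance recovery (relative Frobenius error): {rel:.3f}")
print(f"fa EM iterations: {len(model.loglik_trace) - 1}, "
      f"converged: {model.converged}")

# ICA separates linearly mixed non-Gaussian sources that PCA cannot
rng = np.random.default_rng(5)
z = rng.uniform(-np.sqrt(3), np.sqrt(3), size=(5000, 2))
mixed = ChunkedTable.from_array(z @ np.array([[1.0, 0.6], [-0.4, 1.2]]).T,
                                ["a", "b"], 512)
ica = fit_ica(mixed, 2, seed=1)
corr = np.abs(np.corrcoef(ica.transformed.materialize().T, z.T)[:2, 2:])
print("ica |correlation| of recovered vs true sources:\n", np.round(corr, 3))

# LDA on the screen: one discriminant direction for the binary label
screen, _ = simulate_screen(2000, seed=9)
lda = fit_lda(screen, "is_infected", 1)
top = np.argsort(-np.abs(lda.loadings[:, 0]))[:3]
names = lda.extra["feature_names"]
print("lda top discriminating features:", [names[i] for i in top])
# An ICA correlation matrix that is near-identity after row permutation
# means blind source separation succeeded; the LDA direction weights the
# features that best separate infected from uninfected cells.
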