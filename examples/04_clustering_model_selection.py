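"""Cluster-count sweep with BIC adjudication on separated blobs.

Fits k-means and a diagonal-covariance Gaussian mixture for every candidate
center count and selects the best by BIC; with 3 well-separated blobs the
sweep over {2, 3, 5} should land on 3.
"""

import numpy as np

from screenflow import simulate_blobs, sweep_and_select

centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
table, _ = simulate_blobs(600, centers, spread=1.0, seed=4)

for method in ("kmeans", "gmm"):
    result = sweep_and_select(table, method, [2, 3, 5], seed=0)
    print(f"{method}: best K = {result.best_K}")
    for K, objective, bic in result.selection_table:
        print(f"   K={K:<3} objective={objective:12.1f}  BIC={bic:10.1f}")
# The objective (SSE or log-likelihood) always improves with more centers;
# BIC penalizes the extra parameters and bottoms out at the true count.
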