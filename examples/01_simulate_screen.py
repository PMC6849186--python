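"""Generate a synthetic single-cell infection screen and inspect it.

Each row is one cell with 43 image features; the is_infected label follows a
logistic model putting positive weight on cell area and perimeter and
negative weight on the neighbor count.
"""

import numpy as np

from screenflow import simulate_screen

table, truth = simulate_screen(n_cells=2000, prevalence=0.3, seed=1,
                               outdir="scratch/example_screen")

labels = table.column("is_infected")
print(f"cells: {table.n_rows}, features: {truth.n_features}")
print(f"empirical infection rate: {labels.mean():.3f} (target 0.3)")
print(f"logistic intercept solved for the target rate: {truth.intercept:.3f}")
print("nonzero ground-truth coefficients:", truth.coefficients)
# The empirical rate fluctuates around the target with binomial noise; the
# coefficients are the effects the GLM stage should later recover.
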