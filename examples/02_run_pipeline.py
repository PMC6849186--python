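"""Expand a declarative config into a Petri net and execute it end to end.

The config asks for PCA and ICA to 5 dimensions, GMM and k-means with 50 or
100 centers on each reduction, and a GLM plus random forest on the infection
label — 8 triples in total, of which 6 are dimension-reduction or clustering
result sets.
"""

from pathlib import Path

from screenflow import parse_config, plan_from_config, run_plan, simulate_screen

root = Path("scratch/example_pipeline")
simulate_screen(n_cells=500, prevalence=0.3, seed=7, outdir=root)

(root / "analysis.yml").write_text(f"""\
input: {root / 'single_cell_samples.tsv'}
features: {root / 'feature_columns.tsv'}
response: is_infected
family: binomial
dimension_reduction: pca, ica
n_components: 5
clustering: gmm, kmeans
n_centers: 50, 100
regression: glm, forest
outfolder: {root / 'results'}
seed: 7
""")

cfg = parse_config(root / "analysis.yml")
net, plan = plan_from_config(cfg)
print(f"petri net: {len(net.places)} places, {len(net.transitions)} transitions")
for t in plan.triples:
    print(f"  {Path(t.input_place).name:<28} --[{t.transition.name}]--> "
          f"{Path(t.output_place).name}")

report = run_plan(plan, cfg)
print(report.summary())
# Every output place is a result-set directory holding the transformed or
# fitted tables, a params.txt marker, diagnostics and a plot; rerunning the
# same plan skips all triples because their outputs already exist.
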