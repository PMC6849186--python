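"""Petri-net expansion, triple extraction, scheduling and execution."""

import itertools

import networkx as nx
import numpy as np
import pytest

from screenflow.config import AnalysisConfig
from screenflow.errors import SchedulingError
from screenflow.petri import (
    ExecutionPlan,
    build_net,
    clustering_result_count,
    extract_triples,
    run_plan,
    schedule,
)


def example_config(**over):
    base = dict(
        input_path="single_cell_samples.tsv",
        response="is_infected",
        family="binomial",
        dimred_methods=["pca", "ica"],
        n_components=5,
        clustering_methods=["gmm", "kmeans"],
        n_centers=[50, 100],
        regression_methods=["glm", "forest"],
        outfolder="results",
    )
    base.update(over)
    return AnalysisConfig(**base).validate()


class TestBuildNet:
    def test_worked_example_counts(self):
        net = build_net(example_config())
        assert len(net.transitions) == 8
        assert len(net.places) == 9  # 1 input + 8 outputs
        stage_places = [
            t for t in net.transitions if t.stage in ("dimred", "clustering")
        ]
        assert len(stage_places) == 6  # the six DR + clustering output sets

    def test_empty_pipeline(self):
        net = build_net(example_config(
            dimred_methods=[], clustering_methods=[], n_centers=[],
            regression_methods=[],
        ))
        assert len(net.places) == 1 and len(net.transitions) == 0

    def test_single_stage(self):
        net = build_net(example_config(
            dimred_methods=["pca"], clustering_methods=[], n_centers=[],
            regression_methods=[],
        ))
        assert len(net.places) == 2 and len(net.transitions) == 1

    def test_bipartite_acyclic_single_source(self):
        net = build_net(example_config())
        net.validate()
        assert nx.is_directed_acyclic_graph(net.graph)

    @pytest.mark.parametrize("dimred,clustering,expected", [
        (["pca", "ica"], ["gmm", "kmeans"], 4),
        (["pca"], ["kmeans"], 1),
        (["pca", "ica", "fa"], ["kmeans", "gmm"], 6),
    ])
    def test_clustering_result_count_is_product(self, dimred, clustering,
                                                expected):
        net = build_net(example_config(
            dimred_methods=dimred, clustering_methods=clustering,
        ))
        assert clustering_result_count(net) == expected
        # matches exhaustive enumeration of (dimred, clustering) pairs
        assert expected == len(list(itertools.product(dimred, clustering)))

    def test_triple_count_law_over_all_method_subsets(self):
        """|triples| = |D| + |D|*|C| + |R| for every method-set combination."""
        dimreds = [[], ["pca"], ["pca", "ica"], ["pca", "fa", "ica", "kpca"]]
        clusterings = [[], ["kmeans"], ["kmeans", "gmm"]]
        regressions = [[], ["glm"], ["glm", "forest", "gbm"]]
        for d, c, r in itertools.product(dimreds, clusterings, regressions):
            cfg = example_config(
                dimred_methods=d, clustering_methods=c,
                n_centers=[2] if c else [], regression_methods=r,
            )
            triples = extract_triples(build_net(cfg))
            n_clust = len(c) * (len(d) if d else 1)
            assert len(triples) == len(d) + n_clust + len(r)

    def test_deterministic(self):
        a = extract_triples(build_net(example_config()))
        b = extract_triples(build_net(example_config()))
        assert a == b


class TestTriplesAndSchedule:
    def test_extract_triples_worked_example(self):
        triples = extract_triples(build_net(example_config()))
        assert len(triples) == 8
        outputs = {t.output_place for t in triples}
        assert len(outputs) == 8  # output places unique

    def test_chaining_contract(self):
        cfg = example_config(
            dimred_methods=["pca"], clustering_methods=["kmeans"],
            n_centers=[3], regression_methods=[],
        )
        triples = extract_triples(build_net(cfg))
        assert len(triples) == 2
        by_method = {t.transition.method: t for t in triples}
        assert (by_method["kmeans"].input_place
                == by_method["pca"].output_place)

    def test_forced_order(self):
        cfg = example_config(
            dimred_methods=["pca"], clustering_methods=["kmeans"],
            n_centers=[3], regression_methods=[],
        )
        triples = extract_triples(build_net(cfg))
        for perm in itertools.permutations(triples):
            plan = schedule(list(perm), available={cfg.input_path})
            assert [t.transition.method for t in plan.triples] == \
                ["pca", "kmeans"]

    def test_worked_example_is_a_valid_topological_order(self):
        triples = extract_triples(build_net(example_config()))
        plan = schedule(triples, available={"single_cell_samples.tsv"})
        produced = {"single_cell_samples.tsv"}
        for t in plan.triples:
            assert t.input_place in produced
            produced.add(t.output_place)
        # dimension reductions precede every clustering triple
        idx = {t.transition.name: i for i, t in enumerate(plan.triples)}
        for name, i in idx.items():
            if "@" in name:
                parent = name.split("@")[1]
                assert idx[parent] < i

    def test_missing_input_place_is_scheduling_error(self, tmp_path):
        triples = extract_triples(build_net(example_config(
            input_path=str(tmp_path / "never_written.tsv"),
        )))
        with pytest.raises(SchedulingError, match="never_written"):
            schedule(triples)

    def test_waves_group_independent_triples(self):
        triples = extract_triples(build_net(example_config()))
        plan = schedule(triples, available={"single_cell_samples.tsv"})
        waves = plan.waves()
        assert len(waves) == 2
        assert {t.transition.stage for t in waves[0]} == {"dimred",
                                                          "regression"}
        assert {t.transition.stage for t in waves[1]} == {"clustering"}


class TestRunPlan:
    def _small_config(self, tmp_path, **over):
        from screenflow.simdata import simulate_screen
        simulate_screen(120, seed=5, outdir=tmp_path)
        base = dict(
            input_path=str(tmp_path / "single_cell_samples.tsv"),
            feature_file=str(tmp_path / "feature_columns.tsv"),
            response="is_infected",
            family="binomial",
            dimred_methods=["pca"],
            n_components=3,
            clustering_methods=["kmeans"],
            n_centers=[2, 4],
            regression_methods=["glm"],
            outfolder=str(tmp_path / "results"),
            seed=1,
        )
        base.update(over)
        return AnalysisConfig(**base).validate()

    def test_empty_plan_creates_outfolder(self, tmp_path):
        cfg = self._small_config(
            tmp_path, dimred_methods=[], clustering_methods=[], n_centers=[],
            regression_methods=[],
        )
        report = run_plan(ExecutionPlan([]), cfg)
        assert report.statuses == []
        assert (tmp_path / "results").is_dir()

    def test_run_then_rerun_skips_by_enabledness(self, tmp_path):
        cfg = self._small_config(tmp_path)
        triples = extract_triples(build_net(cfg))
        plan = schedule(triples)
        report = run_plan(plan, cfg, chunk_rows=40)
        assert report.counts() == {"ok": 3}
        again = run_plan(plan, cfg, chunk_rows=40)
        assert again.counts() == {"skipped": 3}
        forced = run_plan(plan, cfg, force=True, chunk_rows=40)
        assert forced.counts() == {"ok": 3}

    def test_fixed_seed_outputs_bit_identical(self, tmp_path):
        cfg_a = self._small_config(tmp_path,
                                   outfolder=str(tmp_path / "ra"))
        cfg_b = self._small_config(tmp_path,
                                   outfolder=str(tmp_path / "rb"))
        run_plan(schedule(extract_triples(build_net(cfg_a))), cfg_a,
                 chunk_rows=40)
        run_plan(schedule(extract_triples(build_net(cfg_b))), cfg_b,
                 chunk_rows=40)
        for sub in (tmp_path / "ra").rglob("*.tsv"):
            twin = tmp_path / "rb" / sub.relative_to(tmp_path / "ra")
            assert sub.read_bytes() == twin.read_bytes()

    def test_method_failure_aborts_dependents_only(self, tmp_path):
        # lda on a binary label supports at most 1 component, so asking for 5
        # fails; its clustering dependent aborts, the regression branch survives
        cfg = self._small_config(
            tmp_path, dimred_methods=["lda"], n_components=5,
            clustering_methods=["kmeans"], n_centers=[2],
        )
        plan = schedule(extract_triples(build_net(cfg)))
        report = run_plan(plan, cfg, chunk_rows=40)
        by = {s.triple.transition.name: s.status for s in report.statuses}
        assert by["lda"] == "failed"
        assert by["kmeans@lda"] == "aborted"
        assert by["glm"] == "ok"
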