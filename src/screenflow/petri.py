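"""Petri-net expansion and execution of an analysis config.

The config is expanded into a bipartite directed graph whose *places* are
data sets on the file system and whose *transitions* are analysis methods.
A transition is enabled when its input place exists on disk; firing it
materializes its output place (a result-set directory). The executable unit
is the *triple* (input place, method, output place); the scheduler orders
triples topologically and the runner fires them, skipping triples whose
output already exists.

Expansion rules: one transition per dimension-reduction method reading the
source table; one per (dimension-reduction output, clustering method) pair —
the n_centers sweep parameterizes a single clustering transition; one per
regression method reading the source table.
"""

from __future__ import annotations

import logging
import os
import time
import traceback
from concurrent.futures import FIRST_COMPLETED, ProcessPoolExecutor, wait
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .chunked import DEFAULT_CHUNK_ROWS, ChunkedTable, read_feature_names, read_tsv, standardize
from .config import AnalysisConfig
from .errors import ConfigError, DataError, SchedulingError
from . import clustering as _clustering
from . import dimred as _dimred
from . import supervised as _supervised

logger = logging.getLogger(__name__)

DIMRED_STAGE = "dimred"
CLUSTERING_STAGE = "clustering"
REGRESSION_STAGE = "regression"

# marker file written last; its presence makes the output place "exist"
DONE_MARKER = "params.txt"


@dataclass(frozen=True)
class Transition:
    """An operation node: method name plus parameterization."""

    name: str                       # unique within the net, e.g. "kmeans@pca"
    method: str                     # e.g. "kmeans"
    stage: str                      # dimred | clustering | regression
    params: tuple[tuple[str, object], ...] = ()

    def param_dict(self) -> dict:
        return dict(self.params)


@dataclass(frozen=True)
class Triple:
    """Executable subgraph: input place -> transition -> output place."""

    input_place: str
    transition: Transition
    output_place: str


@dataclass
class PetriNet:
    graph: nx.DiGraph
    source: str

    @property
    def places(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True)
                if d["kind"] == "place"]

    @property
    def transitions(self) -> list[Transition]:
        return [d["transition"] for n, d in self.graph.nodes(data=True)
                if d["kind"] == "transition"]

    def validate(self) -> "PetriNet":
        for u, v in self.graph.edges:
            ku = self.graph.nodes[u]["kind"]
            kv = self.graph.nodes[v]["kind"]
            if ku == kv:
                raise ValueError(f"arc {u} -> {v} is not bipartite")
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("petri net contains a cycle")
        roots = [p for p in self.places if self.graph.in_degree(p) == 0]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one source place, got {roots}")
        return self


@dataclass
class ExecutionPlan:
    triples: list[Triple]

    def waves(self) -> list[list[Triple]]:
        """Group the plan into stages of mutually independent triples."""
        produced_at: dict[str, int] = {}
        waves: list[list[Triple]] = []
        for t in self.triples:
            level = produced_at.get(t.input_place, -1) + 1
            while len(waves) <= level:
                waves.append([])
            waves[level].append(t)
            produced_at[t.output_place] = level
        return waves


@dataclass
class TripleStatus:
    triple: Triple
    status: str                     # ok | skipped | failed | aborted
    message: str = ""
    seconds: float = 0.0


@dataclass
class RunReport:
    statuses: list[TripleStatus] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.statuses:
            out[s.status] = out.get(s.status, 0) + 1
        return out

    def ok(self) -> bool:
        return all(s.status in ("ok", "skipped") for s in self.statuses)

    def summary(self) -> str:
        lines = [
            f"{s.status:>8}  {s.triple.transition.name:<18} "
            f"-> {s.triple.output_place}"
            + (f"  ({s.message})" if s.message else "")
            for s in self.statuses
        ]
        lines.append(f"totals: {self.counts()}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Net construction
# ---------------------------------------------------------------------------


def _result_dir(config: AnalysisConfig, method: str,
                parent: str | None = None) -> str:
    stem = Path(config.input_path).stem
    name = f"{stem}-{method}" if parent is None else f"{stem}-{method}-from-{parent}"
    return str(Path(config.outfolder) / name)


def build_net(config: AnalysisConfig) -> PetriNet:
    """Expand a validated config into the bipartite Petri net."""
    g = nx.DiGraph()
    source = str(config.input_path)
    g.add_node(source, kind="place")

    def add_transition(t: Transition, input_place: str, output_place: str):
        g.add_node(t.name, kind="transition", transition=t)
        g.add_node(output_place, kind="place")
        g.add_edge(input_place, t.name)
        g.add_edge(t.name, output_place)

    dimred_out: dict[str, str] = {}
    for m in config.dimred_methods:
        t = Transition(
            name=m, method=m, stage=DIMRED_STAGE,
            params=(("n_components", config.n_components),),
        )
        out = _result_dir(config, m)
        add_transition(t, source, out)
        dimred_out[m] = out

    cluster_parents = (
        list(dimred_out.items()) if dimred_out else [(None, source)]
    )
    for c in config.clustering_methods:
        for parent, place in cluster_parents:
            name = f"{c}@{parent}" if parent else c
            t = Transition(
                name=name, method=c, stage=CLUSTERING_STAGE,
                params=(("n_centers", tuple(config.n_centers)),),
            )
            add_transition(t, place, _result_dir(config, c, parent))

    for r in config.regression_methods:
        params: tuple = (("family", config.family),)
        if r in ("forest", "gbm"):
            params += (
                ("n_trees", config.n_trees),
                ("subsample_rate", config.subsample_rate),
            )
        if r == "gbm":
            params += (("learning_rate", config.learning_rate),)
        t = Transition(name=r, method=r, stage=REGRESSION_STAGE, params=params)
        add_transition(t, source, _result_dir(config, r))

    return PetriNet(graph=g, source=source).validate()


def clustering_result_count(net: PetriNet) -> int:
    """Number of clustering result sets = |dimred| x |clustering| methods."""
    return sum(1 for t in net.transitions if t.stage == CLUSTERING_STAGE)


def extract_triples(net: PetriNet) -> list[Triple]:
    """One triple per transition, in deterministic net order."""
    triples = []
    for node, data in net.graph.nodes(data=True):
        if data["kind"] != "transition":
            continue
        inputs = list(net.graph.predecessors(node))
        outputs = list(net.graph.successors(node))
        if len(inputs) != 1 or len(outputs) != 1:
            raise ValueError(f"transition {node} is not a simple triple")
        triples.append(Triple(inputs[0], data["transition"], outputs[0]))
    return triples


def schedule(
    triples: list[Triple],
    available: set[str] | None = None,
) -> ExecutionPlan:
    """Topologically order triples honoring the firing rule.

    An input place must either be produced by an earlier triple, be listed in
    ``available``, or already exist on the file system; otherwise the
    dependency is unsatisfiable and a :class:`SchedulingError` is raised.
    """
    available = set(available or ())
    produced = {t.output_place for t in triples}
    seen_outputs: set[str] = set()
    for t in triples:
        if t.output_place in seen_outputs:
            raise SchedulingError(
                f"duplicate output place {t.output_place!r}"
            )
        seen_outputs.add(t.output_place)
        if (
            t.input_place not in produced
            and t.input_place not in available
            and not os.path.exists(t.input_place)
        ):
            raise SchedulingError(
                f"input place {t.input_place!r} of {t.transition.name} is "
                "never produced and does not exist on the file system"
            )

    ordered: list[Triple] = []
    ready = set(available) | {
        t.input_place for t in triples if t.input_place not in produced
    }
    pending = list(triples)
    while pending:
        fired = [t for t in pending if t.input_place in ready]
        if not fired:
            raise SchedulingError(
                "unsatisfiable dependencies among "
                f"{[t.transition.name for t in pending]}"
            )
        for t in fired:
            ordered.append(t)
            ready.add(t.output_place)
        pending = [t for t in pending if t not in fired]
    return ExecutionPlan(ordered)


def plan_from_config(config: AnalysisConfig) -> tuple[PetriNet, ExecutionPlan]:
    net = build_net(config)
    triples = extract_triples(net)
    return net, schedule(triples, available={net.source})


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------


def _output_exists(triple: Triple) -> bool:
    return (Path(triple.output_place) / DONE_MARKER).exists()


def _write_params(outdir: Path, transition: Transition, seed: int,
                  extra: dict | None = None) -> None:
    lines = [
        f"method: {transition.method}",
        f"stage: {transition.stage}",
        f"seed: {seed}",
    ]
    for k, v in transition.param_dict().items():
        lines.append(f"{k}: {v}")
    for k, v in (extra or {}).items():
        lines.append(f"{k}: {v}")
    (outdir / DONE_MARKER).write_text("\n".join(lines) + "\n")


def _write_matrix_tsv(path: Path, matrix: np.ndarray, columns: list[str],
                      index: list[str] | None = None,
                      index_name: str = "row") -> None:
    with open(path, "w", newline="\n") as fh:
        header = ([index_name] if index is not None else []) + columns
        fh.write("\t".join(header) + "\n")
        for i, row in enumerate(np.atleast_2d(matrix)):
            cells = ([index[i]] if index is not None else [])
            cells += ["%.6g" % v for v in row]
            fh.write("\t".join(cells) + "\n")


def _load_input(config: AnalysisConfig, chunk_rows: int
                ) -> tuple[ChunkedTable, list[str]]:
    """Read the source table, keeping feature columns plus the response."""
    if config.feature_file:
        features = read_feature_names(config.feature_file)
    else:
        header = read_tsv(config.input_path, chunk_rows=10).column_names
        features = [c for c in header if c != config.response]
    columns = list(features)
    if config.response and config.response not in columns:
        columns.append(config.response)
    table = read_tsv(config.input_path, columns=columns, chunk_rows=chunk_rows)
    if config.n_components > len(features):
        raise ConfigError(
            f"n_components={config.n_components} exceeds the "
            f"{len(features)} feature columns"
        )
    return table, features


def _resolve_family(config: AnalysisConfig, table: ChunkedTable) -> str:
    if config.family != "auto":
        return config.family
    if not config.response:
        return "gaussian"
    values = np.unique(table.column(config.response))
    return "binomial" if values.size == 2 else "gaussian"


def _plot_dimred(outdir: Path, result) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.6))
    ev = np.asarray(result.explained, dtype=float)
    axes[0].plot(np.arange(1, ev.size + 1), ev, marker="o")
    axes[0].set_xlabel("component / iteration")
    axes[0].set_ylabel("diagnostic")
    axes[0].set_title(f"{result.method}: explained")
    first = result.transformed.materialize()
    if first.shape[1] >= 2:
        axes[1].scatter(first[:, 0], first[:, 1], s=4, alpha=0.5)
        axes[1].set_xlabel(result.transformed.column_names[0])
        axes[1].set_ylabel(result.transformed.column_names[1])
    else:
        axes[1].hist(first[:, 0], bins=30)
        axes[1].set_xlabel(result.transformed.column_names[0])
    axes[1].set_title("scores")
    fig.tight_layout()
    fig.savefig(outdir / "plot.png", dpi=90)
    plt.close(fig)


def _plot_selection(outdir: Path, result) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = result.selection_table
    ks = [r[0] for r in rows]
    bics = [r[2] for r in rows]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(ks, bics, marker="o")
    ax.axvline(result.best_K, color="crimson", ls="--",
               label=f"best K = {result.best_K}")
    ax.set_xlabel("cluster centers K")
    ax.set_ylabel("BIC")
    ax.set_title(f"{result.method} model selection")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "plot.png", dpi=90)
    plt.close(fig)


def _plot_scores(outdir: Path, result) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    if result.scores is not None and result.y_true is not None:
        for cls, color in ((0, "steelblue"), (1, "darkorange")):
            ax.hist(result.scores[result.y_true == cls], bins=30, alpha=0.6,
                    color=color, label=f"class {cls}")
        ax.legend()
    ax.set_xlabel("fitted P(y = 1)")
    ax.set_ylabel("cells")
    ax.set_title(
        f"{result.method}: precision {result.precision:.3f}, "
        f"recall {result.recall:.3f}"
    )
    fig.tight_layout()
    fig.savefig(outdir / "plot.png", dpi=90)
    plt.close(fig)


def execute_triple(
    triple: Triple,
    config: AnalysisConfig,
    seed: int,
    chunk_rows: int = DEFAULT_CHUNK_ROWS,
) -> None:
    """Fire one transition: run its method and materialize the output place."""
    outdir = Path(triple.output_place)
    outdir.mkdir(parents=True, exist_ok=True)
    transition = triple.transition
    extra: dict = {}

    if transition.stage == DIMRED_STAGE:
        table, features = _load_input(config, chunk_rows)
        feats = table.select(features)
        k = config.n_components
        method = transition.method
        if method in ("pca", "ica", "kpca"):
            feats = standardize(feats, with_std=True)
        if method == "pca":
            result = _dimred.fit_pca(feats, k)
            extra["variance_shares"] = list(
                np.round(result.extra["variance_shares"], 6)
            )
        elif method == "fa":
            _, result = _dimred.fit_factor_analysis(feats, k)
        elif method == "kpca":
            result = _dimred.fit_kpca(feats, k, seed=seed)
        elif method == "ica":
            result = _dimred.fit_ica(feats, k, seed=seed)
        elif method == "lda":
            if not config.response:
                raise ConfigError("lda requires a response column")
            result = _dimred.fit_lda(
                table.select(features + [config.response]), config.response, k
            )
        else:
            raise ConfigError(f"unknown dimension reduction {method!r}")
        transformed = result.transformed
        if config.response and config.response in table.column_names:
            transformed = transformed.with_column(
                config.response, table.column(config.response)
            )
        transformed.write_tsv(outdir / "transformed.tsv")
        row_names = (
            result.extra.get("feature_names", features)
            if result.method != "kpca"
            else [f"rff_{j}" for j in range(result.loadings.shape[0])]
        )
        _write_matrix_tsv(
            outdir / "loadings.tsv", result.loadings,
            [f"comp_{j + 1}" for j in range(result.n_components)],
            index=list(row_names), index_name="feature",
        )
        (outdir / "diagnostics.txt").write_text(
            f"method: {result.method}\nconverged: {result.converged}\n"
            f"explained: {np.asarray(result.explained).tolist()}\n"
        )
        _plot_dimred(outdir, result)
        extra["converged"] = result.converged

    elif transition.stage == CLUSTERING_STAGE:
        parent = Path(triple.input_place)
        if parent.is_dir():
            table = read_tsv(parent / "transformed.tsv", chunk_rows=chunk_rows)
            score_cols = [
                c for c in table.column_names if c != config.response
            ]
            feats = table.select(score_cols)
        else:
            table, features = _load_input(config, chunk_rows)
            feats = standardize(table.select(features), with_std=True)
        result = _clustering.sweep_and_select(
            feats, transition.method, list(config.n_centers), seed=seed
        )
        for K, fit in result.per_K_fits.items():
            _write_matrix_tsv(
                outdir / f"assignments-K{K}.tsv",
                fit.assignments[:, None].astype(float), ["cluster"],
            )
            centers = fit.centers if hasattr(fit, "centers") else fit.means
            _write_matrix_tsv(
                outdir / f"centers-K{K}.tsv", centers, feats.column_names,
            )
        with open(outdir / "model_selection.tsv", "w") as fh:
            fh.write("K\tobjective\tbic\tbest\n")
            for K, obj, bic in result.selection_table:
                fh.write(
                    f"{K}\t{obj:.6g}\t{bic:.6g}\t"
                    f"{int(K == result.best_K)}\n"
                )
        _plot_selection(outdir, result)
        extra["best_K"] = result.best_K

    elif transition.stage == REGRESSION_STAGE:
        table, features = _load_input(config, chunk_rows)
        if not config.response:
            raise ConfigError("regression requires a response column")
        if config.response not in table.column_names:
            raise DataError(
                f"response {config.response!r} not in the input header"
            )
        family = _resolve_family(config, table)
        method = transition.method
        if method == "glm":
            result = _supervised.fit_glm(
                table, config.response, family=family, seed=seed
            )
            _write_matrix_tsv(
                outdir / "coefficients.tsv",
                np.column_stack([result.coefficients, result.std_errors]),
                ["estimate", "std_error"],
                index=result.feature_names, index_name="term",
            )
        elif method in ("forest", "gbm"):
            fitter = (
                _supervised.fit_forest if method == "forest"
                else _supervised.fit_gbm
            )
            kwargs = dict(
                n_trees=config.n_trees,
                subsample_rate=config.subsample_rate,
                seed=seed,
            )
            if method == "gbm":
                kwargs["learning_rate"] = config.learning_rate
            result = fitter(table, config.response, **kwargs)
            _write_matrix_tsv(
                outdir / "importances.tsv",
                result.feature_importances[:, None], ["importance"],
                index=result.feature_names, index_name="feature",
            )
        else:
            raise ConfigError(f"unknown regression method {method!r}")
        (outdir / "metrics.txt").write_text(
            f"method: {method}\nfamily: {family}\n"
            f"precision: {result.precision:.6f}\n"
            f"recall: {result.recall:.6f}\n"
            f"balanced_n: {result.balanced_n}\n"
            + (f"n_trees: {result.n_trees}\n"
               f"subsample_rate: {result.subsample_rate}\n"
               if result.n_trees is not None else "")
        )
        _plot_scores(outdir, result)
        extra["precision"] = round(result.precision, 6)
        extra["recall"] = round(result.recall, 6)
    else:
        raise ConfigError(f"unknown stage {transition.stage!r}")

    _write_params(outdir, transition, seed, extra)


def _run_one(args) -> tuple[str, str, float]:
    """Worker wrapper: returns (output_place, status-or-error, seconds)."""
    triple, config, seed, chunk_rows = args
    t0 = time.perf_counter()
    try:
        execute_triple(triple, config, seed, chunk_rows)
        return triple.output_place, "", time.perf_counter() - t0
    except Exception:
        return triple.output_place, traceback.format_exc(limit=3), \
            time.perf_counter() - t0


def run_plan(
    plan: ExecutionPlan,
    config: AnalysisConfig,
    force: bool = False,
    workers: int = 1,
    chunk_rows: int = DEFAULT_CHUNK_ROWS,
) -> RunReport:
    """Fire every triple of the plan in dependency order.

    A triple whose output place already exists is skipped (the Petri-net
    enabledness rule) unless ``force``. A failing triple aborts its
    dependents but not independent branches. Each triple receives the
    derived seed ``config.seed + its plan index``.
    """
    if not Path(config.input_path).exists():
        raise DataError(f"input file not found: {config.input_path}")
    Path(config.outfolder).mkdir(parents=True, exist_ok=True)

    seeds = {t.output_place: config.seed + i
             for i, t in enumerate(plan.triples)}
    report = RunReport()
    failed_places: set[str] = set()

    def record(triple: Triple, status: str, message: str = "",
               seconds: float = 0.0) -> None:
        logger.info("%s %s -> %s %s", status, triple.transition.name,
                    triple.output_place, message.splitlines()[-1] if message else "")
        report.statuses.append(TripleStatus(triple, status, message, seconds))

    for wave in plan.waves():
        runnable = []
        for t in wave:
            if t.input_place in failed_places:
                failed_places.add(t.output_place)
                record(t, "aborted", "upstream failure")
            elif _output_exists(t) and not force:
                record(t, "skipped", "output already present")
            else:
                runnable.append(t)
        if not runnable:
            continue
        if workers > 1 and len(runnable) > 1:
            with ProcessPoolExecutor(max_workers=workers) as pool:
                futures = {
                    pool.submit(
                        _run_one,
                        (t, config, seeds[t.output_place], chunk_rows),
                    ): t
                    for t in runnable
                }
                done = set(futures)
                while done:
                    finished, done = wait(done, return_when=FIRST_COMPLETED)
                    for fut in finished:
                        t = futures[fut]
                        place, err, secs = fut.result()
                        if err:
                            failed_places.add(place)
                            record(t, "failed", err, secs)
                        else:
                            record(t, "ok", seconds=secs)
        else:
            for t in runnable:
                _, err, secs = _run_one(
                    (t, config, seeds[t.output_place], chunk_rows)
                )
                if err:
                    failed_places.add(t.output_place)
                    record(t, "failed", err, secs)
                else:
                    record(t, "ok", seconds=secs)
    return report


def run_config(
    config: AnalysisConfig,
    force: bool = False,
    workers: int = 1,
    chunk_rows: int = DEFAULT_CHUNK_ROWS,
) -> RunReport:
    """Expand, schedule and execute a config end to end."""
    _, plan = plan_from_config(config)
    return run_plan(plan, config, force=force, workers=workers,
                    chunk_rows=chunk_rows)
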