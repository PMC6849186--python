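"""Declarative analysis configuration.

The config dialect is flat ``key: value`` text (a YAML mapping); list-valued
keys take either YAML lists or comma-separated strings. Cluster-resource keys
(``spark*``, ``*memory*``) are retained verbatim but never acted on locally,
so configs written for a distributed deployment remain loadable.

Schema::

    input: single_cell_samples.tsv      # required, TSV with header
    features: feature_columns.tsv       # optional one-column TSV of names
    response: is_infected               # required for regression / lda
    family: binomial                    # binomial | gaussian | auto
    dimension_reduction: pca, ica       # subset of pca fa kpca ica lda
    n_components: 5
    clustering: gmm, kmeans             # subset of kmeans gmm
    n_centers: 50, 100
    regression: glm, forest             # subset of glm forest gbm
    n_trees: 20                         # optional ensemble parameters
    subsample_rate: 0.25
    learning_rate: 0.1
    outfolder: results
    seed: 23
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError, ValidationError

logger = logging.getLogger(__name__)

DIMRED_METHODS = ("pca", "fa", "kpca", "ica", "lda")
CLUSTERING_METHODS = ("kmeans", "gmm")
REGRESSION_METHODS = ("glm", "forest", "gbm")
FAMILIES = ("binomial", "gaussian", "auto")

_KEY_ALIASES = {
    "input": "input_path",
    "input_path": "input_path",
    "data": "input_path",
    "features": "feature_file",
    "feature_file": "feature_file",
    "response": "response",
    "family": "family",
    "dimension_reduction": "dimred_methods",
    "dimred": "dimred_methods",
    "dimred_methods": "dimred_methods",
    "n_components": "n_components",
    "clustering": "clustering_methods",
    "clustering_methods": "clustering_methods",
    "n_centers": "n_centers",
    "centers": "n_centers",
    "regression": "regression_methods",
    "regression_methods": "regression_methods",
    "outfolder": "outfolder",
    "output": "outfolder",
    "seed": "seed",
    "n_trees": "n_trees",
    "subsample_rate": "subsample_rate",
    "learning_rate": "learning_rate",
}

# keys stored (and logged) but never acted on locally
_RESOURCE_PREFIXES = ("spark", "driver", "executor", "memory", "resources")


@dataclass
class AnalysisConfig:
    """Validated description of one pipeline run."""

    input_path: str
    outfolder: str = "results"
    feature_file: str | None = None
    response: str | None = None
    family: str = "auto"
    dimred_methods: list[str] = field(default_factory=list)
    n_components: int = 2
    clustering_methods: list[str] = field(default_factory=list)
    n_centers: list[int] = field(default_factory=list)
    regression_methods: list[str] = field(default_factory=list)
    n_trees: int = 20
    subsample_rate: float = 0.25
    learning_rate: float = 0.1
    resources: dict[str, str] = field(default_factory=dict)
    seed: int = 23

    def validate(self) -> "AnalysisConfig":
        _check_subset(self.dimred_methods, DIMRED_METHODS, "dimension reduction")
        _check_subset(self.clustering_methods, CLUSTERING_METHODS, "clustering")
        _check_subset(self.regression_methods, REGRESSION_METHODS, "regression")
        if self.family not in FAMILIES:
            raise ValidationError(
                f"family {self.family!r} not one of {sorted(FAMILIES)}"
            )
        if self.regression_methods and not self.response:
            raise ValidationError(
                "regression methods requested but no response column given"
            )
        if "lda" in self.dimred_methods and not self.response:
            raise ValidationError("lda requires a response column as label")
        if self.clustering_methods and not self.n_centers:
            raise ValidationError(
                "clustering methods requested but n_centers is empty"
            )
        if any(k < 1 for k in self.n_centers):
            raise ValidationError(f"n_centers must all be >= 1: {self.n_centers}")
        if self.n_components < 1:
            raise ValidationError("n_components must be >= 1")
        if self.seed < 0:
            raise ValidationError("seed must be non-negative")
        if not 0 < self.subsample_rate <= 1:
            raise ValidationError(
                f"subsample_rate must be in (0, 1]: {self.subsample_rate}"
            )
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        return self


def _check_subset(given: list[str], allowed: tuple[str, ...], what: str) -> None:
    unknown = [m for m in given if m not in allowed]
    if unknown:
        raise ValidationError(
            f"unknown {what} method(s) {unknown}; allowed: {list(allowed)}"
        )
    if len(set(given)) != len(given):
        raise ValidationError(f"duplicate {what} method in {given}")


def _as_list(value) -> list[str]:
    if value is None:
        return []
    if isinstance(value, (list, tuple)):
        return [str(v).strip() for v in value]
    return [v.strip() for v in str(value).split(",") if v.strip()]


def _as_int_list(value) -> list[int]:
    out = []
    for v in _as_list(value):
        try:
            out.append(int(v))
        except ValueError:
            raise ValidationError(f"expected an integer, got {v!r}") from None
    return out


def parse_config(path: str | Path) -> AnalysisConfig:
    """Parse and validate a config file into an :class:`AnalysisConfig`."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} must contain a flat key: value mapping")
    return config_from_mapping(raw)


def config_from_mapping(raw: dict) -> AnalysisConfig:
    fields: dict = {}
    resources: dict[str, str] = {}
    for key, value in raw.items():
        key_l = str(key).strip().lower()
        if key_l in _KEY_ALIASES:
            fields[_KEY_ALIASES[key_l]] = value
        elif any(key_l.startswith(p) or p in key_l for p in _RESOURCE_PREFIXES):
            resources[str(key)] = str(value)
            logger.info("resource key %r = %r retained, not acted on", key, value)
        else:
            logger.warning("ignoring unknown config key %r", key)

    if "input_path" not in fields:
        raise ValidationError("config is missing the required 'input' key")

    cfg = AnalysisConfig(
        input_path=str(fields["input_path"]),
        outfolder=str(fields.get("outfolder", "results")),
        feature_file=(
            str(fields["feature_file"]) if fields.get("feature_file") else None
        ),
        response=(str(fields["response"]) if fields.get("response") else None),
        family=str(fields.get("family", "auto")).lower(),
        dimred_methods=[m.lower() for m in _as_list(fields.get("dimred_methods"))],
        n_components=int(fields.get("n_components", 2)),
        clustering_methods=[
            m.lower() for m in _as_list(fields.get("clustering_methods"))
        ],
        n_centers=_as_int_list(fields.get("n_centers")),
        regression_methods=[
            m.lower() for m in _as_list(fields.get("regression_methods"))
        ],
        n_trees=int(fields.get("n_trees", 20)),
        subsample_rate=float(fields.get("subsample_rate", 0.25)),
        learning_rate=float(fields.get("learning_rate", 0.1)),
        resources=resources,
        seed=int(fields.get("seed", 23)),
    )
    return cfg.validate()


def serialize_config(cfg: AnalysisConfig) -> str:
    """Render a config back to the flat ``key: value`` dialect."""
    lines = [f"input: {cfg.input_path}"]
    if cfg.feature_file:
        lines.append(f"features: {cfg.feature_file}")
    if cfg.response:
        lines.append(f"response: {cfg.response}")
    lines.append(f"family: {cfg.family}")
    if cfg.dimred_methods:
        lines.append(f"dimension_reduction: {', '.join(cfg.dimred_methods)}")
        lines.append(f"n_components: {cfg.n_components}")
    if cfg.clustering_methods:
        lines.append(f"clustering: {', '.join(cfg.clustering_methods)}")
        lines.append(f"n_centers: {', '.join(map(str, cfg.n_centers))}")
    if cfg.regression_methods:
        lines.append(f"regression: {', '.join(cfg.regression_methods)}")
        lines.append(f"n_trees: {cfg.n_trees}")
        lines.append(f"subsample_rate: {cfg.subsample_rate}")
        lines.append(f"learning_rate: {cfg.learning_rate}")
    lines.append(f"outfolder: {cfg.outfolder}")
    lines.append(f"seed: {cfg.seed}")
    for key, value in cfg.resources.items():
        lines.append(f"{key}: {value}")
    return "\n".join(lines) + "\n"
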