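"""Project-parameters file: schema, validation, defaults.

A project is described by one YAML (or JSON) file naming the expression
input, the database snapshots, per-feature transform overrides, thresholds,
label sources, and the optimizer block. Unknown keys are rejected with their
key path so typos fail loudly instead of silently using a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .transforms import (
    DEFAULT_C_BOUNDS,
    DEFAULT_W_BOUNDS,
    IMPUTE_METHODS,
    RESCALE_METHODS,
    FeatureSpec,
)

_TOP_KEYS = {
    "expression", "format", "phenotype", "unit", "databases", "features",
    "feature_overrides", "thresholds", "dependency_aggregation",
    "known_positives", "known_negatives", "evaluation_mode", "phase_scores",
    "moa_filter", "gene_set_selection", "parameters_json", "optimizer",
}
_DB_KEYS = {"normal_expression", "localization", "dependency", "gene_sets", "therapy"}
_THRESHOLD_KEYS = {"low_pct", "high_pct", "restriction_pct"}
_OPTIMIZER_KEYS = {"mode", "min_gain", "seed", "w_bounds", "c_bounds", "ga", "run_ga"}
_OVERRIDE_KEYS = {"rescale_method", "impute_method", "curve", "weight"}
_GA_KEYS = {"population", "generations", "elite_fraction", "mutation_sd",
            "mutation_rate", "polish_top", "nm_maxfev", "seed"}


class ParameterError(ValueError):
    """Invalid project-parameters file."""


def _check_keys(mapping: dict, allowed: set, path: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ParameterError(
            f"unknown key(s) {sorted(unknown)} at {path or '<top level>'}; "
            f"allowed: {sorted(allowed)}"
        )


@dataclass
class OptimizerConfig:
    mode: str = "multi_cancer"
    min_gain: float = 0.001
    seed: int = 0
    w_bounds: tuple = DEFAULT_W_BOUNDS
    c_bounds: tuple = DEFAULT_C_BOUNDS
    run_ga: bool = True
    ga: dict = field(default_factory=dict)


@dataclass
class ProjectParameters:
    """Validated parameters with all defaults filled."""

    expression: str
    phenotype: str
    fmt: str | None = None
    unit: str = "intensity"
    databases: dict = field(default_factory=dict)
    features: list | None = None            # None = include all
    feature_overrides: dict = field(default_factory=dict)
    low_pct: float = 20.0
    high_pct: float = 80.0
    restriction_pct: float = 20.0
    dependency_aggregation: str = "mean"
    known_positives: list | None = None     # user labels override extraction
    known_negatives: list | None = None
    evaluation_mode: str = "auto"
    phase_scores: dict | None = None
    moa_filter: list | None = None
    gene_set_selection: list | None = None
    parameters_json: str | None = None      # optimized (w, c) reused for scoring
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)

    def feature_specs(self, feature_names) -> dict:
        """Per-feature specs: global defaults + named overrides."""
        specs = {}
        for name in feature_names:
            ov = self.feature_overrides.get(name, {})
            specs[name] = FeatureSpec(
                name=name,
                rescale_method=ov.get("rescale_method", "percentile"),
                impute_method=ov.get("impute_method", "min"),
                curve=float(ov.get("curve", 0.0)),
                weight=float(ov.get("weight", 1.0)),
            )
        unknown = set(self.feature_overrides) - set(feature_names)
        if unknown:
            raise ParameterError(f"feature_overrides name unknown feature(s) {sorted(unknown)}")
        return specs


def parse_parameters(path) -> ProjectParameters:
    """Load and validate a YAML/JSON project-parameters file."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ParameterError(f"{path}: parameters file must be a mapping")
    _check_keys(raw, _TOP_KEYS, path="")
    if "expression" not in raw:
        raise ParameterError(f"{path}: missing required key 'expression'")
    if "phenotype" not in raw:
        raise ParameterError(f"{path}: missing required key 'phenotype'")

    databases = raw.get("databases", {}) or {}
    _check_keys(databases, _DB_KEYS, path="databases")

    thresholds = raw.get("thresholds", {}) or {}
    _check_keys(thresholds, _THRESHOLD_KEYS, path="thresholds")

    overrides = raw.get("feature_overrides", {}) or {}
    for fname, ov in overrides.items():
        _check_keys(ov or {}, _OVERRIDE_KEYS, path=f"feature_overrides.{fname}")
        if "rescale_method" in ov and ov["rescale_method"] not in RESCALE_METHODS:
            raise ParameterError(
                f"feature_overrides.{fname}.rescale_method: {ov['rescale_method']!r} "
                f"not in {RESCALE_METHODS}"
            )
        if "impute_method" in ov and ov["impute_method"] not in IMPUTE_METHODS:
            raise ParameterError(
                f"feature_overrides.{fname}.impute_method: {ov['impute_method']!r} "
                f"not in {IMPUTE_METHODS}"
            )

    opt_raw = raw.get("optimizer", {}) or {}
    _check_keys(opt_raw, _OPTIMIZER_KEYS, path="optimizer")
    ga = opt_raw.get("ga", {}) or {}
    _check_keys(ga, _GA_KEYS, path="optimizer.ga")
    mode = opt_raw.get("mode", "multi_cancer")
    if mode not in ("multi_cancer", "phenotype_specific"):
        raise ParameterError(f"optimizer.mode: unknown value {mode!r}")
    optimizer = OptimizerConfig(
        mode=mode,
        min_gain=float(opt_raw.get("min_gain", 0.001)),
        seed=int(opt_raw.get("seed", 0)),
        w_bounds=tuple(opt_raw.get("w_bounds", DEFAULT_W_BOUNDS)),
        c_bounds=tuple(opt_raw.get("c_bounds", DEFAULT_C_BOUNDS)),
        run_ga=bool(opt_raw.get("run_ga", True)),
        ga=dict(ga),
    )

    mode_eval = raw.get("evaluation_mode", "auto")
    if mode_eval not in ("auto", "labeled_only", "full_list"):
        raise ParameterError(f"evaluation_mode: unknown value {mode_eval!r}")
    agg = raw.get("dependency_aggregation", "mean")
    if agg not in ("mean", "max"):
        raise ParameterError(f"dependency_aggregation: unknown value {agg!r}")

    pos = raw.get("known_positives")
    neg = raw.get("known_negatives")
    if pos and neg and set(map(str.upper, pos)) & set(map(str.upper, neg)):
        raise ParameterError("known_positives and known_negatives overlap")

    base = path.parent

    def resolve(p):
        return str((base / p) if not Path(p).is_absolute() else Path(p))

    def resolve_db(entry):
        if isinstance(entry, str):
            return resolve(entry)
        if isinstance(entry, list):
            return [resolve_db(e) for e in entry]
        if isinstance(entry, dict):
            return {k: (resolve(v) if isinstance(v, str) and (k.endswith("path") or k in
                        ("records", "cell_lines")) else v) for k, v in entry.items()}
        return entry

    return ProjectParameters(
        expression=resolve(raw["expression"]),
        phenotype=str(raw["phenotype"]),
        fmt=raw.get("format"),
        unit=raw.get("unit", "intensity"),
        databases={k: resolve_db(v) for k, v in databases.items()},
        features=raw.get("features"),
        feature_overrides=overrides,
        low_pct=float(thresholds.get("low_pct", 20.0)),
        high_pct=float(thresholds.get("high_pct", 80.0)),
        restriction_pct=float(thresholds.get("restriction_pct", 20.0)),
        dependency_aggregation=agg,
        known_positives=pos,
        known_negatives=neg,
        evaluation_mode=mode_eval,
        phase_scores=raw.get("phase_scores"),
        moa_filter=raw.get("moa_filter"),
        gene_set_selection=raw.get("gene_set_selection"),
        parameters_json=resolve(raw["parameters_json"]) if raw.get("parameters_json") else None,
        optimizer=optimizer,
    )
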