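"""Synthetic benchmark generator with planted signal.

Generates everything the pipeline consumes — tumor expression matrices,
normal-tissue / localization / dependency / gene-set / therapy snapshots, and
known-positive / known-negative labels — entirely offline and deterministic
per seed, with a known ground-truth set of informative features so that
feature-recovery and optimization behaviour can be asserted.

The planted structure emulates how real evidence separates good targets:

* a global pool of *target-like* genes carries high surface-localization
  confidence, long extracellular domains, high dependency probability in the
  phenotype's cell lines, and membership in a curated surface-target gene
  set; each phenotype's known-positives are drawn from this pool;
* known-negatives (failed, discontinued-drug targets) share the positives'
  **tumor-expression elevation** — a failed target was still an expressed
  protein — but none of the localization/dependency/gene-set merit. At
  default equal weights the labeled genes are therefore barely separable, and
  an optimizer must discover the discriminating evidence channels;
* normal-tissue expression snapshots are label-independent nuisance, so their
  thirty feature columns are planted noise.

The nine informative features (the ground truth exported with each
simulation) are the four label-associated expression summaries (mean, max,
high-count, low-count), the three localization fields, the dependency
probability, and the gene-set membership column.

Noise model: lognormal expression with completely-at-random dropout; the
simplest model that still exercises rescaling, imputation, and the counting
logic. No attempt is made to mimic real tissue-correlation structure or
mass-spectrometry intensity distributions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .enrichment import (
    DependencyDB,
    GeneSetDB,
    LocalizationDB,
    NormalExpressionDB,
    TherapyRecord,
    build_feature_matrix,
    dependency_feature,
    geneset_features,
    localization_features,
    normal_expression_features,
    therapy_features,
)
from .expression import ExpressionDataset, summarize_expression
from .optimization import Project
from .transforms import FeatureSpec, default_specs

GENE_SET_NAME = "surface_target_program"

#: ground-truth informative feature columns (matrix column names)
INFORMATIVE_FEATURES = (
    "mean_expr", "max_expr", "n_high", "n_low",
    "conf_a", "conf_b", "ecd_length", "dependency", GENE_SET_NAME,
)

#: weight signs a domain expert would assign to the informative features
ORACLE_WEIGHTS = {
    "mean_expr": 1.0, "max_expr": 1.0, "n_high": 1.0, "n_low": -1.0,
    "conf_a": 1.0, "conf_b": 1.0, "ecd_length": 1.0, "dependency": 1.0,
    GENE_SET_NAME: 1.0,
}

_TISSUES = ["adipose", "brain_cortex", "colon", "heart", "kidney", "liver", "lung", "skin"]
_BRAIN_TISSUES = {"brain_cortex"}


@dataclass
class FixtureConfig:
    """Study conditions for one simulated benchmark."""

    seed: int
    n_genes: int = 500
    n_samples: int = 8
    n_phenotypes: int = 12
    n_positives: tuple[int, int] = (5, 15)   # inclusive range, drawn per phenotype
    n_negatives: int = 40
    pos_pool_size: int | None = None         # None: scales with n_genes
    neg_pool_size: int | None = None
    expr_log2fc: float = 2.0                 # tumor elevation of known-positives
    neg_expr_log2fc: float = 1.2             # weaker elevation of known-negatives
    effect_scale: float = 1.0                # 0 = no planted signal anywhere
    dropout: float = 0.05                    # missing-at-random expression cells
    n_tissue_samples: int = 3

    def __post_init__(self) -> None:
        if self.pos_pool_size is None:
            self.pos_pool_size = max(self.n_positives[1], round(0.2 * self.n_genes))
        if self.neg_pool_size is None:
            self.neg_pool_size = max(self.n_negatives, round(0.24 * self.n_genes))
        lo, hi = self.n_positives
        if lo < 1:
            raise ValueError("need at least one positive per phenotype")
        if hi + self.n_negatives >= self.n_genes:
            raise ValueError("labeled genes must be fewer than n_genes")
        if self.pos_pool_size + self.neg_pool_size > self.n_genes:
            raise ValueError("label pools exceed the gene universe")


@dataclass
class SimulatedData:
    """All pipeline inputs for one benchmark, plus the planted truth."""

    expression: dict                 # phenotype -> ExpressionDataset
    normal_dbs: list                 # NormalExpressionDB snapshots
    localization: LocalizationDB
    dependency: DependencyDB
    gene_sets: GeneSetDB
    therapy: list
    positives: dict                  # phenotype -> set
    negatives: dict                  # phenotype -> set
    informative: list = field(default_factory=lambda: list(INFORMATIVE_FEATURES))
    config: FixtureConfig | None = None

    @property
    def phenotypes(self) -> list:
        return sorted(self.expression)


def _mix(rng, background, planted, prob):
    """Per-gene: take the planted draw with probability ``prob``.

    Planted evidence is partially penetrant — not every true target carries
    every kind of evidence, as in real knowledge bases — which keeps any
    single feature from separating the labels on its own.
    """
    take = rng.random(np.shape(background)) < prob
    return np.where(take, planted, background)


#: penetrance of each planted evidence channel among target-pool genes
LOCALIZATION_PENETRANCE = 0.9
DEPENDENCY_PENETRANCE = 0.85
GENESET_PENETRANCE = 0.85


def simulate_project(config: FixtureConfig) -> SimulatedData:
    """Generate a deterministic benchmark for the given study conditions."""
    rng = np.random.default_rng(config.seed)
    s = float(config.effect_scale)
    genes = np.array([f"G{i:04d}" for i in range(1, config.n_genes + 1)])
    pool = rng.choice(genes, size=config.pos_pool_size + config.neg_pool_size, replace=False)
    pos_pool = set(pool[: config.pos_pool_size])
    neg_pool = set(pool[config.pos_pool_size:])

    phenotypes = [f"phenotype{p:02d}" for p in range(1, config.n_phenotypes + 1)]
    positives, negatives, expression = {}, {}, {}
    lo, hi = config.n_positives
    for phen in phenotypes:
        n_pos = int(rng.integers(lo, hi + 1))
        positives[phen] = set(rng.choice(sorted(pos_pool), size=n_pos, replace=False))
        negatives[phen] = set(
            rng.choice(sorted(neg_pool), size=min(config.n_negatives, len(neg_pool)),
                       replace=False)
        )
        logv = rng.normal(np.log(100.0), 1.0, size=(config.n_genes, config.n_samples))
        fc = {g: config.expr_log2fc for g in positives[phen]}
        fc.update({g: config.neg_expr_log2fc for g in negatives[phen]})
        shift = np.array([np.log(2.0) * fc.get(g, 0.0) * s for g in genes])
        vals = np.exp(logv + shift[:, np.newaxis])
        vals[rng.random(vals.shape) < config.dropout] = np.nan
        df = pd.DataFrame(vals, index=genes,
                          columns=[f"{phen}_S{j + 1}" for j in range(config.n_samples)])
        expression[phen] = ExpressionDataset(values=df, phenotype=phen, unit="intensity")

    # --- normal-tissue snapshots: label-independent nuisance -------------
    # A per-gene latent level shared by all three databases (broadly expressed
    # vs restricted genes) plus a gene-by-tissue interaction makes the thirty
    # normal-tissue feature columns strongly correlated, as the real
    # databases are — they all measure the same underlying biology.
    latent_gene = rng.normal(0.0, 0.8, size=config.n_genes)
    normal_dbs = []
    for name, med, sigma, thr in (("gtex_rna", 2.0, 0.6, 10.0),
                                  ("devo_rna", 2.0, 0.6, 10.0),
                                  ("normal_prot", 500.0, 1.0, None)):
        rows = []
        for tissue in _TISSUES:
            gene_tissue = rng.normal(0.0, 0.5, size=config.n_genes)
            for j in range(config.n_tissue_samples):
                sample = f"{name}_{tissue}_S{j + 1}"
                logv = np.log(med) + latent_gene + gene_tissue + rng.normal(
                    0.0, sigma, size=config.n_genes)
                rows.append(pd.DataFrame({
                    "gene": genes, "tissue": tissue, "sample_id": sample,
                    "value": np.round(np.exp(logv), 4), "is_brain": tissue in _BRAIN_TISSUES,
                }))
        normal_dbs.append(NormalExpressionDB(records=pd.concat(rows, ignore_index=True),
                                             name=name, high_threshold=thr))

    # --- localization: planted high confidence for the target pool -------
    is_pool = np.array([g in pos_pool for g in genes])
    conf_a_bg = rng.choice(5, size=config.n_genes, p=[0.35, 0.25, 0.2, 0.12, 0.08])
    conf_a_hi = rng.choice(5, size=config.n_genes, p=[0.02, 0.05, 0.13, 0.3, 0.5])
    conf_b_bg = rng.choice(6, size=config.n_genes, p=[0.3, 0.25, 0.18, 0.12, 0.09, 0.06])
    conf_b_hi = rng.choice(6, size=config.n_genes, p=[0.02, 0.03, 0.05, 0.15, 0.3, 0.45])
    ecd_bg = np.exp(rng.normal(np.log(80.0), 0.8, size=config.n_genes))
    ecd_hi = np.exp(rng.normal(np.log(400.0), 0.6, size=config.n_genes))
    p_loc = LOCALIZATION_PENETRANCE * s
    conf_a = np.where(is_pool, _mix(rng, conf_a_bg, conf_a_hi, p_loc), conf_a_bg).astype(float)
    conf_b = np.where(is_pool, _mix(rng, conf_b_bg, conf_b_hi, p_loc), conf_b_bg).astype(float)
    ecd = np.round(np.where(is_pool, _mix(rng, ecd_bg, ecd_hi, p_loc), ecd_bg)).astype(float)
    loc = pd.DataFrame({"conf_a": conf_a, "conf_b": conf_b, "ecd_length": ecd}, index=genes)
    loc.index.name = "gene"
    for col in loc.columns:  # partial coverage exercises imputation
        loc.loc[rng.random(config.n_genes) < 0.1, col] = np.nan
    loc = loc.dropna(how="all")
    localization = LocalizationDB(table=loc)

    # --- dependency: planted high probability in the phenotype's lines ----
    dep_rows = []
    line_map = {}
    for phen in phenotypes:
        in_pos = np.array([g in positives[phen] for g in genes])
        # per-gene carrier status is drawn once per phenotype so all of the
        # phenotype's cell lines agree on whether a target is a dependency
        carrier = in_pos & (rng.random(config.n_genes) < DEPENDENCY_PENETRANCE * s)
        for j in range(4):
            line = f"{phen}_CL{j + 1}"
            line_map[line] = phen
            bg = rng.beta(1.0, 4.0, size=config.n_genes)
            hi_draw = rng.beta(5.0, 2.0, size=config.n_genes)
            prob = np.where(carrier, hi_draw, bg)
            keep = rng.random(config.n_genes) < 0.9
            dep_rows.append(pd.DataFrame({
                "gene": genes[keep], "cell_line": line,
                "probability": np.round(prob[keep], 5),
            }))
    dependency = DependencyDB(records=pd.concat(dep_rows, ignore_index=True),
                              cell_line_phenotypes=line_map)

    # --- gene set: enriched for the target pool ---------------------------
    p_member = np.where(is_pool, 0.05 + (GENESET_PENETRANCE - 0.05) * s, 0.05)
    members = set(genes[rng.random(config.n_genes) < p_member])
    if not members:
        members = {str(genes[0])}
    gene_sets = GeneSetDB(sets={GENE_SET_NAME: members})

    # --- therapy records consistent with the labels -----------------------
    therapy = []
    active_phases = ["approved", "phase3", "phase2", "phase1"]
    moas = ["adc", "car-t", "antibody"]
    for phen in phenotypes:
        for g in sorted(positives[phen]):
            phase = active_phases[int(rng.integers(len(active_phases)))]
            moa = moas[int(rng.integers(len(moas)))]
            therapy.append(TherapyRecord(gene=g, disease=phen, phase=phase, moa=moa,
                                         source="synthetic"))
        for g in sorted(negatives[phen]):
            therapy.append(TherapyRecord(gene=g, disease=phen, phase="discontinued",
                                         moa=moas[int(rng.integers(len(moas)))],
                                         source="synthetic"))

    return SimulatedData(
        expression=expression, normal_dbs=normal_dbs, localization=localization,
        dependency=dependency, gene_sets=gene_sets, therapy=therapy,
        positives=positives, negatives=negatives, config=config,
    )


def build_projects(data: SimulatedData, dependency_agg: str = "mean") -> list:
    """Run the real feature-extraction pipeline on simulated inputs, yielding
    one optimization-ready :class:`Project` per phenotype (40 features)."""
    projects = []
    for phen in data.phenotypes:
        ds = data.expression[phen]
        summary = summarize_expression(ds)
        genes = ds.gene_ids
        blocks = {}
        for db in data.normal_dbs:
            blocks[db.name] = normal_expression_features(db, genes)
        blocks["localization"] = localization_features(data.localization, genes)
        blocks["dependency"] = dependency_feature(data.dependency, phen, genes,
                                                  agg=dependency_agg)
        blocks["gene_sets"] = geneset_features(data.gene_sets, [GENE_SET_NAME], genes)
        matrix = build_feature_matrix(summary, blocks)
        projects.append(Project(matrix=matrix, positives=data.positives[phen],
                                negatives=data.negatives[phen], phenotype=phen))
    return projects


def oracle_specs(feature_names) -> dict:
    """Expert-knowledge FeatureSpecs: oracle signs on the planted informative
    features, zero weight elsewhere."""
    specs = default_specs(feature_names)
    out = {}
    for name in feature_names:
        w = ORACLE_WEIGHTS.get(name, 0.0)
        out[name] = specs[name].with_params(weight=w)
    return out


def extracted_labels(data: SimulatedData, phenotype: str):
    """Labels recovered through the therapy-record extraction path."""
    genes = data.expression[phenotype].gene_ids
    _, pos, neg = therapy_features(data.therapy, phenotype, genes)
    return pos, neg


def write_snapshots(data: SimulatedData, out_dir) -> dict:
    """Write every snapshot/expression table in the documented TSV schemas
    plus a manifest with the seed, config, and planted truth.

    Output is byte-identical for identical configs (fixed column order,
    ``%.6g`` floats, sorted manifest keys, no timestamps).
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def save(df: pd.DataFrame, fname: str, index: bool = False) -> str:
        p = out / fname
        df.to_csv(p, sep="\t", float_format="%.6g", na_rep="", index=index)
        paths[fname] = str(p)
        return str(p)

    for phen, ds in data.expression.items():
        df = ds.values.copy()
        df.insert(0, "gene", df.index)
        save(df, f"expression_{phen}.tsv")
    for db in data.normal_dbs:
        save(db.records, f"normal_expression_{db.name}.tsv")
    loc = data.localization.table.copy()
    loc.insert(0, "gene", loc.index)
    save(loc, "localization.tsv")
    save(data.dependency.records, "dependency.tsv")
    save(
        pd.DataFrame(sorted(data.dependency.cell_line_phenotypes.items()),
                     columns=["cell_line", "phenotype"]),
        "cell_lines.tsv",
    )
    save(
        pd.DataFrame(
            [(name, g) for name in sorted(data.gene_sets.sets)
             for g in sorted(data.gene_sets.sets[name])],
            columns=["set_name", "gene"],
        ),
        "gene_sets.tsv",
    )
    save(
        pd.DataFrame(
            [(r.gene, r.disease, r.phase, r.moa, r.source) for r in data.therapy],
            columns=["gene", "disease", "phase", "moa", "source"],
        ),
        "therapy.tsv",
    )
    manifest = {
        "config": asdict(data.config) if data.config else None,
        "informative_features": list(data.informative),
        "positives": {k: sorted(v) for k, v in data.positives.items()},
        "negatives": {k: sorted(v) for k, v in data.negatives.items()},
        "files": sorted(paths),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["manifest.json"] = str(out / "manifest.json")
    return paths


def write_params(data: SimulatedData, out_dir, phenotype: str,
                 optimizer: dict | None = None, parameters_json: str | None = None,
                 fname: str | None = None) -> str:
    """Write a project-parameters YAML for one phenotype of a simulated
    benchmark, referencing the snapshot files of :func:`write_snapshots`."""
    from pathlib import Path

    import yaml

    out = Path(out_dir)
    doc: dict = {
        "expression": f"expression_{phenotype}.tsv",
        "phenotype": phenotype,
        "unit": "intensity",
        "databases": {
            "normal_expression": [
                {"path": f"normal_expression_{db.name}.tsv", "name": db.name,
                 "high_threshold": db.high_threshold}
                for db in data.normal_dbs
            ],
            "localization": "localization.tsv",
            "dependency": {"records": "dependency.tsv", "cell_lines": "cell_lines.tsv"},
            "gene_sets": {"path": "gene_sets.tsv", "selected": sorted(data.gene_sets.sets)},
            "therapy": "therapy.tsv",
        },
    }
    if optimizer:
        doc["optimizer"] = optimizer
    if parameters_json:
        doc["parameters_json"] = parameters_json
    path = out / (fname or f"params_{phenotype}.yaml")
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
    return str(path)
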