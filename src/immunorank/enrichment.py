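"""Per-gene features from tabular knowledge-base snapshots.

Four evidence categories feed the scoring matrix alongside the tumor
expression summary:

* **normal-tissue expression** (GTEx-like RNA tables or normal proteomics):
  ten features per database — maximum tissue-level value, maximum sample
  value, counts of tissues/samples above a high-expression threshold, and a
  sample-count-normalized maximum — each computed with all tissues and again
  with brain tissues excluded (therapies that do not cross the blood-brain
  barrier can tolerate brain expression);
* **localization**: surface-protein confidence scores (two scales, 0-4 and
  0-5) and extracellular-domain length in residues;
* **dependency**: CRISPR/RNAi gene-dependency probabilities summarized over
  the cell lines annotated to the queried phenotype;
* **gene sets**: binary membership in user-selected pathways/curated lists;
* **therapy records**: development-phase scores of existing drugs, which also
  define the known-positive / known-negative evaluation labels.

Snapshots are long-format TSVs in the documented schema (see README); no
live database formats are parsed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import log, normalize_gene, normalize_label, percentile
from .expression import ExpressionSummary
from .transforms import FeatureMatrix

NORMAL_FEATURE_STEMS = ("max_tissue", "max_sample", "n_tissues_high", "n_samples_high", "norm_max")

#: Signed score per development phase; discontinued drugs score negative and
#: define known-negative targets. Fully overridable per project.
DEFAULT_PHASE_SCORES = {
    "approved": 1.0,
    "phase3": 0.8,
    "phase2": 0.6,
    "phase1": 0.4,
    "preclinical": 0.2,
    "discontinued": -0.5,
}


# ---------------------------------------------------------------------------
# database containers + loaders


@dataclass
class NormalExpressionDB:
    """Long-format normal-tissue expression: one row per (gene, sample).

    ``high_threshold`` is the value above which a sample/tissue counts as
    high-expressing; ``None`` means "90th percentile of all values in the
    snapshot" (the convention for proteomic intensities, where 10 TPM has no
    meaning).
    """

    records: pd.DataFrame  # columns: gene, tissue, sample_id, value, is_brain
    name: str = "normal"
    high_threshold: float | None = 10.0

    def __post_init__(self) -> None:
        req = {"gene", "tissue", "sample_id", "value", "is_brain"}
        missing = req - set(self.records.columns)
        if missing:
            raise ValueError(f"normal expression snapshot missing columns {sorted(missing)}")
        rec = self.records.copy()
        rec["gene"] = rec["gene"].map(normalize_gene)
        if rec["value"].min() < 0:
            raise ValueError("normal expression values must be non-negative")
        if rec.duplicated(["gene", "sample_id"]).any():
            raise ValueError("duplicate (gene, sample_id) rows in normal expression snapshot")
        if rec["tissue"].nunique() == 0:
            raise ValueError("normal expression snapshot has no tissues")
        self.records = rec

    def resolved_threshold(self) -> float:
        if self.high_threshold is not None:
            return float(self.high_threshold)
        return percentile(self.records["value"].to_numpy(), 90.0)


@dataclass
class LocalizationDB:
    """Per-gene surface-localization evidence; any field may be missing."""

    table: pd.DataFrame  # index gene; columns conf_a, conf_b, ecd_length
    name: str = "localization"

    def __post_init__(self) -> None:
        tab = self.table.copy()
        tab.index = pd.Index([normalize_gene(g) for g in tab.index], name="gene")
        for col, hi in (("conf_a", 4), ("conf_b", 5)):
            bad = tab[col].dropna()
            bad = bad[(bad < 0) | (bad > hi)]
            if len(bad):
                raise ValueError(
                    f"{col} value {bad.iloc[0]} for gene {bad.index[0]} outside range 0–{hi}"
                )
        ecd = tab["ecd_length"].dropna()
        if (ecd < 0).any():
            raise ValueError("ecd_length must be non-negative")
        self.table = tab


@dataclass
class DependencyDB:
    """Gene-dependency probabilities per cell line, with phenotype annotation."""

    records: pd.DataFrame  # columns: gene, cell_line, probability
    cell_line_phenotypes: dict  # cell_line -> phenotype
    name: str = "dependency"

    def __post_init__(self) -> None:
        rec = self.records.copy()
        rec["gene"] = rec["gene"].map(normalize_gene)
        probs = rec["probability"]
        if ((probs < 0) | (probs > 1)).any():
            raise ValueError("dependency probabilities must lie in [0, 1]")
        self.records = rec
        self.cell_line_phenotypes = {
            str(k): normalize_label(v) for k, v in self.cell_line_phenotypes.items()
        }


@dataclass
class GeneSetDB:
    """Named gene sets (pathways or curated target lists)."""

    sets: dict = field(default_factory=dict)  # name -> set of gene symbols
    name: str = "gene_sets"

    def __post_init__(self) -> None:
        clean = {}
        for set_name, members in self.sets.items():
            members = {normalize_gene(g) for g in members}
            if not members:
                raise ValueError(f"gene set {set_name!r} is empty")
            clean[str(set_name)] = members
        self.sets = clean


@dataclass(frozen=True)
class TherapyRecord:
    """One drug-development record linking a gene to a disease."""

    gene: str
    disease: str
    phase: str
    moa: str = ""
    source: str = ""

    def phase_score(self, score_map: dict | None = None) -> float:
        score_map = score_map or DEFAULT_PHASE_SCORES
        if self.phase not in score_map:
            raise ValueError(f"unknown development phase {self.phase!r}; known: {sorted(score_map)}")
        return float(score_map[self.phase])


def load_normal_expression(path, name: str = "normal",
                           high_threshold: float | None = 10.0) -> NormalExpressionDB:
    df = pd.read_csv(path, sep="\t")
    df["is_brain"] = df["is_brain"].astype(bool)
    return NormalExpressionDB(records=df, name=name, high_threshold=high_threshold)


def load_localization(path) -> LocalizationDB:
    df = pd.read_csv(path, sep="\t").set_index("gene")
    return LocalizationDB(table=df[["conf_a", "conf_b", "ecd_length"]])


def load_dependency(path, cell_lines_path) -> DependencyDB:
    rec = pd.read_csv(path, sep="\t")
    lines = pd.read_csv(cell_lines_path, sep="\t")
    mapping = dict(zip(lines["cell_line"].astype(str), lines["phenotype"]))
    return DependencyDB(records=rec, cell_line_phenotypes=mapping)


def load_gene_sets(path) -> GeneSetDB:
    df = pd.read_csv(path, sep="\t")
    sets = {name: set(grp["gene"]) for name, grp in df.groupby("set_name")}
    return GeneSetDB(sets=sets)


def load_therapy(path) -> list[TherapyRecord]:
    df = pd.read_csv(path, sep="\t").fillna("")
    return [
        TherapyRecord(
            gene=normalize_gene(r.gene),
            disease=str(r.disease),
            phase=str(r.phase),
            moa=str(r.moa),
            source=str(r.source),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# feature extraction


def _normal_block(records: pd.DataFrame, genes: pd.Index, threshold: float,
                  suffix: str) -> pd.DataFrame:
    """Five normal-tissue features for one tissue subset.

    The tissue-level value is the median of that tissue's samples. The
    normalized maximum is max over tissues of tissue value weighted by the
    fraction of the gene's samples annotated to that tissue.
    """
    cols = [f"{stem}{suffix}" for stem in NORMAL_FEATURE_STEMS]
    out = pd.DataFrame(np.nan, index=genes, columns=cols)
    if records.empty:
        return out
    per_tissue = records.groupby(["gene", "tissue"])["value"].agg(["median", "size"])
    per_gene_total = records.groupby("gene").size()
    tissue_med = per_tissue["median"]
    weighted = tissue_med * per_tissue["size"] / per_gene_total.reindex(
        per_tissue.index.get_level_values("gene")
    ).to_numpy()
    feats = pd.DataFrame(
        {
            cols[0]: tissue_med.groupby(level="gene").max(),
            cols[1]: records.groupby("gene")["value"].max(),
            cols[2]: tissue_med.gt(threshold).groupby(level="gene").sum().astype(float),
            cols[3]: records.groupby("gene")["value"].apply(lambda v: float((v > threshold).sum())),
            cols[4]: weighted.groupby(level="gene").max(),
        }
    )
    return feats.reindex(genes)[cols]


def normal_expression_features(db: NormalExpressionDB, genes) -> pd.DataFrame:
    """Ten features per gene: the five summaries with all tissues and with
    brain excluded. Genes absent from the snapshot get missing values."""
    genes = pd.Index([normalize_gene(g) for g in genes], name="gene")
    threshold = db.resolved_threshold()
    all_block = _normal_block(db.records, genes, threshold, suffix="")
    nobrain = db.records[~db.records["is_brain"]]
    if nobrain["tissue"].nunique() == 0:
        log.warning("%s: no non-brain tissues; brain-excluded features are missing", db.name)
        nb_block = pd.DataFrame(
            np.nan, index=genes, columns=[f"{s}_nobrain" for s in NORMAL_FEATURE_STEMS]
        )
    else:
        nb_block = _normal_block(nobrain, genes, threshold, suffix="_nobrain")
    block = pd.concat([all_block, nb_block], axis=1)
    block.columns = [f"{db.name}_{c}" for c in block.columns]
    return block


def localization_features(db: LocalizationDB, genes) -> pd.DataFrame:
    """Passthrough of the three localization fields; absent genes are missing."""
    genes = pd.Index([normalize_gene(g) for g in genes], name="gene")
    return db.table.reindex(genes)[["conf_a", "conf_b", "ecd_length"]]


def dependency_feature(db: DependencyDB, phenotype: str, genes,
                       agg: str = "mean") -> pd.Series:
    """Dependency probability aggregated over the phenotype's cell lines."""
    if agg not in ("mean", "max"):
        raise ValueError(f"unknown dependency aggregation {agg!r}; use 'mean' or 'max'")
    genes = pd.Index([normalize_gene(g) for g in genes], name="gene")
    phenotype = normalize_label(phenotype)
    lines = [cl for cl, ph in db.cell_line_phenotypes.items() if ph == phenotype]
    if not lines:
        log.warning("no cell lines annotated to phenotype %r; dependency feature missing", phenotype)
        return pd.Series(np.nan, index=genes, name="dependency")
    sub = db.records[db.records["cell_line"].astype(str).isin(lines)]
    vals = sub.groupby("gene")["probability"].agg(agg)
    return vals.reindex(genes).rename("dependency")


def geneset_features(db: GeneSetDB, selected_sets, genes) -> pd.DataFrame:
    """One 0/1 membership column per selected set, in the requested order."""
    unknown = [s for s in selected_sets if s not in db.sets]
    if unknown:
        raise KeyError(f"unknown gene set(s) {unknown}; available: {sorted(db.sets)}")
    genes = pd.Index([normalize_gene(g) for g in genes], name="gene")
    return pd.DataFrame(
        {s: [1.0 if g in db.sets[s] else 0.0 for g in genes] for s in selected_sets},
        index=genes,
    )


def therapy_features(records, disease: str, genes, moa_filter=None,
                     phase_scores: dict | None = None):
    """Best (maximum) phase score per gene for the disease, plus label sets.

    Returns ``(feature, known_positives, known_negatives)``: the signed score
    of the best matching record per gene (an approved drug dominates a
    discontinued one), and the genes whose best score is positive / negative.
    """
    phase_scores = phase_scores or DEFAULT_PHASE_SCORES
    genes = pd.Index([normalize_gene(g) for g in genes], name="gene")
    disease = normalize_label(disease)
    if moa_filter is not None:
        moa_filter = {normalize_label(m) for m in moa_filter}
    if not records:
        log.warning("empty therapy record list; no known-positive/negative labels extracted")
        return pd.Series(np.nan, index=genes, name="therapy_score"), set(), set()
    best: dict[str, float] = {}
    for rec in records:
        if normalize_label(rec.disease) != disease:
            continue
        if moa_filter is not None and normalize_label(rec.moa) not in moa_filter:
            continue
        g = normalize_gene(rec.gene)
        s = rec.phase_score(phase_scores)
        if g not in best or s > best[g]:
            best[g] = s
    feature = pd.Series({g: best.get(g, np.nan) for g in genes}, name="therapy_score")
    feature.index.name = "gene"
    positives = {g for g, s in best.items() if s > 0}
    negatives = {g for g, s in best.items() if s < 0}
    return feature, positives, negatives


def build_feature_matrix(summary: ExpressionSummary, blocks: dict,
                         selection=None) -> FeatureMatrix:
    """Column-concatenate the expression summary and enrichment blocks over
    the user dataset's gene universe.

    ``blocks`` maps a provenance label to a DataFrame/Series indexed by gene;
    genes absent from a database get missing values. ``selection`` optionally
    restricts (and orders) the feature columns.
    """
    genes = summary.features.index
    pieces = [summary.features]
    provenance = {f: "expression_summary" for f in summary.features.columns}
    for label, block in blocks.items():
        if isinstance(block, pd.Series):
            block = block.to_frame()
        block = block.reindex(genes)
        clash = set(block.columns) & set(provenance)
        if clash:
            raise ValueError(f"duplicate feature name(s) {sorted(clash)} in block {label!r}")
        pieces.append(block)
        provenance.update({f: label for f in block.columns})
    raw = pd.concat(pieces, axis=1)
    matrix = FeatureMatrix(raw=raw, provenance=provenance)
    if selection is not None:
        matrix = matrix.select(list(selection))
    return matrix
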