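"""Gene scoring, ranking, and the normal-tissue-restriction view.

The per-gene score is the weighted average of curved feature values,

    S_g = sum_f w_f * f(r_gf; c_f) / sum_f |w_f|,

normalized by the sum of absolute weights so that negative (penalty) weights
do not inflate the scale. Normalizing by a positive constant leaves the
ranking — and hence every ranking-based evaluation — unchanged relative to
the plain product-sum. Ties in score are broken by ascending gene symbol so
reruns are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import log, normalize_gene, percentile
from .enrichment import NormalExpressionDB
from .transforms import FeatureMatrix, FeatureSpec


@dataclass
class ScoreTable:
    """Ranked scores with weighted feature contributions and label flags.

    ``table`` is sorted by rank (1 = best) and carries one column per feature
    (the weighted, curved contribution ``w_f * f(r_gf; c_f)``) plus ``score``,
    ``rank``, ``percentile`` and boolean flag columns.
    """

    table: pd.DataFrame
    specs: dict = field(default_factory=dict)

    @property
    def ranked_genes(self) -> list[str]:
        return list(self.table.index)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.10g")


def _rank_percentile(n: int) -> np.ndarray:
    """Percentile for ranks 1..n: rank 1 -> 100, rank n -> 0."""
    if n == 1:
        return np.array([100.0])
    ranks = np.arange(1, n + 1)
    return 100.0 * (n - ranks) / (n - 1)


def score_genes(matrix: FeatureMatrix, specs: dict[str, FeatureSpec],
                known_positives=frozenset(), known_negatives=frozenset()) -> ScoreTable:
    """Score and rank all genes of a fully transformed feature matrix."""
    if not matrix.is_transformed:
        raise ValueError("feature matrix must be transformed before scoring")
    names = matrix.feature_names
    weights = np.array([specs[f].weight for f in names], dtype=float)
    denom = np.abs(weights).sum()
    if denom == 0:
        raise ValueError("no active features: all weights are zero")
    curved = matrix.curved.to_numpy(dtype=float)
    contrib = curved * weights[np.newaxis, :]
    scores = contrib.sum(axis=1) / denom
    out = pd.DataFrame(contrib, index=matrix.curved.index, columns=names)
    out["score"] = scores
    # descending score, ties by ascending symbol: index is sorted first, then
    # a stable sort on -score preserves symbol order within ties
    out = out.sort_index(kind="stable")
    out = out.sort_values("score", ascending=False, kind="stable")
    n = len(out)
    out["rank"] = np.arange(1, n + 1)
    out["percentile"] = _rank_percentile(n)
    pos = {normalize_gene(g) for g in known_positives}
    neg = {normalize_gene(g) for g in known_negatives}
    out["known_positive"] = [g in pos for g in out.index]
    out["known_negative"] = [g in neg for g in out.index]
    return ScoreTable(table=out, specs=dict(specs))


def normal_tissue_restriction_filter(table: ScoreTable, db: NormalExpressionDB,
                                     pct: float = 20.0, filter_view: bool = False):
    """Flag genes whose normal-tissue expression is restricted.

    A gene is restricted iff its maximum tissue-level value (median over the
    tissue's samples) falls strictly below the ``pct``-th percentile of the
    distribution of per-gene maximum tissue values across all genes in the
    snapshot. Genes absent from the snapshot have no detected normal
    expression and are flagged restricted, with a logged caveat.

    Returns the flagged table, or only the restricted genes (ranked order
    preserved) when ``filter_view`` is true.
    """
    if db is None:
        raise ValueError("normal-tissue restriction requires a normal expression snapshot")
    tissue_med = db.records.groupby(["gene", "tissue"])["value"].median()
    gene_max = tissue_med.groupby(level="gene").max()
    threshold = percentile(gene_max.to_numpy(), pct)
    flagged = table.table.copy()
    maxima = gene_max.reindex(flagged.index)
    absent = maxima.isna()
    if absent.any():
        log.info(
            "%d gene(s) absent from %s treated as normal-tissue restricted",
            int(absent.sum()), db.name,
        )
    flagged["normal_tissue_restricted"] = absent | (maxima < threshold)
    out = ScoreTable(table=flagged, specs=table.specs)
    if filter_view:
        out = ScoreTable(table=flagged[flagged["normal_tissue_restricted"]], specs=table.specs)
    return out


def top_percentile_view(table: ScoreTable, pct: float) -> ScoreTable:
    """Genes whose score percentile is >= 100 - pct, ranked order preserved.

    With the rank percentile 100*(n - rank)/(n - 1) the boundary is inclusive
    and the top-ranked gene (percentile 100) is always in the view.
    """
    if not 0 < pct <= 100:
        raise ValueError(f"pct must lie in (0, 100], got {pct}")
    sub = table.table[table.table["percentile"] >= 100.0 - pct]
    return ScoreTable(table=sub, specs=table.specs)
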