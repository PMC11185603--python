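"""Ranking evaluation: average precision / MAP and GSEA enrichment.

Average precision (AP) summarizes how early the known-positive targets of a
phenotype appear in the ranked gene list:

    AP = (1 / |P|) * sum_i  i / r_i

where ``r_i`` is the rank of the i-th positive (positives in rank order) —
equivalently the mean of precision-at-rank over the positives. The MAP score
is the arithmetic mean of AP over phenotypes.

Two evaluation modes govern how known-negatives (targets of discontinued
drugs) enter: in ``labeled_only`` mode — the default whenever negatives
exist — the ranking is first restricted to labeled genes and ranks are
recomputed, so every negative ranked above a positive directly lowers
precision; ``full_list`` mode evaluates positives against the complete
ranking and is the fallback for phenotypes with no negatives.

GSEA-style enrichment measures how concentrated a gene set is at the top of
a scored ranking via a weighted Kolmogorov-Smirnov running sum; significance
comes from a size-matched gene-label permutation null.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from ._utils import log, normalize_gene

EVALUATION_MODES = ("auto", "labeled_only", "full_list")


@dataclass
class RankingEvaluation:
    """AP/MAP and optional GSEA results for a scored project."""

    ap_per_phenotype: dict = field(default_factory=dict)
    map_score: float = float("nan")
    positive_ranks: dict = field(default_factory=dict)
    mode: str = "labeled_only"
    es: float | None = None
    p_value: float | None = None
    n_permutations: int | None = None
    seed: int | None = None

    def to_json(self, path) -> None:
        payload = {
            "ap_per_phenotype": self.ap_per_phenotype,
            "map": self.map_score,
            "positive_ranks": self.positive_ranks,
            "mode": self.mode,
            "gsea": {
                "es": self.es,
                "p_value": self.p_value,
                "n_permutations": self.n_permutations,
                "seed": self.seed,
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    def to_tsv(self, path) -> None:
        """Flat per-positive report: phenotype, AP, gene, rank."""
        with open(path, "w") as fh:
            fh.write("phenotype\tap\tpositive\trank\n")
            for phen in sorted(self.ap_per_phenotype):
                ap = self.ap_per_phenotype[phen]
                ranks = self.positive_ranks.get(phen, {})
                for gene in sorted(ranks):
                    fh.write(f"{phen}\t{ap:.6g}\t{gene}\t{ranks[gene]}\n")


def average_precision(ranked_genes, positives, negatives=frozenset(),
                      mode: str = "auto", return_ranks: bool = False):
    """AP of a ranked gene list against known-positive/negative labels."""
    if mode not in EVALUATION_MODES:
        raise ValueError(f"unknown evaluation mode {mode!r}; choose from {EVALUATION_MODES}")
    ranked = [normalize_gene(g) for g in ranked_genes]
    pos = {normalize_gene(g) for g in positives}
    neg = {normalize_gene(g) for g in negatives}
    if pos & neg:
        raise ValueError(f"positives and negatives overlap: {sorted(pos & neg)[:5]}")
    present = [g for g in ranked if g in pos]
    if not present:
        raise ValueError(
            f"no known-positive present in the ranking; missing: {sorted(pos)[:10]}"
        )
    if mode == "auto":
        mode = "labeled_only" if (neg & set(ranked)) else "full_list"
    if mode == "labeled_only":
        if not neg & set(ranked):
            raise ValueError("labeled_only mode requires at least one negative in the ranking")
        evaluated = [g for g in ranked if g in pos or g in neg]
    else:
        evaluated = ranked
    ranks = [r for r, g in enumerate(evaluated, start=1) if g in pos]
    ap = float(np.mean([i / r for i, r in enumerate(ranks, start=1)]))
    if return_ranks:
        return ap, dict(zip((g for g in evaluated if g in pos), ranks))
    return ap


def mean_map(per_phenotype_aps) -> float:
    """MAP: arithmetic mean of per-phenotype average precisions."""
    aps = list(per_phenotype_aps)
    if not aps:
        raise ValueError("mean_map needs at least one AP value")
    return float(np.mean(aps))


def _ranked_items(scores: dict) -> tuple[list[str], np.ndarray]:
    """Genes sorted by descending score, ties broken by ascending symbol."""
    items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    genes = [normalize_gene(g) for g, _ in items]
    vals = np.array([v for _, v in items], dtype=float)
    return genes, vals


def _running_sum(hit_mask: np.ndarray, vals: np.ndarray, p: float) -> np.ndarray:
    n = len(hit_mask)
    n_hit = int(hit_mask.sum())
    increments = np.zeros(n)
    w = np.abs(vals[hit_mask]) ** p
    total = w.sum()
    if total == 0:  # all-zero scores in the set: fall back to unweighted hits
        increments[hit_mask] = 1.0 / n_hit
    else:
        increments[hit_mask] = w / total
    if n_hit < n:
        increments[~hit_mask] = -1.0 / (n - n_hit)
    return np.cumsum(increments)


def gsea_enrichment(scores: dict, gene_set, weight_exponent: float = 1.0) -> float:
    """Signed enrichment score of ``gene_set`` within a score-ranked list.

    The running sum gains ``|score|^p / sum_set |score|^p`` at set members and
    loses ``1/(N - N_hit)`` elsewhere; the ES is the extremum of largest
    magnitude (positive ES: the set concentrates at the top).
    """
    genes, vals = _ranked_items(scores)
    members = {normalize_gene(g) for g in gene_set}
    hit = np.array([g in members for g in genes])
    if not hit.any():
        raise ValueError("gene set is disjoint from the scored genes")
    if hit.all():
        log.warning("gene set covers every scored gene; ES degenerates to 1.0")
    rs = _running_sum(hit, vals, weight_exponent)
    idx = int(np.argmax(np.abs(rs)))
    return float(rs[idx])


def gsea_pvalue(scores: dict, gene_set, n_perm: int = 1000, seed: int = 0,
                weight_exponent: float = 1.0) -> float:
    """Permutation p-value for the enrichment score.

    The null resamples size-matched gene sets (labels drawn without
    replacement from the scored genes). When the number of distinct subsets
    of that size is small enough to enumerate within ``n_perm`` draws, the
    null is computed exactly over all subsets (p = fraction of subsets with
    |ES| at least as extreme, the observed set included); otherwise ``n_perm``
    random draws are used with the +1 correction so p is never exactly zero.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    genes, vals = _ranked_items(scores)
    members = {normalize_gene(g) for g in gene_set}
    hit_obs = np.array([g in members for g in genes])
    k = int(hit_obs.sum())
    n = len(genes)
    if k >= n:
        raise ValueError("gene set must be smaller than the scored universe")
    rs = _running_sum(hit_obs, vals, weight_exponent)
    es_obs = rs[int(np.argmax(np.abs(rs)))]

    def es_of(hit: np.ndarray) -> float:
        r = _running_sum(hit, vals, weight_exponent)
        return float(r[int(np.argmax(np.abs(r)))])

    from math import comb

    if comb(n, k) <= n_perm:
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), k):
            hit = np.zeros(n, dtype=bool)
            hit[list(combo)] = True
            if abs(es_of(hit)) >= abs(es_obs) - 1e-12:
                count += 1
            total += 1
        return count / total
    rng = np.random.default_rng(seed)
    extreme = 0
    for _ in range(n_perm):
        idx = rng.choice(n, size=k, replace=False)
        hit = np.zeros(n, dtype=bool)
        hit[idx] = True
        if abs(es_of(hit)) >= abs(es_obs) - 1e-12:
            extreme += 1
    return (1 + extreme) / (n_perm + 1)


def evaluate_ranking(ranked_by_phenotype: dict, labels_by_phenotype: dict,
                     mode: str = "auto") -> RankingEvaluation:
    """AP per phenotype + MAP for a dict of rankings and (pos, neg) labels."""
    aps = {}
    ranks = {}
    used_mode = mode
    for phen, ranked in ranked_by_phenotype.items():
        pos, neg = labels_by_phenotype[phen]
        ap, r = average_precision(ranked, pos, neg, mode=mode, return_ranks=True)
        aps[phen] = ap
        ranks[phen] = r
    return RankingEvaluation(
        ap_per_phenotype=aps,
        map_score=mean_map(aps.values()),
        positive_ranks=ranks,
        mode=used_mode,
    )
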