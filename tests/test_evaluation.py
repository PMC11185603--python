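"""Average precision / MAP and GSEA enrichment."""

import itertools

import numpy as np
import pytest
from scipy.stats import kstest

from immunorank.evaluation import (
    average_precision,
    gsea_enrichment,
    gsea_pvalue,
    mean_map,
)


def ap_oracle(labels, mode):
    """Brute-force AP: mean precision-at-rank over positives.

    ``labels`` is the ranked list of 'P'/'N'/'U' marks. Independent of the
    implementation under test: literal precision@k scan.
    """
    if mode == "labeled_only":
        labels = [l for l in labels if l != "U"]
    precisions = []
    n_pos_seen = 0
    for k, lab in enumerate(labels, start=1):
        if lab == "P":
            n_pos_seen += 1
            precisions.append(n_pos_seen / k)
    return sum(precisions) / len(precisions)


def _ap_from_labels(labels, mode):
    genes = [f"g{i}" for i in range(len(labels))]
    pos = {g for g, l in zip(genes, labels) if l == "P"}
    neg = {g for g, l in zip(genes, labels) if l == "N"}
    return average_precision(genes, pos, neg, mode=mode)


class TestAveragePrecision:
    def test_worked_labeled_example(self):
        assert _ap_from_labels(["P", "N", "P"], "labeled_only") == pytest.approx(
            (1 / 1 + 2 / 3) / 2)

    def test_perfect_ranking_is_one(self):
        assert _ap_from_labels(["P", "P", "N", "N"], "labeled_only") == 1.0

    def test_full_list_single_positive(self):
        labels = ["U"] * 10
        labels[3] = "P"
        assert _ap_from_labels(labels, "full_list") == pytest.approx(0.25)

    def test_unlabeled_genes_ignored_in_labeled_mode(self):
        assert _ap_from_labels(["U", "P", "U", "N", "P"], "labeled_only") == (
            pytest.approx(_ap_from_labels(["P", "N", "P"], "labeled_only")))

    def test_auto_mode_prefers_labeled_only(self):
        with_neg = _ap_from_labels(["N", "U", "P"], "auto")
        assert with_neg == pytest.approx(0.5)  # labeled sublist [N, P]

    def test_no_positive_in_ranking_fatal(self):
        with pytest.raises(ValueError, match="known-positive"):
            average_precision(["a", "b"], {"zz"}, set())

    def test_overlapping_labels_fatal(self):
        with pytest.raises(ValueError, match="overlap"):
            average_precision(["a"], {"a"}, {"a"})

    def test_moving_positive_up_never_decreases_ap(self):
        labels = ["N", "N", "P", "N", "P", "N"]
        base = _ap_from_labels(labels, "labeled_only")
        up = ["N", "P", "N", "N", "P", "N"]
        assert _ap_from_labels(up, "labeled_only") >= base

    def test_matches_oracle_on_all_small_permutations(self):
        """Exhaustive equivalence with the brute-force precision@k oracle."""
        for n in range(2, 6):
            for labels in itertools.product("PNU", repeat=n):
                if "P" not in labels:
                    continue
                if "N" in labels:
                    assert _ap_from_labels(list(labels), "labeled_only") == (
                        pytest.approx(ap_oracle(list(labels), "labeled_only")))
                assert _ap_from_labels(list(labels), "full_list") == (
                    pytest.approx(ap_oracle(list(labels), "full_list")))

    def test_ap_one_iff_positives_lead(self):
        for labels in itertools.product("PN", repeat=5):
            if "P" not in labels or "N" not in labels:
                continue
            ap = _ap_from_labels(list(labels), "labeled_only")
            leads = all(i < labels.index("N") for i, l in enumerate(labels) if l == "P")
            assert (ap == 1.0) == leads


class TestMeanMap:
    def test_values(self):
        assert mean_map([0.5]) == 0.5
        assert mean_map([0.2, 0.4, 0.6]) == pytest.approx(0.4)
        assert mean_map([1.0, 1.0]) == 1.0

    def test_empty_fatal(self):
        with pytest.raises(ValueError):
            mean_map([])


def gsea_oracle(scores, gene_set, p=1.0):
    """Independent running-sum ES: explicit python loop over the ranking."""
    items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    hits = [g in gene_set for g, _ in items]
    denom = sum(abs(v) ** p for (g, v), h in zip(items, hits) if h)
    n_miss = len(items) - sum(hits)
    running, best = 0.0, 0.0
    for (g, v), h in zip(items, hits):
        if h:
            running += (abs(v) ** p) / denom if denom else 1.0 / sum(hits)
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


class TestGseaEnrichment:
    SCORES = {"a": 3.0, "b": 2.0, "c": 1.0}

    def test_top_gene_set_es_plus_one(self):
        assert gsea_enrichment(self.SCORES, {"a"}) == pytest.approx(1.0)

    def test_bottom_gene_set_es_minus_one(self):
        assert gsea_enrichment(self.SCORES, {"c"}) == pytest.approx(-1.0)

    def test_full_universe_degenerate_es_one(self):
        assert gsea_enrichment(self.SCORES, {"a", "b", "c"}) == pytest.approx(1.0)

    def test_disjoint_set_fatal(self):
        with pytest.raises(ValueError, match="disjoint"):
            gsea_enrichment(self.SCORES, {"zz"})

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            n = int(rng.integers(4, 25))
            scores = {f"g{i}": float(rng.normal()) for i in range(n)}
            k = int(rng.integers(1, n))
            gene_set = set(rng.choice(sorted(scores), size=k, replace=False))
            assert gsea_enrichment(scores, gene_set) == pytest.approx(
                gsea_oracle(scores, gene_set)), (scores, gene_set)

    def test_es_bounded_and_rank_based_at_p_zero(self):
        rng = np.random.default_rng(10)
        scores = {f"g{i}": float(rng.normal()) for i in range(30)}
        gene_set = set(list(scores)[:7])
        es = gsea_enrichment(scores, gene_set, weight_exponent=0.0)
        assert -1 <= es <= 1
        # strictly monotone relabeling of scores preserves the p=0 statistic
        warped = {g: np.exp(v) for g, v in scores.items()}
        assert gsea_enrichment(warped, gene_set, weight_exponent=0.0) == (
            pytest.approx(es))


class TestGseaPvalue:
    def test_single_gene_set_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(11)
        scores = {f"g{i}": float(rng.normal()) for i in range(12)}
        top = max(scores, key=scores.get)
        p = gsea_pvalue(scores, {top}, n_perm=1000, seed=0)
        es_obs = abs(gsea_enrichment(scores, {top}))
        count = sum(abs(gsea_oracle(scores, {g})) >= es_obs - 1e-12 for g in scores)
        assert p == pytest.approx(count / len(scores))

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(12)
        scores = {f"g{i}": float(rng.normal()) for i in range(40)}
        gene_set = set(list(scores)[:6])
        p1 = gsea_pvalue(scores, gene_set, n_perm=300, seed=5)
        p2 = gsea_pvalue(scores, gene_set, n_perm=300, seed=5)
        assert p1 == p2

    def test_null_pvalues_roughly_uniform(self):
        """Random sets under shuffled scores: KS check at alpha=0.01."""
        rng = np.random.default_rng(13)
        genes = [f"g{i}" for i in range(30)]
        ps = []
        for _ in range(200):
            scores = dict(zip(genes, rng.normal(size=30)))
            gene_set = set(rng.choice(genes, size=4, replace=False))
            ps.append(gsea_pvalue(scores, gene_set, n_perm=200, seed=int(rng.integers(1 << 31))))
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_oversized_set_fatal(self):
        scores = {"a": 1.0, "b": 0.5}
        with pytest.raises(ValueError, match="smaller"):
            gsea_pvalue(scores, {"a", "b"}, n_perm=100, seed=0)
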