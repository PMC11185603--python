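"""Enrichment feature extraction from database snapshots."""

import numpy as np
import pandas as pd
import pytest

from immunorank.enrichment import (
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
from immunorank.expression import ExpressionDataset, summarize_expression


def _normal_db(rows, threshold=10.0):
    df = pd.DataFrame(rows, columns=["gene", "tissue", "sample_id", "value", "is_brain"])
    return NormalExpressionDB(records=df, name="db", high_threshold=threshold)


def _worked_db():
    rows = []
    for tissue, vals, brain in (("A", [5, 15], False), ("B", [0, 2], False),
                                ("Brain", [50, 60], True)):
        for j, v in enumerate(vals):
            rows.append(("G", tissue, f"{tissue}{j}", float(v), brain))
    return _normal_db(rows)


class TestNormalExpression:
    def test_worked_example_with_and_without_brain(self):
        feats = normal_expression_features(_worked_db(), ["G"]).loc["G"]
        assert feats["db_max_tissue"] == 55        # median of brain samples
        assert feats["db_max_sample"] == 60
        assert feats["db_n_tissues_high"] == 1
        assert feats["db_n_samples_high"] == 3
        assert feats["db_max_tissue_nobrain"] == 10
        assert feats["db_max_sample_nobrain"] == 15
        assert feats["db_n_tissues_high_nobrain"] == 0
        assert feats["db_n_samples_high_nobrain"] == 1

    def test_absent_gene_all_features_missing(self):
        feats = normal_expression_features(_worked_db(), ["G", "OTHER"])
        assert feats.loc["OTHER"].isna().all()
        assert feats.shape == (2, 10)

    def test_threshold_tie_is_strict(self):
        db = _normal_db([("G", "A", "s1", 10.0, False)])
        feats = normal_expression_features(db, ["G"]).loc["G"]
        assert feats["db_n_tissues_high"] == 0
        assert feats["db_n_samples_high"] == 0

    def test_record_order_invariance(self):
        db1 = _worked_db()
        shuffled = db1.records.sample(frac=1.0, random_state=5)
        db2 = NormalExpressionDB(records=shuffled, name="db", high_threshold=10.0)
        pd.testing.assert_frame_equal(
            normal_expression_features(db1, ["G"]),
            normal_expression_features(db2, ["G"]),
        )

    def test_brain_excluded_max_never_exceeds_all_tissue_max(self, small_data):
        db = small_data.normal_dbs[0]
        genes = small_data.expression[small_data.phenotypes[0]].gene_ids
        feats = normal_expression_features(db, genes).dropna()
        for stem in ("max_tissue", "max_sample"):
            assert (feats[f"{db.name}_{stem}_nobrain"]
                    <= feats[f"{db.name}_{stem}"] + 1e-12).all()

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        rows = []
        genes = [f"G{i}" for i in range(6)]
        tissues = [("T1", False), ("T2", False), ("BrainX", True)]
        for g in genes:
            for t, brain in tissues:
                for j in range(rng.integers(1, 4)):
                    rows.append((g, t, f"{g}_{t}_{j}", float(rng.gamma(2, 4)), brain))
        db = _normal_db(rows, threshold=6.0)
        feats = normal_expression_features(db, genes)
        rec = db.records
        for g in genes:
            sub = rec[rec["gene"] == g]
            med = {t: sub[sub["tissue"] == t]["value"].median()
                   for t in sub["tissue"].unique()}
            counts = {t: (sub["tissue"] == t).sum() for t in med}
            total = len(sub)
            assert feats.loc[g, "db_max_tissue"] == pytest.approx(max(med.values()))
            assert feats.loc[g, "db_max_sample"] == pytest.approx(sub["value"].max())
            assert feats.loc[g, "db_n_tissues_high"] == sum(v > 6.0 for v in med.values())
            assert feats.loc[g, "db_n_samples_high"] == (sub["value"] > 6.0).sum()
            assert feats.loc[g, "db_norm_max"] == pytest.approx(
                max(med[t] * counts[t] / total for t in med))

    def test_proteomics_threshold_is_90th_percentile(self):
        rng = np.random.default_rng(3)
        rows = [(f"G{i}", "T", f"s{i}", float(v), False)
                for i, v in enumerate(rng.gamma(3, 100, size=50))]
        db = NormalExpressionDB(records=pd.DataFrame(
            rows, columns=["gene", "tissue", "sample_id", "value", "is_brain"]),
            high_threshold=None)
        assert db.resolved_threshold() == pytest.approx(
            np.percentile(db.records["value"], 90))


class TestLocalization:
    def test_passthrough_and_partial_records(self):
        db = LocalizationDB(table=pd.DataFrame(
            {"conf_a": [4.0, 4.0], "conf_b": [5.0, np.nan],
             "ecd_length": [320.0, np.nan]}, index=["A", "B"]))
        feats = localization_features(db, ["A", "B", "C"])
        assert tuple(feats.loc["A"]) == (4, 5, 320)
        assert feats.loc["B", "conf_a"] == 4
        assert np.isnan(feats.loc["B", "conf_b"])
        assert feats.loc["C"].isna().all()

    def test_out_of_range_confidence_rejected_at_load(self):
        with pytest.raises(ValueError, match="0–4"):
            LocalizationDB(table=pd.DataFrame(
                {"conf_a": [7.0], "conf_b": [1.0], "ecd_length": [10.0]}, index=["A"]))


class TestDependency:
    @pytest.fixture()
    def db(self):
        rec = pd.DataFrame({
            "gene": ["G", "G", "H"], "cell_line": ["c1", "c2", "c1"],
            "probability": [0.2, 0.9, 0.4],
        })
        return DependencyDB(records=rec,
                            cell_line_phenotypes={"c1": "nbl", "c2": "nbl", "c3": "ews"})

    def test_mean_and_max_aggregation(self, db):
        mean = dependency_feature(db, "NBL", ["G"], agg="mean")
        assert mean.loc["G"] == pytest.approx(0.55)
        mx = dependency_feature(db, "nbl", ["G"], agg="max")
        assert mx.loc["G"] == pytest.approx(0.9)

    def test_phenotype_without_lines_gives_missing(self, db):
        out = dependency_feature(db, "osteosarcoma", ["G", "H"])
        assert out.isna().all()

    def test_unknown_aggregation_rejected(self, db):
        with pytest.raises(ValueError, match="aggregation"):
            dependency_feature(db, "nbl", ["G"], agg="median")

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            DependencyDB(records=pd.DataFrame(
                {"gene": ["G"], "cell_line": ["c"], "probability": [1.4]}),
                cell_line_phenotypes={"c": "x"})


class TestGeneSets:
    def test_membership_columns_in_requested_order(self):
        db = GeneSetDB(sets={"s1": {"A"}, "s2": {"A", "B"}})
        feats = geneset_features(db, ["s2", "s1"], ["A", "B", "C"])
        assert list(feats.columns) == ["s2", "s1"]
        assert feats.loc["A"].tolist() == [1.0, 1.0]
        assert feats.loc["B"].tolist() == [1.0, 0.0]
        assert feats.loc["C"].tolist() == [0.0, 0.0]

    def test_unknown_set_rejected_with_available_names(self):
        db = GeneSetDB(sets={"s1": {"A"}})
        with pytest.raises(KeyError, match="s1"):
            geneset_features(db, ["nope"], ["A"])

    def test_adding_gene_flips_exactly_one_cell(self):
        genes = ["A", "B", "C"]
        before = geneset_features(GeneSetDB(sets={"s": {"A"}}), ["s"], genes)
        after = geneset_features(GeneSetDB(sets={"s": {"A", "C"}}), ["s"], genes)
        diff = (after - before).to_numpy()
        assert diff.sum() == 1.0 and (diff >= 0).all()


class TestTherapy:
    RECORDS = [
        TherapyRecord("CD19", "b-all", "approved", moa="car-t"),
        TherapyRecord("CD19", "b-all", "discontinued", moa="adc"),
        TherapyRecord("EGFR", "b-all", "discontinued", moa="adc"),
        TherapyRecord("GPC2", "nbl", "phase1", moa="adc"),
    ]

    def test_best_record_wins_and_labels(self):
        feat, pos, neg = therapy_features(self.RECORDS, "B-ALL", ["CD19", "EGFR", "GPC2"])
        assert feat.loc["CD19"] == pytest.approx(1.0)  # approved dominates discontinued
        assert "CD19" in pos and "CD19" not in neg
        assert feat.loc["EGFR"] == pytest.approx(-0.5)
        assert "EGFR" in neg
        assert np.isnan(feat.loc["GPC2"])  # different disease

    def test_moa_filter_excludes_records(self):
        feat, pos, _ = therapy_features(self.RECORDS, "b-all",
                                        ["CD19"], moa_filter={"adc"})
        # only the discontinued ADC record matches the filter
        assert feat.loc["CD19"] == pytest.approx(-0.5)
        assert "CD19" not in pos

    def test_empty_record_list_gives_empty_labels(self):
        feat, pos, neg = therapy_features([], "b-all", ["CD19"])
        assert pos == set() and neg == set()
        assert feat.isna().all()

    def test_custom_phase_map(self):
        feat, _, _ = therapy_features(self.RECORDS, "nbl", ["GPC2"],
                                      phase_scores={"phase1": 0.9, "approved": 1.0,
                                                    "discontinued": -1.0,
                                                    "phase3": 0.8, "phase2": 0.6,
                                                    "preclinical": 0.2})
        assert feat.loc["GPC2"] == pytest.approx(0.9)


class TestBuildFeatureMatrix:
    @pytest.fixture()
    def summary(self):
        ds = ExpressionDataset(values=pd.DataFrame(
            np.arange(12.0).reshape(3, 4) + 1.0,
            index=["A", "B", "C"], columns=list("wxyz")))
        return summarize_expression(ds)

    def test_concatenation_shape_and_provenance(self, summary):
        loc = pd.DataFrame({"conf_a": [1.0], "conf_b": [2.0], "ecd_length": [3.0]},
                           index=["A"])
        dep = pd.Series([0.5, 0.7, np.nan], index=["A", "B", "C"], name="dependency")
        m = build_feature_matrix(summary, {"loc": loc, "dep": dep})
        assert m.raw.shape == (3, 9)
        assert m.provenance["mean_expr"] == "expression_summary"
        assert m.provenance["conf_a"] == "loc"
        # gene absent from a block keeps its summary but gets missing features
        assert m.raw.loc["B", ["conf_a", "conf_b", "ecd_length"]].isna().all()
        assert not m.raw.loc["B", "mean_expr"] != m.raw.loc["B", "mean_expr"]

    def test_selection_orders_columns(self, summary):
        m = build_feature_matrix(summary, {}, selection=["n_high", "mean_expr"])
        assert m.feature_names == ["n_high", "mean_expr"]

    def test_unknown_selection_rejected(self, summary):
        with pytest.raises(KeyError, match="nope"):
            build_feature_matrix(summary, {}, selection=["nope"])
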