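"""Quasi H-scores, quartile categorization, and the nine cascade filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adcscout.cascade import (
    CascadeConfig,
    categorize_quartiles,
    check_consistency_6a,
    evidence_score,
    filter_critical_normal,
    filter_dual_quasi_h,
    filter_evidence,
    filter_hsc_mpp,
    filter_membrane_evidence,
    filter_surfaceome,
    filter_tumor_quasi_h,
    ihc_quasi_h_table,
    ihc_tissue_categories,
    mrna_quasi_h_table,
    quasi_h_from_expression,
    quasi_h_from_fractions,
    run_cascade,
)
from adcscout.io import ConfigError, ExpressionMatrix, Level
from adcscout.synthetic import generate_target_inputs


def _normal(rows):
    df = pd.DataFrame(rows, columns=["gene", "tissue", "cell_type", "level"])
    df["level"] = pd.Categorical(
        df["level"], categories=["Not detected", "Low", "Medium", "High"], ordered=True
    )
    return df


def _matrix(values, index, columns, cohorts, unit="FPKM"):
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=index, columns=columns),
        cohort_of=pd.Series(cohorts, index=columns),
        unit=unit,
    )


class TestQuasiHFromFractions:
    @pytest.mark.parametrize(
        "fractions,expected",
        [((0, 0, 100), 300.0), ((0, 0, 0), 0.0), ((20, 30, 50), 230.0), ((0, 0, 60), 180.0)],
    )
    def test_formula(self, fractions, expected):
        assert quasi_h_from_fractions(*fractions) == pytest.approx(expected)

    def test_fraction_sum_over_100_rejected(self):
        with pytest.raises(ValueError, match="more than 100"):
            quasi_h_from_fractions(60, 50, 20)

    @given(
        st.tuples(st.floats(0, 100), st.floats(0, 100), st.floats(0, 100)).filter(
            lambda t: sum(t) <= 100
        )
    )
    @settings(max_examples=100, derandomize=True)
    def test_bounds_and_maximum_attained_only_at_all_high(self, fracs):
        score = quasi_h_from_fractions(*fracs)
        assert 0.0 <= score <= 300.0
        if score == 300.0:
            assert fracs[2] == 100.0


class TestCategorizeQuartiles:
    def test_four_level_example(self):
        # Q1 = 1.75, Q3 = 5.25 for 0..7 under linear interpolation
        cats = categorize_quartiles(np.arange(8), "four_level")
        expected = [0, 1, 2, 2, 2, 2, 3, 3]
        assert list(cats) == expected

    def test_all_zero_is_not_detected(self):
        assert set(categorize_quartiles([0, 0, 0, 0], "four_level")) == {0}

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="insufficient samples"):
            categorize_quartiles([1, 2, 3], "four_level")

    def test_value_at_q1_low_in_four_level_medium_in_three_level(self):
        values = [1.0, 1.0, 3.0, 5.0]  # Q1 = 1.0
        assert categorize_quartiles(values, "four_level")[0] == Level.LOW
        assert categorize_quartiles(values, "three_level")[0] == Level.MEDIUM

    def test_value_at_q3_is_medium_in_both_schemes(self):
        values = [1.0, 2.0, 4.0, 4.0]  # Q3 = 4.0
        assert categorize_quartiles(values, "four_level")[2] == Level.MEDIUM
        assert categorize_quartiles(values, "three_level")[2] == Level.MEDIUM

    @given(
        st.lists(st.floats(0, 1e4, allow_nan=False), min_size=4, max_size=40),
        st.floats(0.01, 1e3),
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotone_and_scale_invariant(self, values, scale):
        cats = categorize_quartiles(values, "four_level")
        order = np.argsort(values)
        nonzero = [i for i in order if values[i] > 0]
        assert all(
            cats[a] <= cats[b] for a, b in zip(nonzero, nonzero[1:])
        ), "categories must be monotone in value"
        scaled = categorize_quartiles(np.asarray(values) * scale, "four_level")
        assert list(scaled) == list(cats)


class TestQuasiHFromExpression:
    def _cohort_matrix(self, values):
        cols = [f"S{i}" for i in range(len(values))]
        return _matrix([values], ["G"], cols, ["BRCA"] * len(values))

    def test_uniform_values_score_200(self):
        m = self._cohort_matrix([5.0, 5.0, 5.0, 5.0])
        assert quasi_h_from_expression(m, "BRCA", "G") == pytest.approx(200.0)

    def test_mixed_example_scores_200(self):
        # {1,2,3,100}: Q1=1.75, Q3=27.25 -> (low, med, med, high) -> 25+100+75
        m = self._cohort_matrix([1.0, 2.0, 3.0, 100.0])
        assert quasi_h_from_expression(m, "BRCA", "G") == pytest.approx(200.0)

    def test_score_bounded_in_100_300(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m = self._cohort_matrix(list(rng.lognormal(1, 1, 12)))
            score = quasi_h_from_expression(m, "BRCA", "G")
            assert 100.0 <= score <= 300.0

    def test_absent_gene_names_the_gene(self):
        m = self._cohort_matrix([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(KeyError, match="MISSING"):
            quasi_h_from_expression(m, "BRCA", "MISSING")


class TestAnnotationFilters:
    def test_membrane_and_evidence(self, annotations_frame):
        res = filter_membrane_evidence(annotations_frame)
        assert res.kept == ["A", "D"]
        assert res.dropped["B"] == "no protein evidence"
        assert res.dropped["C"] == "no membrane annotation"

    def test_surfaceome_intersection(self, annotations_frame):
        res = filter_surfaceome(["A", "D"], annotations_frame)
        assert res.kept == ["A"]
        assert res.dropped["D"] == "not in surfaceome"

    def test_evidence_scoring_and_drop(self, annotations_frame):
        scores = evidence_score(annotations_frame)
        assert scores["A"] == 2 and scores["B"] == 0
        res, _ = filter_evidence(["A", "B"], annotations_frame)
        assert res.kept == ["A"] and "B" in res.dropped

    def test_filters_idempotent(self, annotations_frame):
        first = filter_membrane_evidence(annotations_frame)
        second = filter_membrane_evidence(annotations_frame, first.kept)
        assert second.kept == first.kept and second.dropped == {}


class TestCriticalNormal:
    def _records(self):
        return _normal(
            [
                ("A", "liver", "hepatocytes", "High"),
                ("A", "lung", "pneumocytes", "Low"),
                ("B", "liver", "hepatocytes", "Medium"),
                ("B", "lung", "pneumocytes", "Medium"),
                ("C", "cerebellum", "Purkinje cells", "High"),
                ("C", "liver", "hepatocytes", "Low"),
            ]
        )

    def test_high_in_critical_dropped(self):
        res = filter_critical_normal(self._records(), ["A", "B", "C"], ("liver", "lung"))
        assert res.kept == ["B", "C"]
        assert "liver" in res.dropped["A"]

    def test_high_only_in_noncritical_kept(self):
        # cerebellum is not on the critical list; C stays
        res = filter_critical_normal(self._records(), ["C"], ("liver", "lung"))
        assert res.kept == ["C"]

    def test_unknown_critical_tissue_is_config_error(self):
        with pytest.raises(ConfigError, match="spleen"):
            filter_critical_normal(self._records(), ["A"], ("spleen",))


class TestTumorQuasiH:
    def _pathology(self, rows):
        return pd.DataFrame(
            rows, columns=["gene", "cancer_type", "frac_low", "frac_medium", "frac_high"]
        )

    def test_strictly_above_threshold_in_one_cancer(self):
        path = self._pathology(
            [("A", "BRCA", 20, 60, 0), ("A", "LUAD", 1, 0, 50), ("B", "BRCA", 0, 75, 0)]
        )
        # A: 140 and 151; B: 150 exactly -> dropped under strict >
        table, res = filter_tumor_quasi_h(path, ["A", "B"], 150.0)
        assert res.kept == ["A"]
        assert "B" in res.dropped
        assert len(table) == 1 and table.loc[0, "cancer_type"] == "LUAD"

    def test_no_tumor_data_reason(self):
        table, res = filter_tumor_quasi_h(self._pathology([]), ["A"], 150.0)
        assert res.dropped["A"] == "no tumor data"

    def test_missing_ihc_falls_back_to_mrna_score(self):
        path = self._pathology([("A", "BRCA", 0, 0, 10)])  # score 30, fails alone
        fallback = pd.DataFrame({"LUAD": [200.0]}, index=["A"])
        table, res = filter_tumor_quasi_h(path, ["A"], 150.0, fallback_scores=fallback)
        assert res.kept == ["A"]
        assert table.loc[0, "source"] == "mrna"


class TestConsistency6a:
    def _cats(self, data):
        return pd.DataFrame(data).T  # gene -> {tissue: code}

    def test_identical_passes_both_policies(self):
        m = self._cats({"A": {"liver": 1.0, "lung": 2.0}})
        for policy in ("within_one", "exact"):
            assert check_consistency_6a(m, m.copy(), ["A"], policy).kept == ["A"]

    def test_distance_three_fails_both(self):
        m = self._cats({"A": {"liver": 3.0}})
        h = self._cats({"A": {"liver": 0.0}})
        for policy in ("within_one", "exact"):
            res = check_consistency_6a(m, h, ["A"], policy)
            assert "A" in res.dropped

    def test_distance_one_passes_within_one_only(self):
        m = self._cats({"A": {"liver": 2.0}})
        h = self._cats({"A": {"liver": 3.0}})
        assert check_consistency_6a(m, h, ["A"], "within_one").kept == ["A"]
        assert "A" in check_consistency_6a(m, h, ["A"], "exact").dropped

    def test_no_overlap_fails(self):
        m = self._cats({"A": {"liver": 2.0}})
        h = self._cats({"A": {"lung": 2.0}})
        res = check_consistency_6a(m, h, ["A"])
        assert res.dropped["A"] == "no overlapping evidence"

    def test_ihc_categories_take_max_over_cell_types(self):
        df = _normal(
            [("A", "liver", "hepatocytes", "Low"), ("A", "liver", "bile duct cells", "High")]
        )
        cats = ihc_tissue_categories(df)
        assert cats.loc["A", "liver"] == 3.0


class TestDualQuasiH:
    def test_absent_from_mrna_dropped(self):
        ihc = pd.DataFrame({"BRCA": [200.0]}, index=["A"])
        mrna = pd.DataFrame(columns=["BRCA"], dtype=float)
        res = filter_dual_quasi_h(["A"], ihc, mrna, 150.0)
        assert res.dropped["A"] == "absent from tumor mRNA data"

    def test_requires_same_cancer_to_clear_in_both(self):
        ihc = pd.DataFrame({"BRCA": [200.0], "LUAD": [100.0]}, index=["A"] * 1)
        mrna = pd.DataFrame({"BRCA": [180.0], "LUAD": [200.0]}, index=["A"])
        assert filter_dual_quasi_h(["A"], ihc, mrna, 150.0).kept == ["A"]
        mrna_bad = pd.DataFrame({"BRCA": [140.0], "LUAD": [200.0]}, index=["A"])
        assert "A" in filter_dual_quasi_h(["A"], ihc, mrna_bad, 150.0).dropped


class TestHscMpp:
    def _hema(self):
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(50)]
        cols = ["HSC_1", "HSC_2", "MPP_1", "Mono_1", "Mono_2", "Ery_1"]
        values = rng.lognormal(1, 1, (50, 6))
        m = _matrix(values, genes, cols, [c.rsplit("_", 1)[0] for c in cols], unit="AU")
        return m

    def test_high_mean_dropped_and_labels_partition(self):
        m = self._hema()
        q1, q3 = np.quantile(m.values.to_numpy().ravel(), [0.25, 0.75])
        m.values.loc["G0", ["HSC_1", "HSC_2", "MPP_1"]] = q3 * 3
        m.values.loc["G1", ["HSC_1", "HSC_2", "MPP_1"]] = q1 / 3
        m.values.loc["G2", ["HSC_1", "HSC_2", "MPP_1"]] = (q1 + q3) / 2
        res, labels = filter_hsc_mpp(m, ["G0", "G1", "G2"], ["HSC_1", "HSC_2", "MPP_1"])
        assert res.dropped["G0"] == "high expression on HSC/MPP cells"
        assert labels["G1"] == Level.LOW and labels["G2"] == Level.MEDIUM
        assert set(res.kept) == set(labels)

    def test_absent_gene_dropped_with_reason(self):
        res, _ = filter_hsc_mpp(self._hema(), ["NOPE"], ["HSC_1"])
        assert res.dropped["NOPE"] == "absent from hematopoietic study"

    def test_no_designated_samples_is_config_error(self):
        with pytest.raises(ConfigError, match="HSC/MPP"):
            filter_hsc_mpp(self._hema(), ["G0"], [])


class TestRunCascade:
    def test_trace_counts_monotone(self, cascade_result):
        counts = [n for _, n in cascade_result.trace.counts]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_stage_survivors_nested(self, cascade_result):
        # every drop reason is recorded exactly once per item
        reasons = cascade_result.trace.drop_reasons()
        assert reasons["item"].is_unique

    def test_empty_universe_gives_nine_zero_stages(self):
        bundle = generate_target_inputs(0, seed=0)
        res = run_cascade(
            bundle.annotations,
            bundle.normal_ihc,
            bundle.pathology,
            None,
            None,
            None,
            CascadeConfig(),
        )
        assert len(res.trace.stages) == 9
        assert all(n == 0 for _, n in res.trace.counts)
        assert res.prioritized == []

    def test_invalid_threshold_rejected_before_compute(self, target_bundle):
        with pytest.raises(ConfigError, match="outside"):
            run_cascade(
                target_bundle.annotations,
                target_bundle.normal_ihc,
                target_bundle.pathology,
                None,
                None,
                None,
                CascadeConfig(quasi_h_threshold=400.0),
            )

    def test_score_matrices_cover_survivors(self, cascade_result):
        for gene in cascade_result.prioritized:
            assert gene in cascade_result.ihc_scores.index
            assert gene in cascade_result.mrna_scores.index
        final = cascade_result.final_indications
        assert set(final["gene"]) <= set(cascade_result.prioritized)
        assert (final["score"] > 150.0).all()
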