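"""Compound dedupe, sensitivity windows, response screening and clustering."""

import numpy as np
import pandas as pd
import pytest

from adcscout.io import ConfigError
from adcscout.payloads import (
    PayloadConfig,
    classify_sensitivity,
    cluster_profiles,
    cumulative_response,
    dedupe_compounds,
    drop_failed,
    partition_groups,
    response_profiles,
    run_payload_pipeline,
)
from adcscout.synthetic import GroupSpec, generate_gi50_inputs


def _meas(rows):
    return pd.DataFrame(
        rows,
        columns=["nsc_id", "name", "cell_line", "panel", "log_gi50", "failed_screen", "status"],
    )


class TestDedupe:
    def test_case_and_whitespace_variants_merge_to_smallest_nsc(self):
        m = _meas(
            [
                (2, "taxol ", "A", "Leukemia", -8.5, False, "none"),
                (1, "Taxol", "A", "Leukemia", -8.4, False, "none"),
            ]
        )
        out = dedupe_compounds(m)
        assert set(out["nsc_id"]) == {1}
        assert set(out["name"]) == {"Taxol"}

    def test_unnamed_compounds_never_merged(self):
        m = _meas(
            [
                (1, "", "A", "Leukemia", -6.0, False, "none"),
                (2, "", "A", "Leukemia", -6.0, False, "none"),
            ]
        )
        assert dedupe_compounds(m)["nsc_id"].nunique() == 2

    def test_injected_duplicates_reduce_count_by_k(self):
        bundle = generate_gi50_inputs(
            n_compounds=60,
            planted=GroupSpec(3, 5, 2, 2, 2),
            seed=4,
            n_duplicate_pairs=4,
        )
        before = bundle.measurements["nsc_id"].nunique()
        after = dedupe_compounds(bundle.measurements)["nsc_id"].nunique()
        assert after == before - 4
        assert len(bundle.truth.payload_groups["duplicate_pairs"]) == 4


class TestClassification:
    @pytest.mark.parametrize(
        "log,expected",
        [(-9.0, "picomolar"), (-10.5, "picomolar"), (-8.0, "low_nanomolar"),
         (-8.5, "low_nanomolar"), (-7.3, "none"), (-5.0, "none")],
    )
    def test_windows_with_inclusive_boundaries(self, log, expected):
        assert classify_sensitivity(log) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_sensitivity(float("nan"))

    def test_windows_disjoint_and_exhaustive_below_10nM(self):
        rng = np.random.default_rng(0)
        for log in rng.uniform(-12, -8, 200):
            assert classify_sensitivity(log) in ("picomolar", "low_nanomolar")


class TestResponseProfiles:
    def _renal(self, n_resp, n_lines, nsc=1, level=-8.5):
        rows = []
        for i in range(n_lines):
            v = level if i < n_resp else -6.0
            rows.append((nsc, "x", f"R{i}", "Renal Cancer", v, False, "none"))
        return _meas(rows)

    def test_percentage_arithmetic(self):
        prof = response_profiles(self._renal(4, 6), "low_nanomolar")
        assert prof.loc[1, "Renal Cancer"] == pytest.approx(100 * 4 / 6)

    def test_half_responsive_qualifies_at_default_threshold(self):
        rows = [
            (1, "x", "P1", "Prostate Cancer", -8.5, False, "none"),
            (1, "x", "P2", "Prostate Cancer", -6.0, False, "none"),
        ]
        prof = response_profiles(_meas(rows), "low_nanomolar")
        assert prof.loc[1, "Prostate Cancer"] == pytest.approx(50.0)
        assert bool(prof.loc[1, "qualifies"])

    def test_inactive_compound_not_in_any_class(self):
        rows = [(1, "x", "L1", "Leukemia", -6.0, False, "none")]
        assert response_profiles(_meas(rows), "low_nanomolar").empty
        assert response_profiles(_meas(rows), "picomolar").empty

    def test_unmeasured_panel_is_missing_not_zero(self):
        prof = response_profiles(self._renal(2, 2), "low_nanomolar")
        assert np.isnan(prof.loc[1, "Leukemia"])

    def test_replicate_duplication_invariance(self):
        base = self._renal(3, 6)
        doubled = pd.concat([base, base], ignore_index=True)
        a = response_profiles(base, "low_nanomolar")
        b = response_profiles(doubled, "low_nanomolar")
        pd.testing.assert_frame_equal(a, b)

    def test_picomolar_lines_count_toward_10nM_response(self):
        rows = [
            (1, "x", "R1", "Renal Cancer", -9.5, False, "none"),  # picomolar line
            (1, "x", "R2", "Renal Cancer", -8.5, False, "none"),  # band line
        ]
        prof = response_profiles(_meas(rows), "low_nanomolar")
        assert prof.loc[1, "Renal Cancer"] == pytest.approx(100.0)

    def test_pure_picomolar_compound_not_in_nano_class(self):
        rows = [(1, "x", "R1", "Renal Cancer", -9.5, False, "none")]
        assert response_profiles(_meas(rows), "low_nanomolar").empty
        assert not response_profiles(_meas(rows), "picomolar").empty


class TestPartitionAndFailures:
    def test_partition_conservation(self):
        groups = partition_groups([1, 2, 3], [3, 4])
        by = groups.set_index("nsc_id")["membership"]
        assert by[1] == "picomolar_only" and by[3] == "overlap" and by[4] == "low_nanomolar_only"
        assert len(groups) == 4
        assert groups["membership"].value_counts().sum() == len(set([1, 2, 3]) | set([3, 4]))

    def test_drop_failed_removes_flagged(self):
        prof = pd.DataFrame({"Renal Cancer": [100.0, 80.0]}, index=[1, 2])
        out = drop_failed(prof, pd.Series({1: True, 2: False}))
        assert list(out.index) == [2]


class TestClustering:
    def _blobs(self):
        rng = np.random.default_rng(0)
        a = 90 + rng.uniform(-5, 5, (6, 9))
        b = 10 + rng.uniform(-5, 5, (6, 9))
        from adcscout.io import NCI60_PANELS

        return pd.DataFrame(
            np.vstack([a, b]), index=range(1, 13), columns=list(NCI60_PANELS)
        )

    def test_two_separated_groups_recovered_at_k2(self):
        prof = self._blobs()
        labels = cluster_profiles(prof, 2)
        assert labels.loc[1:6].nunique() == 1
        assert labels.loc[7:12].nunique() == 1
        assert labels.loc[1] != labels.loc[12]

    def test_row_order_invariance(self):
        prof = self._blobs()
        shuffled = prof.sample(frac=1.0, random_state=5)
        pd.testing.assert_series_equal(cluster_profiles(prof, 3), cluster_profiles(shuffled, 3))

    def test_k_equal_n_gives_singletons(self):
        prof = self._blobs()
        labels = cluster_profiles(prof, len(prof))
        assert labels.nunique() == len(prof)

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError, match="clusters"):
            cluster_profiles(self._blobs(), 13)


class TestPipeline:
    def test_small_planted_partition_recovered(self):
        bundle = generate_gi50_inputs(
            n_compounds=80, planted=GroupSpec(4, 12, 3, 2, 5), seed=2, n_duplicate_pairs=2
        )
        result = run_payload_pipeline(
            bundle.measurements,
            PayloadConfig(cluster_counts={"picomolar_only": 2, "low_nanomolar_only": 3, "overlap": 2}),
        )
        assert result.group_sizes == {
            "picomolar_only": 4,
            "low_nanomolar_only": 12,
            "overlap": 3,
        }
        by = result.groups.set_index("nsc_id")["membership"]
        truth = bundle.truth.payload_groups
        for key in ("picomolar_only", "low_nanomolar_only", "overlap"):
            assert set(by.index[by == key]) == set(truth[key])

    def test_all_failed_gives_empty_groups(self):
        bundle = generate_gi50_inputs(
            n_compounds=10, planted=GroupSpec(0, 0, 0, 4, 6), seed=1, n_duplicate_pairs=0
        )
        result = run_payload_pipeline(bundle.measurements)
        assert result.groups.empty
        assert all(v == 0 for v in result.group_sizes.values())

    def test_traces_non_increasing_per_branch(self, payload_result):
        for trace in payload_result.traces.values():
            counts = [n for _, n in trace.counts]
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_zero_line_panel_is_config_error(self):
        with pytest.raises(ConfigError, match="no cell lines"):
            generate_gi50_inputs(
                n_compounds=10,
                lines_per_panel={"Leukemia": 0},
                planted=GroupSpec(0, 0, 0, 0, 0),
                seed=0,
                n_duplicate_pairs=0,
            )


def test_cumulative_response_reaches_100_only_when_all_lines_respond():
    rows = [
        (1, "p", "R1", "Renal Cancer", -8.5, False, "none"),
        (1, "p", "R2", "Renal Cancer", -9.5, False, "none"),
        (2, "q", "R1", "Renal Cancer", -8.5, False, "none"),
        (2, "q", "R2", "Renal Cancer", -6.0, False, "none"),
    ]
    prof = cumulative_response(_meas(rows))
    assert prof.loc[1, "Renal Cancer"] == pytest.approx(100.0)
    assert prof.loc[2, "Renal Cancer"] == pytest.approx(50.0)
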