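"""Site grouping, normalization, differential testing, BH, and collapse."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosphokin.quant import (
    bh_adjust,
    build_site_groups,
    collapse_site_fc,
    differential_test,
    equal_median_normalize,
    parse_sites,
    select_changed_proteins,
    to_matrix,
)


def brute_force_bh(p):
    """Step-up by definition: q_i = min_{j>=i} p_(j) * m / j, input order."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestParseSites:
    def test_parses_and_sorts_structure(self):
        assert parse_sites("S15;T20") == ((15, "S"), (20, "T"))

    @pytest.mark.parametrize("bad", ["", "X15", "S0", "T20;S15", "S15;S15", "S15,T20"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(ValueError):
            parse_sites(bad)


class TestBuildSiteGroups:
    def test_same_site_set_sums_on_linear_scale(self, toy_measurements):
        grouped = build_site_groups(toy_measurements)
        row = grouped[
            (grouped["site_key"] == "PROTA_S15") & (grouped["run"] == "US_1h_r1")
        ]
        assert len(row) == 1
        assert row["intensity"].iloc[0] == pytest.approx(np.log2(2**10.0 + 2**11.0))

    def test_site_sets_group_by_equality_not_overlap(self, toy_measurements):
        grouped = build_site_groups(toy_measurements)
        keys = set(grouped["site_key"])
        assert keys == {"PROTA_S15", "PROTA_S15_T20"}

    def test_total_linear_intensity_conserved_per_run(self, toy_measurements):
        grouped = build_site_groups(toy_measurements)
        for run in toy_measurements["run"].unique():
            before = np.exp2(
                toy_measurements.loc[toy_measurements["run"] == run, "intensity"]
            ).sum()
            after = np.exp2(grouped.loc[grouped["run"] == run, "intensity"]).sum()
            assert after == pytest.approx(before)

    def test_empty_table_yields_empty_table(self):
        assert build_site_groups(pd.DataFrame(columns=["site_positions"])).empty

    def test_position_beyond_protein_length_rejected(self, toy_measurements):
        with pytest.raises(ValueError, match="beyond length"):
            build_site_groups(toy_measurements, sequences={"PROTA": "MS" * 5})

    def test_linear_scale_input_supported(self, toy_measurements):
        linear = toy_measurements.assign(intensity=np.exp2(toy_measurements["intensity"]))
        pd.testing.assert_frame_equal(
            build_site_groups(linear, linear_scale=True),
            build_site_groups(toy_measurements),
        )


class TestEqualMedianNormalize:
    def _matrix(self, rng, offsets):
        base = rng.normal(20, 2, size=(40, len(offsets)))
        return pd.DataFrame(
            base + np.asarray(offsets),
            index=[f"s{i}" for i in range(40)],
            columns=[f"r{j}" for j in range(len(offsets))],
        )

    def test_equal_medians_are_a_fixed_point(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.0, 2.0, 4.0]})
        pd.testing.assert_frame_equal(equal_median_normalize(m), m)

    def test_injected_run_offsets_recovered_up_to_constant(self):
        rng = np.random.default_rng(0)
        col = rng.normal(20, 2, size=40)
        base = pd.DataFrame(
            {"r0": col, "r1": col, "r2": col}, index=[f"s{i}" for i in range(40)]
        )
        shifted = base + np.array([1.0, 0.0, -1.0])
        norm = equal_median_normalize(shifted)
        resid = (norm - base).to_numpy()
        assert np.allclose(resid, resid[0, 0])  # one common constant
        meds = norm.median(axis=0)
        assert np.allclose(meds, meds.iloc[0], atol=1e-9)

    def test_single_run_unchanged(self):
        m = pd.DataFrame({"a": [1.0, 5.0, 9.0]})
        pd.testing.assert_frame_equal(equal_median_normalize(m), m)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        m = self._matrix(rng, [2.0, -1.0, 0.5, 0.0])
        once = equal_median_normalize(m)
        pd.testing.assert_frame_equal(equal_median_normalize(once), once)

    def test_run_without_finite_values_rejected(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="no finite"):
            equal_median_normalize(m)


def _matrix_from(treated, control):
    runs = [f"fibrin_1h_r{i}" for i in range(1, len(treated) + 1)] + [
        f"US_1h_r{i}" for i in range(1, len(control) + 1)
    ]
    meta = pd.DataFrame(
        {
            "run": runs,
            "condition": ["fibrin"] * len(treated) + ["US"] * len(control),
            "timepoint": "1h",
            "replicate": list(range(1, len(treated) + 1)) + list(range(1, len(control) + 1)),
        }
    ).set_index("run")
    matrix = pd.DataFrame([treated + control], index=["P_S1"], columns=runs)
    return matrix, meta


class TestDifferentialTest:
    def test_identical_samples_give_zero_fc_unit_p(self):
        matrix, meta = _matrix_from([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        out = differential_test(matrix, meta, "fibrin", "1h")
        assert out["log2fc"].iloc[0] == 0.0
        assert out["p"].iloc[0] == 1.0

    def test_exact_mean_difference_is_the_fold_change(self):
        matrix, meta = _matrix_from([3.0, 3.0, 3.0], [1.0, 1.0, 1.0])
        out = differential_test(matrix, meta, "fibrin", "1h")
        assert out["log2fc"].iloc[0] == pytest.approx(2.0)
        assert out["p"].iloc[0] < 1e-6  # variance floor keeps p defined

    def test_one_sided_detection_gives_infinite_fc_undefined_p(self):
        matrix, meta = _matrix_from([3.0, 3.5, 3.2], [np.nan, np.nan, np.nan])
        out = differential_test(matrix, meta, "fibrin", "1h")
        assert np.isposinf(out["log2fc"].iloc[0])
        assert np.isnan(out["p"].iloc[0])

    def test_unknown_contrast_rejected(self):
        matrix, meta = _matrix_from([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="unknown contrast"):
            differential_test(matrix, meta, "iC3b", "1h")

    def test_welch_matches_scipy_on_random_data(self):
        from scipy import stats as ss

        rng = np.random.default_rng(3)
        t, c = rng.normal(0, 1, 4).tolist(), rng.normal(0.5, 2, 3).tolist()
        matrix, meta = _matrix_from(t, c)
        out = differential_test(matrix, meta, "fibrin", "1h")
        want = ss.ttest_ind(t, c, equal_var=False)
        assert out["p"].iloc[0] == pytest.approx(want.pvalue, rel=1e-9)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_hand_evaluated_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones_stay_ones(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_matches_brute_force_step_up(self, p):
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])


def _stats_row(site_key, cond, tp, fc, p, adj_p=0.5):
    return {
        "site_key": site_key,
        "condition": cond,
        "timepoint": tp,
        "log2fc": fc,
        "se": 0.1,
        "p": p,
        "adj_p": adj_p,
        "n_treated": 3,
        "n_control": 3,
    }


class TestCollapseSiteFc:
    def test_single_finite_record_is_itself(self):
        stats = pd.DataFrame([_stats_row("A_S15", "fibrin", "1h", 1.2, 0.01)])
        out = collapse_site_fc(stats)
        assert len(out) == 1
        assert out["fc"].iloc[0] == 1.2 and out["source_p"].iloc[0] == 0.01

    def test_lowest_p_wins_regardless_of_magnitude(self):
        stats = pd.DataFrame(
            [
                _stats_row("A_S15", "fibrin", "1h", 1.2, 0.01),
                _stats_row("A_S15_T20", "fibrin", "1h", -3.0, 0.5),
            ]
        )
        out = collapse_site_fc(stats)
        s15 = out[out["position"] == 15]
        assert s15["fc"].iloc[0] == 1.2

    def test_infinite_fold_changes_excluded_from_selection(self):
        stats = pd.DataFrame(
            [
                _stats_row("A_S15", "fibrin", "1h", np.inf, 0.001),
                _stats_row("A_S15_T20", "fibrin", "1h", 0.4, 0.2),
            ]
        )
        out = collapse_site_fc(stats)
        assert out[out["position"] == 15]["fc"].iloc[0] == 0.4

    def test_all_infinite_site_omitted(self):
        stats = pd.DataFrame([_stats_row("A_S15", "fibrin", "1h", np.inf, 0.001)])
        assert collapse_site_fc(stats).empty

    def test_output_pairs_are_a_subset_of_input_records(self, small_study):
        from phosphokin.quant import quantify

        site_stats, site_fc = quantify(small_study.measurements)
        pairs = set(zip(site_stats["log2fc"], site_stats["p"].fillna(-1.0)))
        assert all(
            pair in pairs
            for pair in zip(site_fc["fc"], site_fc["source_p"].fillna(-1.0))
        )


class TestSelectChangedProteins:
    def _stats(self):
        rows = [
            _stats_row("P1_S1", "fibrin", "1h", 1.0, 0.001, adj_p=0.04),
            _stats_row("P1_S1", "fibrin", "3h", 1.0, 0.1, adj_p=0.2),
            _stats_row("P2_S1", "fibrin", "1h", 1.0, 0.001, adj_p=0.01),
            _stats_row("P3_S1", "fibrin", "1h", 1.0, 0.5, adj_p=0.9),
            _stats_row("P4_S1", "fibrin", "1h", 1.0, 0.2, adj_p=0.6),
            _stats_row("P5_S1", "fibrin", "3h", 1.0, 0.3, adj_p=0.7),
        ]
        return pd.DataFrame(rows)

    def test_no_hits_gives_empty_set(self):
        stats = self._stats().assign(adj_p=0.9)
        assert select_changed_proteins(stats) == set()

    def test_significant_at_one_timepoint_suffices(self):
        assert "P1" in select_changed_proteins(self._stats())

    def test_toy_table_counts(self):
        assert select_changed_proteins(self._stats()) == {"P1", "P2"}


def test_matrix_round_trip_preserves_values(small_study):
    grouped = build_site_groups(small_study.measurements)
    matrix, meta = to_matrix(grouped)
    assert set(meta.columns) == {"condition", "timepoint", "replicate"}
    sample = grouped.iloc[0]
    assert matrix.loc[sample["site_key"], sample["run"]] == pytest.approx(
        sample["intensity"]
    )
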