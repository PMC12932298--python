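"""Cohort change metrics, ratio conventions, paired tests, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from tibiofem.contact import ContactAreaTable
from tibiofem.load_stats import (
    StatsConfig,
    change_metrics,
    cohort_report,
    ml_ratio,
    paired_t,
    paired_tests,
)
from tibiofem.phantom import cohort_specs, cohort_truth_areas, simulate_cohort_tables


def make_table(subject, areas_by_measure):
    """areas_by_measure: {(cond, itf, comp): value}; others filled with 100."""
    t = ContactAreaTable(subject)
    for cond in ("unloaded", "loaded"):
        for itf in ("cartilage_cartilage", "meniscofemoral", "meniscotibial"):
            for comp in ("medial", "lateral"):
                t.areas[(cond, itf, comp)] = areas_by_measure.get(
                    (cond, itf, comp), 100.0
                )
    return t


def cc_tables(pairs):
    """Subjects whose medial cc areas follow (unloaded, loaded) pairs."""
    out = []
    for i, (a0, a1) in enumerate(pairs):
        out.append(
            make_table(
                f"s{i}",
                {
                    ("unloaded", "cartilage_cartilage", "medial"): a0,
                    ("loaded", "cartilage_cartilage", "medial"): a1,
                    ("unloaded", "cartilage_cartilage", "lateral"): 0.0,
                    ("loaded", "cartilage_cartilage", "lateral"): 0.0,
                },
            )
        )
    return out


def get_row(df, itf, comp):
    return df[(df.interface == itf) & (df.compartment == comp)].iloc[0]


class TestChangeMetrics:
    def test_mean_of_per_subject_percentages(self):
        # (100 -> 110) and (200 -> 230): +20 mm^2 and +12.5% — the
        # per-subject convention; percentage-of-means would give 13.3%
        rep = change_metrics(cc_tables([(100, 110), (200, 230)]))
        row = get_row(rep.measures, "cartilage_cartilage", "medial")
        assert row["mean_change"] == pytest.approx(20.0)
        assert row["mean_pct_change"] == pytest.approx(12.5)
        assert row["mean_pct_change"] != pytest.approx(100 * 20 / 150, abs=0.1)

    def test_unchanged_cohort_zero(self):
        rep = change_metrics(cc_tables([(100, 100), (250, 250), (80, 80)]))
        row = get_row(rep.measures, "cartilage_cartilage", "medial")
        assert row["mean_change"] == 0.0
        assert row["sd_change"] == 0.0
        assert row["mean_pct_change"] == 0.0

    def test_zero_unloaded_subject_excluded_from_percentage(self, caplog):
        tables = cc_tables([(100, 110), (0.0, 10.0), (200, 220)])
        with caplog.at_level("WARNING"):
            rep = change_metrics(tables)
        row = get_row(rep.measures, "cartilage_cartilage", "medial")
        assert row["mean_pct_change"] == pytest.approx(10.0)  # 10% and 10%
        assert rep.excluded and "s1" in rep.excluded[0][2]

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            change_metrics(cc_tables([(1, 2)]))

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(c=st.floats(0.1, 50.0), seed=st.integers(0, 100))
    def test_scale_equivariance(self, c, seed):
        rng = np.random.default_rng(seed)
        pairs = [(rng.uniform(50, 300), rng.uniform(50, 300)) for _ in range(5)]
        base = change_metrics(cc_tables(pairs)).measures
        scaled = change_metrics(
            cc_tables([(a * c, b * c) for a, b in pairs])
        ).measures
        r0 = get_row(base, "cartilage_cartilage", "medial")
        r1 = get_row(scaled, "cartilage_cartilage", "medial")
        assert r1["mean_pct_change"] == pytest.approx(r0["mean_pct_change"], rel=1e-9)
        assert r1["mean_change"] == pytest.approx(c * r0["mean_change"], rel=1e-9)


class TestMLRatio:
    def _tables(self, med_lat_pairs):
        return [
            make_table(
                f"s{i}",
                {
                    ("unloaded", "cartilage_cartilage", "medial"): m,
                    ("unloaded", "cartilage_cartilage", "lateral"): l,
                },
            )
            for i, (m, l) in enumerate(med_lat_pairs)
        ]

    def _get(self, df, itf, cond):
        return df[(df.interface == itf) & (df.condition == cond)].iloc[0]

    def test_equal_compartments_ratio_one(self):
        df = ml_ratio(self._tables([(100, 100), (80, 80)]))
        row = self._get(df, "cartilage_cartilage", "unloaded")
        assert row["mean_ratio"] == pytest.approx(1.0)
        assert row["sd_ratio"] == pytest.approx(0.0)

    def test_ratio_mean_and_sd(self):
        df = ml_ratio(self._tables([(150, 100), (170, 100)]))
        row = self._get(df, "cartilage_cartilage", "unloaded")
        assert row["mean_ratio"] == pytest.approx(1.6)
        assert row["sd_ratio"] == pytest.approx(0.1414, abs=1e-3)

    def test_per_subject_convention_not_ratio_of_means(self):
        df = ml_ratio(self._tables([(300, 100), (150, 150)]))
        row = self._get(df, "cartilage_cartilage", "unloaded")
        assert row["mean_ratio"] == pytest.approx(2.0)  # (3.0 + 1.0)/2

    def test_zero_lateral_excluded(self, caplog):
        with caplog.at_level("WARNING"):
            df = ml_ratio(self._tables([(300, 100), (50, 0.0)]))
        row = self._get(df, "cartilage_cartilage", "unloaded")
        assert row["n"] == 1
        assert row["mean_ratio"] == pytest.approx(3.0)


class TestPairedTests:
    def test_closed_form_matches_scipy(self):
        d = np.array([4.1, -1.2, 3.3, 0.7, 5.9, -0.4, 2.2, 1.8, 3.0])
        res = paired_t(d)
        t_ref, p_ref = sps.ttest_rel(d, np.zeros(9))
        assert res["t"] == pytest.approx(float(t_ref), abs=1e-6)
        assert res["p"] == pytest.approx(float(p_ref), abs=1e-6)
        # explicit textbook formula
        assert res["t"] == pytest.approx(
            d.mean() / (d.std(ddof=1) / np.sqrt(9)), abs=1e-12
        )

    def test_identical_pairs_degenerate_no_fabricated_p(self):
        res = paired_t(np.zeros(6))
        assert res["degenerate"]
        assert np.isnan(res["t"]) and np.isnan(res["p"])

    def test_antisymmetric_differences_t_zero_p_one(self):
        res = paired_t(np.array([-2.0, 2.0, -1.0, 1.0]))
        assert res["t"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0, abs=1e-12)

    def test_paired_tests_table_flags(self):
        tables = cc_tables([(100, 130), (110, 135), (90, 125), (105, 140)])
        df = paired_tests(tables)
        row = df[(df.test == "load_change") & (df.interface == "cartilage_cartilage")
                 & (df.compartment == "medial")].iloc[0]
        assert row["significant"]
        assert row["p"] < 0.01
        assert 0 < row["shapiro_W"] <= 1

    def test_needs_three_subjects(self):
        with pytest.raises(ValueError, match="3 subjects"):
            paired_tests(cc_tables([(1, 2), (3, 4)]))


class TestSimulatedCohorts:
    def test_recovered_effect_within_two_se(self):
        specs = cohort_specs(9, seed=21)
        truth = cohort_truth_areas(specs, with_load_effect=True, resolution=0.6)
        tables = simulate_cohort_tables(9, seed=21, truth=truth, measurement_cv=0.05)
        rep = change_metrics(tables)
        row = get_row(rep.measures, "cartilage_cartilage", "medial")
        true_changes = [
            t["loaded"][("cartilage_cartilage", "medial")]
            - t["unloaded"][("cartilage_cartilage", "medial")]
            for t in truth
        ]
        se = row["sd_change"] / np.sqrt(9)
        assert abs(row["mean_change"] - np.mean(true_changes)) < 2 * se + 1e-9

    def test_null_cohort_type_one_error_near_alpha(self):
        specs = cohort_specs(9, seed=5)
        truth = cohort_truth_areas(specs, with_load_effect=False, resolution=0.8)
        rejections = 0
        n_rep = 200
        for rep_i in range(n_rep):
            tables = simulate_cohort_tables(
                9, seed=1000 + rep_i, truth=truth, measurement_cv=0.05
            )
            a0 = np.array([t.total("unloaded", "cartilage_cartilage") for t in tables])
            a1 = np.array([t.total("loaded", "cartilage_cartilage") for t in tables])
            if paired_t(a1 - a0)["p"] < 0.05:
                rejections += 1
        rate = rejections / n_rep
        assert 0.01 <= rate <= 0.10  # loose bound at 200 replicates


class TestReport:
    def test_cohort_report_formats(self):
        tables = cc_tables([(100, 130), (110, 135), (90, 125), (105, 140)])
        rep = cohort_report(tables)
        assert rep.n_subjects == 4
        fmt = rep.formatted()
        assert "mm2" in fmt.iloc[0]["change"]
        assert len(rep.contrasts) > 0
        assert (rep.measures["sd_unloaded"] >= 0).all()
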