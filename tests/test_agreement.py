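"""Tests of CV/AVD/PD, ICC, pooled stats and the agreement tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scanagree import published
from scanagree.agreement import (
    ALL_SCANNERS,
    ALL_VOLUMES,
    aggregate_structure_means,
    avd,
    classify_icc,
    cv_percent,
    icc_absolute_single,
    percentual_difference,
    pooled_group_stats,
    summarize_agreement,
)
from scanagree.records import records_to_frame
from scanagree.synthetic import SimulationConfig, simulate_volume_table

positive_volumes = st.floats(min_value=0.5, max_value=2000.0, allow_nan=False)


class TestPairMetrics:
    @pytest.mark.parametrize(
        "values,expected",
        [((100.0, 100.0), 0.0), ((99.0, 101.0), np.sqrt(2.0)), ((1.0, 2.0, 3.0), 50.0)],
    )
    def test_cv_hand_values(self, values, expected):
        assert cv_percent(values) == pytest.approx(expected, abs=1e-12)

    def test_cv_errors(self):
        with pytest.raises(ValueError):
            cv_percent([5.0])
        with pytest.raises(ValueError):
            cv_percent([1.0, -3.0])

    def test_avd_hand_values_and_symmetry(self):
        assert avd(1139.0, 1136.0) == 3.0
        assert avd(42.0, 42.0) == 0.0
        assert avd(3.0, 8.0) == avd(8.0, 3.0)

    def test_percentual_difference_hand_value(self):
        assert percentual_difference(99.0, 101.0) == pytest.approx(2.0, abs=1e-12)
        assert percentual_difference(7.0, 7.0) == 0.0

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(a=positive_volumes, b=positive_volumes)
    def test_pd_is_sqrt2_times_cv(self, a, b):
        """The percentual difference of a pair is exactly sqrt(2) x its CV."""
        from hypothesis import assume

        if a == b:
            assert percentual_difference(a, b) == 0.0
        else:
            assume(abs(a - b) > 1e-6 * max(a, b))  # avoid cancellation at 1 ulp
            ratio = percentual_difference(a, b) / cv_percent([a, b])
            assert ratio == pytest.approx(np.sqrt(2.0), abs=1e-9)


def anova_oracle(matrix: np.ndarray):
    """Independent two-way ANOVA decomposition via explicit loops."""
    n, k = matrix.shape
    grand = matrix.mean()
    ss_rows = sum(k * (matrix[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (matrix[:, j].mean() - grand) ** 2 for j in range(k))
    ss_total = sum((matrix[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = (ss_total - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err + k / n * (ms_cols - ms_err))
    return icc, (ms_rows, ms_cols, ms_err)


class TestICC:
    def test_perfect_agreement_is_one(self):
        x = np.array([[10.0, 10.0], [20.0, 20.0], [30.0, 30.0]])
        res = icc_absolute_single(x)
        assert res.estimate == 1.0
        assert res.classification == "excellent"
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_matches_independent_anova_oracle(self, rng):
        for _ in range(50):
            n, k = int(rng.integers(3, 12)), int(rng.integers(2, 5))
            x = rng.normal(50, 10, (n, 1)) + rng.normal(0, 3, (n, k)) + rng.normal(0, 1, (1, k))
            res = icc_absolute_single(x)
            expected, ms = anova_oracle(x)
            assert res.estimate == pytest.approx(expected, abs=1e-10)
            assert res.mean_squares == pytest.approx(ms, abs=1e-8)

    def test_hand_computed_six_by_two(self):
        x = np.array([[1.0, 2.0], [3.0, 3.5], [5.0, 5.5], [7.0, 6.0], [9.0, 9.5], [11.0, 12.0]])
        expected, _ = anova_oracle(x)
        assert icc_absolute_single(x).estimate == pytest.approx(expected, abs=1e-10)

    def test_variance_ratio_simulation(self, rng):
        """SA^2 = 81, SW^2 = 1 gives ICC ~ 81/82 at n = 200 subjects."""
        n = 200
        x = rng.normal(100, 9, (n, 1)) + rng.normal(0, 1, (n, 2))
        res = icc_absolute_single(x)
        assert res.estimate == pytest.approx(81.0 / 82.0, abs=0.01)

    def test_equals_one_way_form_when_column_ms_matches_error_ms(self, rng):
        """With MS_cols == MS_err the two-way and one-way forms coincide."""
        n, k = 12, 2
        x = rng.normal(50, 8, (n, 1)) + rng.normal(0, 2, (n, k))
        x -= x.mean(axis=0, keepdims=True)  # zero column effects
        _, (_, _, ms_err) = anova_oracle(x)
        d = np.sqrt(ms_err / (2 * n))
        x += np.array([[+d, -d]])  # set SS_cols so that MS_cols == MS_err
        res = icc_absolute_single(x)
        assert res.estimate == pytest.approx(res.one_way_estimate, abs=1e-8)

    def test_matches_pingouin_reference(self, rng):
        """Estimate and 95% CI agree with pingouin's ICC(A,1) implementation."""
        pg = pytest.importorskip("pingouin")
        for _ in range(10):
            n, k = int(rng.integers(5, 12)), int(rng.integers(2, 4))
            x = rng.normal(50, 10, (n, 1)) + rng.normal(0, 2, (n, k)) + rng.normal(0, 1, (1, k))
            res = icc_absolute_single(x)
            df = pd.DataFrame(
                {
                    "targets": np.repeat(np.arange(n), k),
                    "raters": np.tile(np.arange(k), n),
                    "scores": x.ravel(),
                }
            )
            table = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="scores")
            row = table[table["Type"] == "ICC(A,1)"].iloc[0]
            assert res.estimate == pytest.approx(row["ICC"], abs=1e-10)
            # pingouin rounds its CI to two decimals
            assert res.ci_low == pytest.approx(row["CI95"][0], abs=0.006)
            assert res.ci_high == pytest.approx(row["CI95"][1], abs=0.006)

    def test_incomplete_matrix_rejected(self):
        x = np.array([[1.0, 2.0], [3.0, np.nan], [5.0, 6.0]])
        with pytest.raises(ValueError, match="incomplete|balanced"):
            icc_absolute_single(x)

    @pytest.mark.parametrize(
        "estimate,expected",
        [
            (0.40, "poor"),
            (0.50, "moderate"),
            (0.74, "moderate"),
            (0.75, "good"),
            (0.89, "good"),
            (0.90, "excellent"),
            (0.93, "excellent"),
        ],
    )
    def test_classification_bands(self, estimate, expected):
        assert classify_icc(estimate) == expected


class TestPooledGroupStats:
    def test_study_demographics(self):
        """Two groups of five pool to the published total 60.6 +/- 16.3."""
        mean, sd = pooled_group_stats([(5, 52.2, 17.6), (5, 69.0, 10.5)])
        assert round(mean, 1) == 60.6
        assert round(sd, 1) == 16.3

    def test_single_group_is_identity(self):
        mean, sd = pooled_group_stats([(8, 4.2, 1.1)])
        assert (mean, sd) == pytest.approx((4.2, 1.1))

    def test_two_identical_groups_shrink_sd(self):
        n, m, s = 7, 10.0, 2.0
        mean, sd = pooled_group_stats([(n, m, s), (n, m, s)])
        assert mean == m
        assert sd == pytest.approx(s * np.sqrt(2 * (n - 1) / (2 * n - 1)), abs=1e-12)

    def test_matches_concatenated_sample(self, rng):
        a = rng.normal(10, 3, size=40)
        b = rng.normal(14, 5, size=25)
        mean, sd = pooled_group_stats(
            [(40, a.mean(), a.std(ddof=1)), (25, b.mean(), b.std(ddof=1))]
        )
        combined = np.concatenate([a, b])
        assert mean == pytest.approx(combined.mean(), abs=1e-10)
        assert sd == pytest.approx(combined.std(ddof=1), abs=1e-10)


class TestSummarizeAgreement:
    def test_noise_free_table_is_perfect(self, noise_free_config):
        records = simulate_volume_table(noise_free_config)
        table = summarize_agreement(records, mode="intra")
        per_structure = table.data[table.data["structure"] != ALL_VOLUMES]
        assert (per_structure["cv_mean"] == 0).all()
        assert (per_structure["avd_mean"] == 0).all()
        assert (per_structure["pd_mean"] == 0).all()
        assert (per_structure["icc"] == 1.0).all()

    def test_single_structure_all_volumes_row_equals_structure_row(self):
        cfg = SimulationConfig(
            n_subjects=6,
            scanners=("a", "b"),
            structures=[("only", 50.0, 5.0)],
            scanner_bias={},
            residual_cv_percent=1.0,
            seed=2,
        )
        table = summarize_agreement(simulate_volume_table(cfg), mode="intra")
        a_rows = table.data[table.data["comparison"] == "a"]
        struct = a_rows[a_rows["structure"] == "only"].iloc[0]
        allv = a_rows[a_rows["structure"] == ALL_VOLUMES].iloc[0]
        assert allv["cv_mean"] == struct["cv_mean"]
        assert allv["icc"] == struct["icc"]

    def test_all_volumes_mean_is_unweighted_structure_mean(self, default_table):
        table = summarize_agreement(default_table, mode="intra")
        for comparison, group in table.data.groupby("comparison"):
            per_structure = group[group["structure"] != ALL_VOLUMES]["cv_mean"]
            allv = group[group["structure"] == ALL_VOLUMES]["cv_mean"].iloc[0]
            assert allv == pytest.approx(per_structure.mean(), abs=1e-12)

    def test_all_volumes_invariant_to_structure_order(self, default_table):
        df = records_to_frame(default_table)
        shuffled = df.sample(frac=1.0, random_state=0)
        t1 = summarize_agreement(df, mode="intra")
        t2 = summarize_agreement(shuffled, mode="intra")
        for comparison in df["scanner_id"].unique():
            v1 = t1.row(ALL_VOLUMES, comparison)["cv_mean"]
            v2 = t2.row(ALL_VOLUMES, comparison)["cv_mean"]
            assert v1 == pytest.approx(v2, abs=1e-12)

    def test_all_scanner_mode_drops_pairwise_metrics(self, default_table):
        table = summarize_agreement(default_table, mode="all_scanner")
        assert set(table.data["comparison"]) == {ALL_SCANNERS}
        per_structure = table.data[table.data["structure"] != ALL_VOLUMES]
        assert per_structure["avd_mean"].isna().all()
        assert per_structure["icc"].notna().all()

    def test_inter_mode_uses_scanner_means(self):
        """Inter-scanner CV vanishes when the two repetitions average identically."""
        records = []
        from scanagree.records import VolumeRecord

        for subj in ("s1", "s2", "s3"):
            base = {"s1": 100.0, "s2": 110.0, "s3": 120.0}[subj]
            for scanner in ("a", "b"):
                # repetitions differ, but their mean is scanner-independent
                delta = 2.0 if scanner == "a" else 4.0
                for rep, v in ((1, base - delta), (2, base + delta)):
                    records.append(VolumeRecord(subj, scanner, rep, "s", v))
        table = summarize_agreement(records, mode="inter")
        row = table.row("s", "a-b")
        assert row["cv_mean"] == pytest.approx(0.0, abs=1e-12)
        intra = summarize_agreement(records, mode="intra")
        assert intra.row("s", "a")["cv_mean"] > 0

    def test_incomplete_design_rejected(self, default_table):
        df = records_to_frame(default_table).iloc[:-1]
        with pytest.raises(ValueError, match="missing"):
            summarize_agreement(df, mode="intra")

    def test_published_aggregation_convention(self):
        """Unweighted means of the published per-structure CVs give the
        printed all-volumes rows."""
        mean, sd = aggregate_structure_means(published.INTRA_CV_MEAN["achieva"].values())
        assert round(mean, 2) == 1.05
        assert round(sd, 2) == 0.87
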