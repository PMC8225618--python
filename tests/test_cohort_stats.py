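import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from arvquant.cohort_stats import (
    ContingencyTable,
    PatientRecord,
    StatsError,
    call_positive,
    compare_epcam_fractions,
    fisher_exact_two_tailed,
    fisher_from_counts,
    heatmap_matrix,
    load_cohort_csv,
    log2_transform,
    mann_whitney,
    read_heatmap_matrix,
    records_to_frame,
    summarize_cohort,
    write_heatmap_matrix,
)
from arvquant.synthetic_data import synthetic_epcam_fraction_cohort
from helpers import fisher_two_tailed_oracle, mann_whitney_exact_oracle


def rec(subject_id, **copies):
    return PatientRecord(subject_id=subject_id, copies=copies)


class TestPositivityAndSummary:
    def test_call_positive_rules(self):
        r = PatientRecord("s", copies={"AR-V7": 8.5, "AR-FL": 0.0})
        assert call_positive(r, "AR-V7", 0)
        assert not call_positive(r, "AR-FL", 0)
        assert not call_positive(r, "AR-v567es", 0)  # missing -> not detected

    def test_threshold_is_strict(self):
        r = PatientRecord("s", copies={"AR-V7": 2.0})
        assert not call_positive(r, "AR-V7", 2.0)
        assert call_positive(r, "AR-V7", 1.9)

    def test_prevalence_rounding(self):
        records = [
            rec(f"s{i}", **{"AR-V7": 1.0 if i < 19 else 0.0}) for i in range(29)
        ]
        s = summarize_cohort(records, transcripts=["AR-V7"]).per_transcript["AR-V7"]
        assert (s.n_positive, s.n_total, s.prevalence_percent) == (19, 29, 66)

    def test_summary_includes_zeros(self):
        records = [rec(f"s{i}", **{"AR-V7": v}) for i, v in enumerate([0, 1, 2, 3])]
        s = summarize_cohort(records, transcripts=["AR-V7"]).per_transcript["AR-V7"]
        assert s.median == 1.5 and s.mean == 1.5 and s.range == (0.0, 3.0)

    def test_all_zero_cohort(self):
        records = [rec(f"s{i}", **{"AR-V7": 0.0}) for i in range(5)]
        s = summarize_cohort(records, transcripts=["AR-V7"]).per_transcript["AR-V7"]
        assert s.prevalence_percent == 0 and s.median == 0 and s.mean == 0

    def test_empty_cohort_rejected(self):
        with pytest.raises(StatsError):
            summarize_cohort([])


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((5, 5, 5, 5), 1.0),
            ((2, 8, 8, 2), 0.02301),  # enumeration over N=20, K=10, n=10
        ],
    )
    def test_known_values(self, table, expected):
        assert fisher_exact_two_tailed(ContingencyTable(*table)) == pytest.approx(
            expected, abs=5e-6
        )

    def test_matches_bruteforce_oracle_systematically(self):
        for a in range(6):
            for b in range(6):
                for c in range(6):
                    for d in range(6):
                        if a + b + c + d == 0:
                            continue
                        got = fisher_exact_two_tailed(ContingencyTable(a, b, c, d))
                        want = fisher_two_tailed_oracle(a, b, c, d)
                        assert got == pytest.approx(want, rel=1e-12, abs=1e-15)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        a=st.integers(0, 30), b=st.integers(0, 30),
        c=st.integers(0, 30), d=st.integers(0, 30),
    )
    def test_matches_scipy_and_oracle_random(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        got = fisher_exact_two_tailed(ContingencyTable(a, b, c, d))
        assert got == pytest.approx(fisher_two_tailed_oracle(a, b, c, d), rel=1e-10)
        _, p_scipy = scipy.stats.fisher_exact([[a, b], [c, d]])
        assert got == pytest.approx(p_scipy, rel=1e-9, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        a=st.integers(0, 15), b=st.integers(0, 15),
        c=st.integers(0, 15), d=st.integers(0, 15),
    )
    def test_point_probabilities_normalize(self, a, b, c, d):
        """Hypergeometric point probabilities over the full support sum to 1."""
        if a + b + c + d == 0:
            return
        from math import comb

        r1, r2, c1 = a + b, c + d, a + c
        n = r1 + r2
        lo, hi = max(0, c1 - r2), min(r1, c1)
        total = sum(comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1))
        assert total == comb(n, c1)

    def test_negative_count_rejected(self):
        with pytest.raises(StatsError):
            ContingencyTable(-1, 2, 3, 4)

    def test_from_counts_wrapper(self):
        tbl, p = fisher_from_counts(6, 53, 10, 17)
        assert (tbl.a, tbl.b, tbl.c, tbl.d) == (6, 47, 10, 7)
        assert 0 < p < 1


class TestMannWhitney:
    def test_fully_separated_small(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0 and p == pytest.approx(0.1)

    def test_identical_samples(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        nx=st.integers(2, 5), ny=st.integers(2, 5), data=st.data()
    )
    def test_exact_branch_matches_permutation_oracle(self, nx, ny, data):
        vals = st.integers(0, 6)  # small range forces ties
        x = data.draw(st.lists(vals, min_size=nx, max_size=nx))
        y = data.draw(st.lists(vals, min_size=ny, max_size=ny))
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(mann_whitney_exact_oracle(x, y), abs=1e-12)

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 50)
        y = rng.normal(2, 1, 50)  # 2-sigma shift
        _, p = mann_whitney(x, y)
        assert p < 1e-4

    def test_approximate_branch_tracks_scipy(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.5, 1, 25)
        u, p = mann_whitney(x, y)
        res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(res.statistic)
        assert p == pytest.approx(res.pvalue, rel=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(StatsError):
            mann_whitney([], [1.0])


class TestLog2Transform:
    @pytest.mark.parametrize("raw,expected", [(0, 0.0), (7, 3.0), (1023, 10.0)])
    def test_values(self, raw, expected):
        assert log2_transform([raw])[0] == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(StatsError):
            log2_transform([-1])


class TestEpcamComparison:
    def test_published_positivity_pattern(self):
        """The matched-fraction cohort reproduces the reported prevalences:
        AR-V7 60% vs 90%, AR-v567es 20% vs 60%, AR-FL 80% vs 100%."""
        df = compare_epcam_fractions(synthetic_epcam_fraction_cohort()).set_index(
            "transcript_id"
        )
        assert df.loc["AR-V7", "epcam_pos_prevalence_percent"] == 60
        assert df.loc["AR-V7", "epcam_neg_prevalence_percent"] == 90
        assert df.loc["AR-v567es", "epcam_pos_prevalence_percent"] == 20
        assert df.loc["AR-v567es", "epcam_neg_prevalence_percent"] == 60
        assert df.loc["AR-FL", "epcam_pos_prevalence_percent"] == 80
        assert df.loc["AR-FL", "epcam_neg_prevalence_percent"] == 100
        assert (df["fisher_p"] > 0).all() and (df["fisher_p"] <= 1).all()

    def test_identical_fractions_give_p_one(self):
        records = []
        for status in ("pos", "neg"):
            for i in range(6):
                records.append(
                    PatientRecord(
                        f"x{i}", epcam_status=status,
                        copies={"AR-V7": 1.0 if i < 3 else 0.0},
                    )
                )
        df = compare_epcam_fractions(records, transcripts=["AR-V7"])
        row = df.iloc[0]
        assert row["epcam_pos_prevalence_percent"] == row["epcam_neg_prevalence_percent"]
        assert row["fisher_p"] == pytest.approx(1.0)

    def test_missing_fraction_rejected(self):
        records = [PatientRecord("a", epcam_status="pos", copies={"AR-V7": 1.0})]
        with pytest.raises(StatsError):
            compare_epcam_fractions(records)


class TestHeatmapMatrix:
    def test_shape_and_order(self):
        records = [rec("s2", **{"AR-FL": 1.0}), rec("s1", **{"AR-FL": 2.0})]
        m = heatmap_matrix(records)
        assert m.shape == (2, 3)
        assert list(m.index) == ["s1", "s2"]

    def test_missing_value_distinct_from_zero(self, tmp_path):
        records = [
            PatientRecord("s1", copies={"AR-FL": 0.0, "AR-V7": 3.0}),  # AR-v567es unmeasured
        ]
        m = heatmap_matrix(records)
        assert m.loc["s1", "AR-FL"] == 0.0
        assert math.isnan(m.loc["s1", "AR-v567es"])
        path = tmp_path / "m.tsv"
        write_heatmap_matrix(m, path)
        assert "ND" in path.read_text()
        back = read_heatmap_matrix(path)
        assert back.loc["s1", "AR-FL"] == 0.0
        assert math.isnan(back.loc["s1", "AR-v567es"])

    def test_round_trip_exact(self, tmp_path):
        records = [rec(f"s{i}", **{"AR-FL": i * 1.25, "AR-V7": i}) for i in range(4)]
        m = heatmap_matrix(records)
        path = tmp_path / "m.tsv"
        write_heatmap_matrix(m, path)
        back = read_heatmap_matrix(path)
        assert np.array_equal(m.to_numpy(), back.to_numpy(), equal_nan=True)


class TestCohortIO:
    def test_long_table_round_trip(self, tmp_path):
        records = [
            PatientRecord("p1", epcam_status="pos", copies={"AR-FL": 5.0, "AR-V7": 0.0}),
            PatientRecord("p2", epcam_status="neg", copies={"AR-FL": 1.0}),
        ]
        path = tmp_path / "cohort.csv"
        records_to_frame(records).to_csv(path, index=False)
        loaded = load_cohort_csv(path)
        assert {r.subject_id for r in loaded} == {"p1", "p2"}
        by_id = {r.subject_id: r for r in loaded}
        assert by_id["p1"].copies == {"AR-FL": 5.0, "AR-V7": 0.0}
        assert by_id["p1"].epcam_status == "pos"
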