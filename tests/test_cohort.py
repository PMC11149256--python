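import itertools

import numpy as np
import pytest
from scipy import stats

from oracles import exact_ranksum_moments, exact_ranksum_pvalue
from tau3d import cohort_report, load_table1, rank_sum_test, region_medians


@pytest.fixture(scope="module")
def table():
    return load_table1()


class TestLoadTable1:
    def test_row_and_group_counts(self, table):
        assert len(table) == 60
        counts = table.diagnosis.value_counts()
        assert counts["AD"] == 37 and counts["Control"] == 23

    def test_first_row(self, table):
        row = table.loc[table.id == 1].iloc[0]
        assert row.diagnosis == "AD"
        assert (row.frontal, row.occipital, row.parietal, row.temporal) == (67.4, 31.8, 59.7, 36.6)

    def test_row_45(self, table):
        row = table.loc[table.id == 45].iloc[0]
        assert row.diagnosis == "Control" and row.frontal == 86.7

    def test_all_values_positive(self, table):
        assert (table[["frontal", "occipital", "parietal", "temporal"]] > 0).all().all()


class TestRankSumTest:
    def test_identical_groups(self):
        res = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert res.z == 0.0 and res.p == 1.0

    def test_published_frontal_and_temporal_z(self, table):
        """Frozen values computed from the bundled table; cross-checked against
        scipy's Mann-Whitney asymptotic p below."""
        ad = table.loc[table.diagnosis == "AD"]
        co = table.loc[table.diagnosis == "Control"]
        z_frontal = rank_sum_test(ad.frontal, co.frontal).z
        z_temporal = rank_sum_test(ad.temporal, co.temporal).z
        assert z_frontal == pytest.approx(2.2198, abs=5e-4)
        assert z_temporal == pytest.approx(2.9813, abs=5e-4)

    def test_agrees_with_scipy_mannwhitneyu(self, table):
        for col in ("frontal", "occipital", "parietal", "temporal"):
            ad = table.loc[table.diagnosis == "AD", col]
            co = table.loc[table.diagnosis == "Control", col]
            res = rank_sum_test(ad, co)
            ref = stats.mannwhitneyu(co, ad, alternative="two-sided",
                                     method="asymptotic", use_continuity=False)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_small_sample_matches_exact_enumeration(self):
        mean, var = exact_ranksum_moments([1, 2, 3, 4], n_b=2)
        res = rank_sum_test([1, 2], [3, 4])
        u_b = 4.0  # both of {3,4} beat both of {1,2}
        assert res.z == pytest.approx((u_b - mean) / np.sqrt(var), abs=1e-9)

    def test_standardization_matches_enumeration_for_all_small_splits(self, rng):
        """For every split size with n1+n2 <= 8, the normal-approximation z must
        equal the exactly enumerated standardized U (ties included)."""
        data = rng.integers(0, 5, size=8).astype(float)  # small range forces ties
        for n_total in (4, 6, 8):
            pooled = data[:n_total]
            for n_b in range(1, n_total):
                a, b = pooled[:-n_b], pooled[-n_b:]
                mean, var = exact_ranksum_moments(pooled, n_b=n_b)
                if var == 0:
                    continue
                r = stats.rankdata(pooled)
                u_b = r[-n_b:].sum() - n_b * (n_b + 1) / 2
                assert rank_sum_test(a, b).z == pytest.approx(
                    (u_b - mean) / np.sqrt(var), abs=1e-9)

    def test_ordering_consistent_with_exact_p(self, rng):
        """Within a fixed group-size configuration, larger |z| must correspond
        to smaller exact two-sided p (the orderings agree; across different
        configurations the discreteness of the exact null differs)."""
        for n, k in [(6, 3), (7, 2), (8, 4)]:
            cases = []
            for _ in range(8):
                vals = rng.normal(size=n)
                a, b = vals[:k], vals[k:]
                cases.append((abs(rank_sum_test(a, b).z), exact_ranksum_pvalue(a, b)))
            for (z1, p1), (z2, p2) in itertools.combinations(cases, 2):
                if z2 > z1 + 1e-9:
                    assert p2 <= p1 + 1e-9

    def test_antisymmetry(self, rng):
        a = rng.normal(size=9)
        b = rng.normal(loc=0.7, size=6)
        fwd = rank_sum_test(a, b)
        rev = rank_sum_test(b, a)
        assert fwd.z == pytest.approx(-rev.z, abs=1e-12)
        assert fwd.p == pytest.approx(rev.p, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(size=7)
        base = rank_sum_test(a, b)
        warped = rank_sum_test(np.exp(a), np.exp(b))
        assert warped.z == pytest.approx(base.z, abs=1e-12)

    def test_constant_shift_invariance(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(size=5)
        base = rank_sum_test(a, b)
        shifted = rank_sum_test(a + 42.0, b + 42.0)
        assert shifted.z == pytest.approx(base.z, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1, 2])


class TestRegionMedians:
    def test_frontal_rounded_medians(self, table):
        ms = region_medians(table, "frontal")
        assert ms.rounded_medians == (68, 71)

    def test_temporal_rounded_medians(self, table):
        ms = region_medians(table, "temporal")
        assert ms.rounded_medians == (39, 43)

    def test_sample_std_convention(self, table):
        ms = region_medians(table, "frontal")
        ad = table.loc[table.diagnosis == "AD", "frontal"]
        assert ms.std_a == pytest.approx(np.std(ad, ddof=1))

    def test_unknown_region(self, table):
        with pytest.raises(KeyError):
            region_medians(table, "cerebellum")


class TestCohortReport:
    def test_all_four_lobes_significant(self, table):
        report = cohort_report(table)
        assert list(report.region) == ["frontal", "occipital", "parietal", "temporal"]
        assert (report.z.abs() > 2).all()
        assert (report.p < 0.05).all()
        assert (report.z > 0).all()  # control subjects rank higher everywhere

    def test_balanced_shuffle_shrinks_z(self, table):
        rng = np.random.default_rng(7)
        mags = []
        for _ in range(20):
            shuffled = table.copy()
            shuffled["diagnosis"] = rng.permutation(table.diagnosis.to_numpy())
            mags.append(cohort_report(shuffled).z.abs().mean())
        assert np.mean(mags) < cohort_report(table).z.abs().mean() / 2

    def test_single_group_rejected(self, table):
        controls = table[table.diagnosis == "Control"]
        with pytest.raises(ValueError):
            cohort_report(controls)
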