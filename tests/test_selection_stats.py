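import numpy as np
import pandas as pd
import pytest
from scipy import stats

from g4scan.selection_stats import (cadd_bin_trend, compare_maf,
                                    constraint_matched_sample,
                                    delta_by_subtype_test, filter_call_rate,
                                    length_stratify, pathogenicity_contrast,
                                    rare_fraction, subtype_distribution_shift)


class TestCallRateFilter:
    def test_boundary_inclusive(self):
        rows = pd.DataFrame({"an": [121850, 121849, 152312, 0]})
        kept = filter_call_rate(rows)
        assert list(kept["an"]) == [121850, 152312]

    def test_zero_fraction_keeps_all(self):
        rows = pd.DataFrame({"an": [0, 5]})
        assert len(filter_call_rate(rows, frac=0.0)) == 2


class TestConstraintMatching:
    def test_quartile_occupancy_preserved_exactly(self):
        rng = np.random.default_rng(0)
        a = pd.DataFrame({"constraint_z": rng.normal(0, 1, 200)})
        b = pd.DataFrame({"constraint_z": rng.normal(0.3, 1.4, 3000)})
        matched = constraint_matched_sample(a, b, seed=1)
        edges = np.quantile(a["constraint_z"], [0.25, 0.5, 0.75])
        occ_a = np.bincount(np.searchsorted(edges, a["constraint_z"],
                                            side="left"), minlength=4)
        occ_m = np.bincount(np.searchsorted(edges, matched["constraint_z"],
                                            side="left"), minlength=4)
        assert np.array_equal(occ_a, occ_m)
        assert len(matched) == len(a)

    def test_concentrated_group_samples_from_one_bin(self):
        a = pd.DataFrame({"constraint_z": np.full(10, -5.0)})
        b = pd.DataFrame({"constraint_z": np.r_[np.full(50, -5.0),
                                                np.full(50, 5.0)]})
        matched = constraint_matched_sample(a, b, seed=2)
        assert (matched["constraint_z"] == -5.0).all()

    def test_empty_bin_in_b_raises(self):
        a = pd.DataFrame({"constraint_z": [-2.0, -1.0, 1.0, 2.0]})
        b = pd.DataFrame({"constraint_z": [-2.0, -1.5]})
        with pytest.raises(ValueError, match="bin"):
            constraint_matched_sample(a, b, seed=3)

    def test_sampling_without_replacement(self):
        a = pd.DataFrame({"constraint_z": np.linspace(-1, 1, 40)})
        b = pd.DataFrame({"constraint_z": np.linspace(-1, 1, 40)})
        matched = constraint_matched_sample(a, b, seed=4)
        assert matched.index.is_unique


class TestCompareMaf:
    def test_identical_samples(self):
        x = np.array([0.1, 0.2, 0.3])
        res = compare_maf(x, x)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_complete_separation(self):
        res = compare_maf([0.001, 0.002, 0.003], [0.1, 0.2, 0.3])
        assert res.statistic == 1.0 and res.p <= 0.05 + 1e-12

    def test_simulated_selection_shift_detected(self):
        rng = np.random.default_rng(5)
        res = compare_maf(rng.beta(0.3, 30, 2000), rng.beta(0.5, 30, 2000))
        assert res.p < 0.05

    def test_mwu_alternative(self):
        rng = np.random.default_rng(6)
        res = compare_maf(rng.beta(0.3, 30, 500), rng.beta(0.5, 30, 500),
                          test="mwu")
        assert res.test == "mwu" and res.p < 0.05

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_maf([0.1], [0.1, 0.2])


class TestRareFraction:
    def test_counts_strictly_below_threshold(self):
        assert rare_fraction([0.0005, 0.002, 0.05]) == pytest.approx(1 / 3)
        assert rare_fraction([0.001, 0.002]) == 0.0  # boundary excluded
        assert rare_fraction([0.5, 0.9]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rare_fraction([])


class TestLengthStratify:
    def test_middle_lengths_excluded(self):
        rows = pd.DataFrame({"rg4_length": [20, 25, 30]})
        short, long_ = length_stratify(rows)
        assert list(short["rg4_length"]) == [20]
        assert list(long_["rg4_length"]) == [30]

    def test_raised_long_bound(self):
        rows = pd.DataFrame({"rg4_length": [20, 25, 30, 31]})
        _, long_ = length_stratify(rows, long_min=31)
        assert list(long_["rg4_length"]) == [31]

    def test_empty_input(self):
        short, long_ = length_stratify(pd.DataFrame({"rg4_length": []}))
        assert short.empty and long_.empty


class TestCaddTrend:
    def test_constant_delta(self):
        rows = pd.DataFrame({"cadd_raw": np.linspace(0, 10, 50),
                             "delta": np.full(50, -0.5)})
        table = cadd_bin_trend(rows, n_bins=5)
        assert (table["mean_delta"] == -0.5).all()
        assert (table["sd_delta"] == 0.0).all()

    def test_single_row_single_bin(self):
        table = cadd_bin_trend(pd.DataFrame({"cadd_raw": [2.0],
                                             "delta": [-0.3]}), n_bins=4)
        assert len(table) == 1 and table["n"].iloc[0] == 1

    def test_linear_relationship_gives_monotone_bins(self):
        cadd = np.linspace(0, 10, 200)
        rows = pd.DataFrame({"cadd_raw": cadd, "delta": -0.05 * cadd})
        means = cadd_bin_trend(rows, n_bins=5)["mean_delta"].to_numpy()
        assert (np.diff(means) < 0).all()


class TestSubtypeShift:
    def test_identical_distributions(self):
        counts = {"CANONICAL": 40, "LONGLOOP": 30}
        res = subtype_distribution_shift(counts, counts)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_disjoint_supports_extreme(self):
        res = subtype_distribution_shift({"x": 1000, "y": 0},
                                         {"x": 0, "y": 1000})
        assert res.p < 1e-10

    def test_single_category_rejected(self):
        with pytest.raises(ValueError):
            subtype_distribution_shift({"x": 10}, {"x": 20})

    def test_empty_categories_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            res = subtype_distribution_shift({"x": 10, "y": 5, "z": 0},
                                             {"x": 8, "y": 9, "z": 0})
        assert np.isfinite(res.p)


class TestDeltaBySubtype:
    def test_identical_means_give_null(self):
        groups = {"a": np.array([1., 2., 3.]), "b": np.array([2., 3., 1.]),
                  "c": np.array([3., 1., 2.])}
        res = delta_by_subtype_test(groups)
        assert res.omnibus_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.omnibus_p == pytest.approx(1.0)

    def test_shifted_group_flagged_in_pairwise(self):
        rng = np.random.default_rng(7)
        groups = {"a": rng.normal(0, 1, 200), "b": rng.normal(0, 1, 200),
                  "c": rng.normal(-1, 1, 200)}
        res = delta_by_subtype_test(groups)
        pw = res.pairwise.set_index(["group_a", "group_b"])
        assert pw.loc[("a", "c"), "p_adjusted"] < 0.01
        assert pw.loc[("b", "c"), "p_adjusted"] < 0.01
        assert pw.loc[("a", "b"), "p_adjusted"] > 0.05

    def test_dunn_mode_detects_shift(self):
        rng = np.random.default_rng(8)
        groups = {"a": rng.normal(0, 1, 100), "b": rng.normal(-1, 1, 100)}
        res = delta_by_subtype_test(groups, method="dunn")
        assert res.method == "kruskal+dunn-bh"
        assert res.pairwise["p_adjusted"].iloc[0] < 0.01

    def test_dunn_matches_kruskal_for_two_groups(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)
        res = delta_by_subtype_test({"a": a, "b": b}, method="dunn")
        # with two groups the Dunn z^2 equals the Kruskal-Wallis H statistic
        H, _ = stats.kruskal(a, b)
        assert res.pairwise["statistic"].iloc[0] ** 2 == pytest.approx(H)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            delta_by_subtype_test({"a": np.array([1., 2., 3.])})

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            delta_by_subtype_test({"a": np.array([1., 2., 3.]),
                                   "b": np.array([1., 2.])})


class TestPathogenicityContrast:
    def _table(self):
        df = pd.DataFrame({
            "clinsig": ["PATHOGENIC"] * 10 + ["BENIGN"] * 90,
            "delta": [0.0] * 100,
        })
        df.loc[:4, "delta"] = -0.6     # 5 pathogenic strongly disrupting
        df.loc[10:14, "delta"] = -0.6  # 5 benign strongly disrupting
        return df

    def test_fold_enrichment_ratio(self):
        res = pathogenicity_contrast(self._table())
        assert res.fold_enrichment == pytest.approx(5.0)

    def test_binomial_tail(self):
        res = pathogenicity_contrast(self._table())
        # P(X >= 5 | n=10, p=0.1) by direct tail enumeration
        expect = sum(stats.binom.pmf(k, 10, 0.1) for k in range(5, 11))
        assert res.binomial_p == pytest.approx(expect, rel=1e-9)
        assert res.binomial_p == pytest.approx(1.63e-3, abs=5e-5)

    def test_identical_distributions_mwu_near_half(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame({
            "clinsig": ["PATHOGENIC"] * 2000 + ["BENIGN"] * 2000,
            "delta": rng.normal(-0.2, 0.1, 4000),
        })
        res = pathogenicity_contrast(df, disrupt_thr=-10)
        assert 0.2 < res.mwu_p < 0.8
        assert res.fold_enrichment is None  # no disrupting rows

    def test_requires_both_classes(self):
        df = pd.DataFrame({"clinsig": ["BENIGN"] * 5, "delta": [0.0] * 5})
        with pytest.raises(ValueError):
            pathogenicity_contrast(df)
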