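"""Moderated t statistics, permutation FDR, overlaps and Mann-Whitney."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tpaquant.diffstats import (StatsError, log2_fold_change,
                                overlap_from_counts, overlap_from_sets,
                                overlap_summary, pairwise_mann_whitney,
                                permutation_fdr_test, quantified_fraction,
                                s0_t_statistic, star_label)
from tpaquant.quantify import Log2Matrix, tpa_concentrations
from tpaquant.synthdata import SimConfig, generate_dataset

from conftest import make_design, make_table


def _log2m(data: dict[str, list]) -> Log2Matrix:
    return Log2Matrix(values=pd.DataFrame(data))


class TestFoldChange:
    def test_identical_means_give_zero(self):
        log2m = _log2m({"A_b1_t1": [5.0], "A_b2_t1": [7.0],
                        "B_b1_t1": [6.0], "B_b2_t1": [6.0]})
        design = make_design({"A": 2, "B": 2})
        assert log2_fold_change(log2m, design, "A", "B").iloc[0] == 0.0

    def test_difference_of_group_means(self):
        log2m = _log2m({"A_b1_t1": [11.0], "A_b2_t1": [13.0],
                        "B_b1_t1": [9.0], "B_b2_t1": [11.0]})
        design = make_design({"A": 2, "B": 2})
        assert log2_fold_change(log2m, design, "A", "B").iloc[0] == 2.0

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(0)
        design = make_design({"A": 3, "B": 3})
        log2m = _log2m({r: rng.normal(20, 1, 10) for r in design.runs})
        ab = log2_fold_change(log2m, design, "A", "B")
        ba = log2_fold_change(log2m, design, "B", "A")
        np.testing.assert_allclose(ab.values, -ba.values, rtol=1e-12)

    def test_unknown_group_errors(self):
        design = make_design({"A": 2, "B": 2})
        log2m = _log2m({r: [1.0] for r in design.runs})
        with pytest.raises(KeyError, match="nope"):
            log2_fold_change(log2m, design, "A", "nope")


class TestS0Statistic:
    def test_s0_zero_reduces_to_classical_pooled_t(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(0, 1, 6)
            y = rng.normal(0.5, 2, 8)
            expected = stats.ttest_ind(x, y, equal_var=True).statistic
            assert s0_t_statistic(x, y, s0=0.0) == pytest.approx(expected,
                                                                 abs=1e-10)

    def test_equal_samples_give_zero(self):
        x = [1.0, 2.0, 3.0]
        for s0 in (0.0, 0.1, 5.0):
            assert s0_t_statistic(x, x, s0=s0) == 0.0

    def test_hand_computed_example(self):
        # x=(1,2,3), y shifted +3: mean diff -3, unit variances, pooled
        # sd 1, se sqrt(2/3); the s0 constant enters the denominator
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        expected = -3.0 / (np.sqrt(2.0 / 3.0) + 0.1)
        assert s0_t_statistic(x, y, s0=0.1) == pytest.approx(expected,
                                                             rel=1e-12)

    def test_welch_variant(self):
        x, y = [1.0, 2.0, 3.0, 8.0], [4.0, 5.0, 6.0]
        expected = stats.ttest_ind(x, y, equal_var=False).statistic
        assert s0_t_statistic(x, y, s0=0.0, variance="welch") == \
            pytest.approx(expected, abs=1e-10)

    def test_zero_variance_with_zero_s0_errors(self):
        with pytest.raises(StatsError):
            s0_t_statistic([1.0, 1.0], [2.0, 2.0], s0=0.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=1000))
    def test_magnitude_nonincreasing_in_s0(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 5)
        y = rng.normal(1, 1, 5)
        mags = [abs(s0_t_statistic(x, y, s0=s0))
                for s0 in (0.0, 0.05, 0.1, 0.5, 2.0)]
        assert all(a >= b - 1e-12 for a, b in zip(mags, mags[1:]))


def _toy_contrast_matrix(seed=0, n_null=30, n_shift=2, shift=5.0, n=3):
    """n-vs-n complete matrix with a few strongly shifted proteins."""
    rng = np.random.default_rng(seed)
    design = make_design({"A": n, "B": n})
    base = rng.normal(20, 0.3, size=(n_null + n_shift, 2 * n))
    base[:n_shift, :n] += shift
    return Log2Matrix(values=pd.DataFrame(
        base, columns=design.runs,
        index=[f"P{i}" for i in range(n_null + n_shift)])), design


class TestPermutationFDR:
    # With C(6,3) = 20 distinct label assignments (identity included), the
    # smallest estimable FDR on a 3-vs-3 toy is 2/20 = 0.1 exactly, which
    # sampling noise can straddle; toys therefore test at 0.15.
    def test_sampled_matches_exhaustive_on_3v3(self):
        log2m, design = _toy_contrast_matrix()
        exhaustive = permutation_fdr_test(log2m, design, "A", "B", seed=1,
                                          fdr=0.15)
        sampled = permutation_fdr_test(log2m, design, "A", "B", seed=1,
                                       fdr=0.15, exhaustive_limit=1,
                                       n_perm=2000)
        assert set(exhaustive.significant) == set(sampled.significant)
        assert set(exhaustive.significant) == {"P0", "P1"}

    def test_direction_labels_and_counts(self):
        log2m, design = _toy_contrast_matrix()
        res = permutation_fdr_test(log2m, design, "A", "B", seed=1, fdr=0.15)
        assert res.direction_set("up") == {"P0", "P1"}
        assert res.n_up + res.n_down == len(res.significant)
        sig = res.table["significant"]
        up = res.table["direction"] == "up"
        assert ((up & sig & (res.table["log2fc"] > 0)) == up).all()
        # antisymmetry under swapping the group order
        res_rev = permutation_fdr_test(log2m, design, "B", "A", seed=1,
                                       fdr=0.15)
        assert res_rev.direction_set("down") == res.direction_set("up")
        assert res_rev.direction_set("up") == res.direction_set("down")

    def test_seeded_determinism(self):
        log2m, design = _toy_contrast_matrix(n=6)  # forces sampling
        a = permutation_fdr_test(log2m, design, "A", "B", seed=4,
                                 exhaustive_limit=10, n_perm=100)
        b = permutation_fdr_test(log2m, design, "A", "B", seed=4,
                                 exhaustive_limit=10, n_perm=100)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_null_simulation_controls_fdr(self):
        fracs = []
        for seed in range(5):
            config = SimConfig(n_proteins=1000, seed=seed, mnar_slope=0.0,
                               frac_decoy=0, frac_contaminant=0,
                               frac_only_by_site=0)
            table, design, *_ = generate_dataset(config)
            log2m = Log2Matrix(values=np.log2(table.intensities))
            res = permutation_fdr_test(log2m, design, "chRCC", "NAT",
                                       fdr=0.01, s0=0.1, n_perm=250,
                                       seed=seed)
            fracs.append(len(res.significant) / 1000)
        assert np.median(fracs) <= 0.01

    def test_planted_effect_detected_with_direction(self):
        hits = 0
        for seed in range(10):
            config = SimConfig(n_proteins=100, seed=seed, mnar_slope=0.0,
                               sigma_bio=0.2, sigma_tech=0.2,
                               effect_table={"PW": {"chRCC": 5.0}},
                               pathway_sizes={"PW": 1},
                               frac_decoy=0, frac_contaminant=0,
                               frac_only_by_site=0)
            table, design, _, truth = generate_dataset(config)
            log2m = Log2Matrix(values=np.log2(table.intensities))
            res = permutation_fdr_test(log2m, design, "chRCC", "NAT",
                                       n_perm=100, seed=seed)
            (planted,) = truth.differential("chRCC", "NAT")
            hits += planted in res.direction_set("up")
        assert hits >= 9

    def test_missing_values_rejected(self):
        design = make_design({"A": 2, "B": 2})
        log2m = _log2m({r: [1.0] for r in design.runs})
        log2m.values.iloc[0, 0] = np.nan
        with pytest.raises(StatsError, match="missing"):
            permutation_fdr_test(log2m, design, "A", "B")

    def test_collapse_technical_averages_replicates(self):
        design = make_design({"A": 2, "B": 2}, n_tech=2)
        rng = np.random.default_rng(0)
        log2m = _log2m({r: rng.normal(20, 1, 40) for r in design.runs})
        res = permutation_fdr_test(log2m, design, "A", "B", seed=0,
                                   collapse_technical="mean")
        # collapsed fold change equals the run-level fold change here
        # (balanced design), so the table is still fully populated
        assert len(res.table) == 40


class TestOverlap:
    def test_printed_downregulated_counts(self):
        # 272 and 352 down with 241 shared: union 383 -> 63%
        out = overlap_from_counts(272, 352, 241)
        assert out["union"] == 383
        assert out["percent_of_union"] == 63

    def test_printed_upregulated_counts(self):
        # 260 and 226 up with 117 shared: union 369 -> 32%
        out = overlap_from_counts(260, 226, 117)
        assert out["union"] == 369
        assert out["percent_of_union"] == 32

    def test_disjoint_sets_zero_percent(self):
        out = overlap_from_sets({"a", "b"}, {"c"})
        assert out["intersection"] == 0
        assert out["percent_of_union"] == 0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.sets(st.integers(0, 50)), st.sets(st.integers(0, 50)))
    def test_inclusion_exclusion_identities(self, a, b):
        out = overlap_from_sets(a, b)
        assert out["union"] == out["n_a"] + out["n_b"] - out["intersection"]
        assert out["intersection"] <= min(out["n_a"], out["n_b"])

    def test_summary_from_contrast_results(self):
        log2m, design = _toy_contrast_matrix()
        res_a = permutation_fdr_test(log2m, design, "A", "B", seed=1, fdr=0.15)
        res_b = permutation_fdr_test(log2m, design, "A", "B", seed=2, fdr=0.15)
        summary = overlap_summary(res_a, res_b)
        assert set(summary.index) == {"up", "down"}
        assert summary.loc["up", "intersection"] == 2


def _conc(values_a, values_b, design):
    from tpaquant.quantify import ConcentrationMatrix
    data = dict(zip(design.runs_for("A"), values_a))
    data.update(zip(design.runs_for("B"), values_b))
    return ConcentrationMatrix(values=pd.DataFrame(
        {r: [data[r]] for r in design.runs}, index=["P0"]))


class TestMannWhitney:
    def test_identical_multisets_give_p_one(self):
        design = make_design({"A": 3, "B": 3})
        conc = _conc([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], design)
        out = pairwise_mann_whitney(conc, design, "P0")
        assert out["p_value"].iloc[0] == pytest.approx(1.0)
        assert out["stars"].iloc[0] == ""

    def test_fully_separated_small_groups(self):
        # (1,2,3) vs (4,5,6): U = 0, exact two-sided p = 2/C(6,3) = 0.1
        design = make_design({"A": 3, "B": 3})
        out = pairwise_mann_whitney(
            _conc([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], design), design, "P0")
        assert out["U"].iloc[0] == 0.0
        assert out["p_value"].iloc[0] == pytest.approx(0.1)
        assert out["stars"].iloc[0] == ""

    def test_star_thresholds(self):
        assert star_label(5e-4) == "**"
        assert star_label(5e-5) == "***"
        assert star_label(5e-6) == "****"
        assert star_label(2e-3) == ""
        assert star_label(1e-3) == "**"

    def test_insufficient_observations_skipped_with_warning(self):
        design = make_design({"A": 2, "B": 2})
        conc = _conc([1.0, np.nan], [2.0, 3.0], design)
        with pytest.warns(UserWarning, match="skipped"):
            out = pairwise_mann_whitney(conc, design, "P0")
        assert len(out) == 0


class TestQuantifiedFraction:
    def test_toy_counts(self):
        design = make_design({"A": 5}, n_tech=2)
        runs = design.runs
        data = {r: [] for r in runs}
        # 3 proteins present in 10, 7 and 6 runs -> 2 pass at 70%
        for counts in (10, 7, 6):
            for i, r in enumerate(runs):
                data[r].append(1.0 if i < counts else 0)
        table = make_table(data)
        n_q, n_total, pct = quantified_fraction(table, design)
        assert (n_q, n_total) == (2, 3)
        assert pct == pytest.approx(66.7)

    def test_all_and_none(self):
        design = make_design({"A": 2})
        full = make_table({r: [1.0, 2.0] for r in design.runs})
        assert quantified_fraction(full, design)[2] == 100.0
        empty = make_table({design.runs[0]: [1.0, 1.0],
                            design.runs[1]: [0, 0]})
        n_q, _, pct = quantified_fraction(empty, design, min_frac=1.0)
        assert (n_q, pct) == (0, 0.0)

    def test_printed_percentage_arithmetic(self):
        # 1379 of 1610 rounds to 85.7 at one decimal
        assert round(100 * 1379 / 1610, 1) == 85.7
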