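"""Differential statistics, standardization, clustering, MDS, shares, screening."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from meprod.errors import MeprodError
from meprod.stats import (
    CLASS_DOWN,
    CLASS_ND,
    CLASS_UNCHANGED,
    CLASS_UP,
    benjamini_hochberg,
    classify_regulation,
    fold_change_stats,
    hierarchical_cluster,
    mds_embed,
    pooled_t_test,
    ternary_shares,
    titration_linear_screen,
    zscore_standardize,
)


def bh_bruteforce(pvals):
    """Independent O(n^2) step-up: adj_(i) = min_{j>=i} p_(j) * n / j, capped at 1."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adj_sorted = [
        min(min(pvals[order[j]] * (n / (j + 1)) for j in range(i, n)), 1.0)
        for i in range(n)
    ]
    out = [0.0] * n
    for rank, idx in enumerate(order):
        out[idx] = adj_sorted[rank]
    return out


class TestBenjaminiHochberg:
    def test_textbook_example(self):
        assert list(benjamini_hochberg([0.01, 0.02, 0.03])) == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(derandomize=True, max_examples=300)
    def test_matches_bruteforce_exactly(self, pvals):
        assert list(benjamini_hochberg(pvals)) == bh_bruteforce(pvals)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(derandomize=True, max_examples=100)
    def test_adjusted_never_below_raw_and_monotone(self, pvals):
        adj = benjamini_hochberg(pvals)
        assert all(a >= p for a, p in zip(adj, pvals))
        order = np.argsort(pvals, kind="mergesort")
        assert all(np.diff(adj[order]) >= 0)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(42)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 20))
            ours = benjamini_hochberg(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(ours, theirs, rtol=1e-12)


class TestPooledTTest:
    def test_textbook_values(self):
        control = [1.0, 1.1, 0.9]
        treated = [2.0, 2.1, 1.9]
        t, p = pooled_t_test(treated, control)
        assert t == pytest.approx(12.2474487, rel=1e-6)  # 1 / (0.1 * sqrt(2/3))
        # cross-check against scipy's equal-variance implementation
        ref = sps.ttest_ind(treated, control, equal_var=True)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_identical_groups(self):
        t, p = pooled_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_zero_variance_distinct_means(self):
        t, p = pooled_t_test([2.0, 2.0], [1.0, 1.0])
        assert t == math.inf and p == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_swapping_groups_flips_sign_keeps_p(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 4), rng.normal(0.5, 1, 5)
        t1, p1 = pooled_t_test(a, b)
        t2, p2 = pooled_t_test(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


def protein_frame(rows):
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["127N", "127C", "128N", "128C"]
    )


class TestFoldChangeStats:
    # design6 columns: control = 127N/127C, treated = 128N/128C

    def test_identical_groups_give_null_stats(self, design6):
        table = protein_frame({"P1": [1.0, 2.0, 1.0, 2.0]})
        (s,) = fold_change_stats(table, design6, "treated", "control")
        assert s.log2fc == 0.0 and s.t_stat == 0.0 and s.p == 1.0

    def test_doubled_translation(self, design6):
        table = protein_frame({"P1": [1.0, 1.2, 2.0, 2.4]})
        (s,) = fold_change_stats(table, design6, "treated", "control")
        assert s.log2fc == pytest.approx(1.0)
        assert s.mean_treated == pytest.approx(2.2)

    def test_nd_rule_and_bh_family_exclusion(self, design6):
        table = protein_frame(
            {
                "P1": [1.0, 1.1, 0.0, 0.0],  # treated fully below baseline
                "P2": [1.0, 1.1, 2.0, 2.1],
                "P3": [1.0, 1.2, 0.4, 0.5],
            }
        )
        stats = fold_change_stats(table, design6, "treated", "control")
        by_acc = {s.master_accession: s for s in stats}
        assert by_acc["P1"].regulation_class == CLASS_ND
        assert math.isnan(by_acc["P1"].adj_p)
        # BH family has exactly the two testable proteins
        tested = [s for s in stats if s.regulation_class != CLASS_ND]
        expected = bh_bruteforce([s.p for s in tested])
        assert [s.adj_p for s in tested] == pytest.approx(expected)

    def test_missing_replicate_cells_excluded(self, design6):
        table = protein_frame({"P1": [1.0, np.nan, 2.0, 2.1],
                               "P2": [1.0, 1.1, 2.0, 2.1]})
        stats = fold_change_stats(table, design6, "treated", "control")
        assert [s.master_accession for s in stats] == ["P2"]

    def test_unknown_condition_rejected(self, design6):
        table = protein_frame({"P1": [1.0, 1.1, 2.0, 2.1]})
        with pytest.raises(MeprodError, match="missing"):
            fold_change_stats(table, design6, "treated", "missing")

    def test_single_replicate_condition_rejected(self):
        from meprod.design import ChannelSpec, PlexDesign

        design = PlexDesign(
            plex_id="uneven",
            channels=(
                ChannelSpec(channel_id="126", role="noise"),
                ChannelSpec(channel_id="127N", role="sample",
                            condition="control", replicate=1),
                ChannelSpec(channel_id="127C", role="sample",
                            condition="control", replicate=2),
                ChannelSpec(channel_id="128N", role="sample",
                            condition="treated", replicate=1),
                ChannelSpec(channel_id="129N", role="booster"),
            ),
        )
        table = pd.DataFrame({"127N": [1.0], "127C": [1.1], "128N": [2.0]},
                             index=["P1"])
        with pytest.raises(MeprodError, match="fewer than two replicate"):
            fold_change_stats(table, design, "treated", "control")


class TestClassifyRegulation:
    def _stat(self, log2fc, adj_p, nd=False):
        from meprod.stats import TranslationStat

        return TranslationStat(
            master_accession="P1",
            mean_control=1.0,
            mean_treated=0.0 if nd else 2.0,
            log2fc=math.nan if nd else log2fc,
            t_stat=0.0,
            p=adj_p,
            adj_p=adj_p,
            regulation_class=CLASS_ND if nd else CLASS_UNCHANGED,
        )

    @pytest.mark.parametrize(
        "log2fc, adj_p, expected",
        [
            (-0.6, 0.01, CLASS_DOWN),
            (-0.6, 0.2, CLASS_UNCHANGED),
            (-0.49, 0.001, CLASS_UNCHANGED),  # |fc| threshold is inclusive at 0.5
            (-0.5, 0.001, CLASS_DOWN),
            (0.7, 0.01, CLASS_UP),
            (0.7, 0.05, CLASS_UNCHANGED),  # p threshold is strict
        ],
    )
    def test_threshold_rules(self, log2fc, adj_p, expected):
        (out,) = classify_regulation([self._stat(log2fc, adj_p)])
        assert out.regulation_class == expected

    def test_nd_takes_precedence(self):
        (out,) = classify_regulation([self._stat(0, 0, nd=True)])
        assert out.regulation_class == CLASS_ND

    def test_classes_partition_inputs(self):
        stats = [self._stat(fc, p) for fc in (-1, 0, 1) for p in (0.01, 0.5)]
        stats.append(self._stat(0, 0, nd=True))
        out = classify_regulation(stats)
        assert len(out) == len(stats)
        assert {s.regulation_class for s in out} <= {
            CLASS_UP, CLASS_DOWN, CLASS_UNCHANGED, CLASS_ND
        }


class TestZscore:
    def test_simple_row(self):
        z = zscore_standardize(pd.DataFrame({"a": [1.0], "b": [2.0], "c": [3.0]}))
        assert list(z.values.iloc[0]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_row_zeroed_and_flagged(self):
        frame = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]], index=["c", "v"])
        z = zscore_standardize(frame)
        assert list(z.values.loc["c"]) == [0.0, 0.0, 0.0]
        assert z.constant_rows == ["c"]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(rng.normal(size=(5, 4)))
        once = zscore_standardize(frame).values
        twice = zscore_standardize(once).values
        pd.testing.assert_frame_equal(once, twice)

    def test_row_moments(self):
        rng = np.random.default_rng(1)
        z = zscore_standardize(pd.DataFrame(rng.normal(2, 3, size=(10, 6)))).values
        assert np.allclose(z.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-9)


class TestHierarchicalCluster:
    def test_two_columns_single_merge(self):
        frame = pd.DataFrame({"a": [0.0, 0.0], "b": [3.0, 4.0]})
        result = hierarchical_cluster(frame, on="columns")
        assert result.linkage.shape == (1, 4)
        assert result.linkage[0, 2] == pytest.approx(5.0)

    def test_near_pair_merges_before_far_column(self):
        # d(a,b)=1, d(a,c)=d(b,c)=10: exhaustively, (a,b) is the only first merge
        frame = pd.DataFrame({"a": [0.0], "b": [1.0], "c": [10.5]})
        result = hierarchical_cluster(frame, on="columns")
        first = sorted(result.linkage[0, :2].astype(int))
        assert [result.labels[i] for i in first] == ["a", "b"]

    def test_duplicated_column_merges_at_zero(self):
        frame = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0], "c": [9.0, 9.0]})
        result = hierarchical_cluster(frame, on="columns")
        assert result.linkage[0, 2] == 0.0
        first = sorted(result.linkage[0, :2].astype(int))
        assert [result.labels[i] for i in first] == ["a", "b"]

    def test_non_finite_cells_reported(self):
        frame = pd.DataFrame({"a": [1.0, np.nan], "b": [1.0, 2.0]})
        with pytest.raises(MeprodError, match="non-finite"):
            hierarchical_cluster(frame)


class TestMdsEmbed:
    def test_two_samples_symmetric_on_axis(self):
        frame = pd.DataFrame({"a": [0.0, 0.0], "b": [3.0, 4.0]})
        coords = mds_embed(frame)
        assert list(coords.columns) == ["dim1"]
        assert coords.loc["a", "dim1"] == pytest.approx(2.5)
        assert coords.loc["b", "dim1"] == pytest.approx(-2.5)

    def test_equilateral_distances_preserved(self):
        # three mutually equidistant samples embed exactly in the plane
        frame = pd.DataFrame(
            {"a": [1.0, 0.0, 0.0], "b": [0.0, 1.0, 0.0], "c": [0.0, 0.0, 1.0]}
        )
        coords = mds_embed(frame).to_numpy()
        d = math.sqrt(2.0)
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(
                    d, abs=1e-6
                )

    def test_planar_configuration_roundtrips(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(2, 6))  # rank-2 data: distances are 2-embeddable
        frame = pd.DataFrame(pts, columns=[f"s{i}" for i in range(6)])
        coords = mds_embed(frame).to_numpy()
        from scipy.spatial.distance import pdist

        original = pdist(pts.T)
        embedded = pdist(coords)
        np.testing.assert_allclose(embedded, original, atol=1e-6)

    def test_duplicated_sample_identical_coordinates(self):
        frame = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0], "c": [4.0, 0.0]})
        coords = mds_embed(frame)
        np.testing.assert_allclose(coords.loc["a"], coords.loc["b"], atol=1e-9)

    def test_degenerate_input_warns_and_zeroes(self):
        frame = pd.DataFrame({"a": [1.0, 1.0], "b": [1.0, 1.0], "c": [1.0, 1.0]})
        with pytest.warns(UserWarning, match="degenerate"):
            coords = mds_embed(frame)
        assert np.allclose(coords.to_numpy(), 0.0)


class TestTernaryShares:
    def test_symmetric_and_weighted_shares(self):
        table = pd.DataFrame(
            {"t1": [1.0, 2.0], "t2": [1.0, -1.0], "t3": [-1.0, 1.0]},
            index=["P1", "P2"],
        )
        shares = ternary_shares(table)
        assert list(shares.loc["P1"]) == pytest.approx([1 / 3, 1 / 3, 1 / 3])
        assert list(shares.loc["P2"]) == pytest.approx([0.5, 0.25, 0.25])
        assert shares.sum(axis=1).to_numpy() == pytest.approx([1.0, 1.0])

    def test_all_zero_protein_excluded(self):
        table = pd.DataFrame({"t1": [0.0, 1.0], "t2": [0.0, 1.0]}, index=["Z", "P"])
        shares = ternary_shares(table)
        assert list(shares.index) == ["P"]


def ols_oracle(x, y):
    """Textbook OLS: slope, intercept, r^2, and slope t-test p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    sxy = ((x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    ss_res, ss_tot = (resid**2).sum(), ((y - ybar) ** 2).sum()
    r2 = 1 - ss_res / ss_tot
    se = math.sqrt(ss_res / (n - 2) / sxx)
    t = slope / se
    p = 2 * sps.t.sf(abs(t), n - 2)
    return slope, intercept, r2, p


class TestTitrationLinearScreen:
    doses = [0.0, 1.0, 2.0, 4.0, 8.0]

    def test_exact_linear_decrease_selected(self):
        table = pd.DataFrame(
            {f"d{i}": [1.0 - 0.1 * d] for i, d in enumerate(self.doses)},
            index=["P1"],
        )
        (res,) = titration_linear_screen(table, self.doses)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(-0.1)
        assert res.is_linear_responder

    def test_constant_protein_not_selected(self):
        table = pd.DataFrame(
            {f"d{i}": [0.7] for i in range(len(self.doses))}, index=["P1"]
        )
        (res,) = titration_linear_screen(table, self.doses)
        assert res.slope == 0.0 and not res.is_linear_responder

    def test_noisy_fit_matches_closed_form_ols(self):
        rng = np.random.default_rng(11)
        y = 1.0 - 0.08 * np.asarray(self.doses) + rng.normal(0, 0.02, 5)
        table = pd.DataFrame([y], index=["P1"],
                             columns=[f"d{i}" for i in range(5)])
        (res,) = titration_linear_screen(table, self.doses)
        slope, intercept, r2, p = ols_oracle(self.doses, y)
        assert res.slope == pytest.approx(slope, rel=1e-10)
        assert res.intercept == pytest.approx(intercept, rel=1e-10)
        assert res.r_squared == pytest.approx(r2, rel=1e-10)
        assert res.p_slope == pytest.approx(p, rel=1e-8)

    def test_fewer_than_three_doses_rejected(self):
        table = pd.DataFrame({"a": [1.0], "b": [0.5]}, index=["P1"])
        with pytest.raises(MeprodError, match="three dose"):
            titration_linear_screen(table, [0.0, 1.0])

    def test_power_on_truly_linear_titration(self):
        # every protein responds linearly; at calibrated noise >=95% are found
        rng = np.random.default_rng(7)
        n = 400
        doses = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        slopes = -rng.uniform(0.05, 0.2, n)
        y = 1.0 + slopes[:, None] * doses[None, :]
        y = y * rng.lognormal(0, 0.03, size=y.shape)
        table = pd.DataFrame(y, index=[f"P{i}" for i in range(n)],
                             columns=[f"d{i}" for i in range(5)])
        results = titration_linear_screen(table, doses)
        selected = sum(r.is_linear_responder for r in results)
        assert selected >= 0.95 * n
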