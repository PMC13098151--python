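"""Tests of the paired twin/cotwin analyses and TPM utilities."""

import itertools

import numpy as np
import pandas as pd
import pytest

from oosplit import (
    InvalidInputError,
    TwinPairModel,
    TwinPairTable,
    assign_ab,
    delta_analysis,
    drop_incomplete_pairs,
    filter_tpm,
    load_panel,
    normalized_group_means,
    paired_correlation,
    paired_location_test,
    rank_absolute_differences,
)
from oosplit._stats import spearman, wilcoxon_paired
from oosplit.twins import attach_actb, tpm_pair_correlation

from conftest import make_pairs


class TestAssignAB:
    def test_lower_total_becomes_a(self, toy_pairs):
        table = assign_ab(toy_pairs)
        sub = table.members("p1").set_index("role")
        assert sub.loc["a", "total_cells"] == 48
        assert sub.loc["b", "total_cells"] == 52

    def test_tie_broken_by_sample_id(self, toy_pairs, caplog):
        table = assign_ab(toy_pairs)
        sub = table.members("p2").set_index("role")
        assert sub.loc["a", "sample_id"] == "p2_1"  # lexicographic

    def test_actb_key(self, toy_pairs):
        data = toy_pairs.data.copy()
        data["actb_tpm"] = [500.0, 300.0, 400, 600, 100, 900, 250, 200]
        table = assign_ab(TwinPairTable(data), key="actb_tpm")
        for pair_id in table.pair_ids:
            sub = table.members(pair_id).set_index("role")
            assert sub.loc["a", "actb_tpm"] <= sub.loc["b", "actb_tpm"]

    def test_idempotent_and_order_invariant(self, toy_pairs):
        once = assign_ab(toy_pairs)
        twice = assign_ab(once)
        pd.testing.assert_frame_equal(once.data, twice.data)
        shuffled = TwinPairTable(
            toy_pairs.data.iloc[::-1].reset_index(drop=True)
        )
        roles_a = assign_ab(toy_pairs).data.set_index("sample_id")["role"]
        roles_b = assign_ab(shuffled).data.set_index("sample_id")["role"]
        pd.testing.assert_series_equal(roles_a.sort_index(),
                                       roles_b.sort_index())

    def test_missing_key_names_pair(self, toy_pairs):
        data = toy_pairs.data.copy()
        data.loc[data["sample_id"] == "p3_1", "total_cells"] = np.nan
        with pytest.raises(InvalidInputError, match="p3"):
            assign_ab(TwinPairTable(data))


class TestPairedCorrelation:
    def test_perfect_agreement(self):
        table = assign_ab(make_pairs(
            [(f"p{i}", "NF", (40 + i, 40 + i), (5, 5), (8, 8), (20, 20))
             for i in range(5)]
        ))
        res = paired_correlation(table, "total_cells")
        assert res.rho == pytest.approx(1.0)

    def test_matches_rank_formula(self):
        """One discordant rank: rho equals the textbook 1 - 6*sum(d^2)/(n(n^2-1))."""
        a_vals = [10, 20, 30, 40, 50]
        b_vals = [12, 22, 35, 55, 45]  # last two swapped in rank
        table = assign_ab(make_pairs(
            [(f"p{i}", "NF", (a, b), (1, 1), (1, 1), (1, 1))
             for i, (a, b) in enumerate(zip(a_vals, b_vals))]
        ))
        res = paired_correlation(table, "total_cells")
        d2 = sum((ra - rb) ** 2 for ra, rb in zip([1, 2, 3, 4, 5],
                                                  [1, 2, 3, 5, 4]))
        assert res.rho == pytest.approx(1 - 6 * d2 / (5 * 24))

    def test_monotone_transform_invariance(self, rng):
        a = rng.normal(50, 10, 12)
        b = a + rng.normal(0, 5, 12)
        r1 = spearman(a, b)
        r2 = spearman(np.exp(a / 20), b**3)
        assert r1.rho == pytest.approx(r2.rho)

    def test_too_few_pairs(self):
        table = assign_ab(make_pairs(
            [("p1", "NF", (40, 42), (5, 5), (8, 8), (20, 20)),
             ("p2", "NF", (44, 45), (5, 5), (8, 8), (20, 20))]
        ))
        with pytest.raises(InvalidInputError, match="3 complete pairs"):
            paired_correlation(table, "total_cells")


class TestPairedLocationTest:
    def test_all_zero_differences(self):
        table = assign_ab(make_pairs(
            [(f"p{i}", "NF", (40, 40), (5, 5), (8, 8), (20, 20))
             for i in range(4)]
        ))
        res = paired_location_test(table, "epiblast")
        assert res.pvalue == 1.0
        assert res.n_zero == 4

    def test_exact_p_for_six_positive_differences(self):
        """Six uniformly signed differences: exact two-sided p = 2/2^6."""
        res = wilcoxon_paired([0] * 6, [1, 2, 3, 4, 5, 6])
        assert res.pvalue == pytest.approx(2 / 64)

    def test_exact_p_matches_sign_enumeration(self):
        """Exact p agrees with brute-force enumeration of all sign flips."""
        diffs = np.array([1.5, -2.0, 3.0, 4.5, -0.5, 2.5, 6.0])
        ranks = pd.Series(np.abs(diffs)).rank().to_numpy()
        w_obs = ranks[diffs > 0].sum()
        total = ranks.sum()
        stats_all = [
            np.array(signs) @ ranks
            for signs in itertools.product([0, 1], repeat=len(diffs))
        ]
        mean = total / 2
        p_brute = np.mean(
            [abs(w - mean) >= abs(w_obs - mean) - 1e-12 for w in stats_all]
        )
        res = wilcoxon_paired(np.zeros_like(diffs), diffs)
        assert res.pvalue == pytest.approx(p_brute)


class TestDeltaAnalysis:
    def test_identical_twins(self):
        table = make_pairs(
            [(f"p{i}", "NF", (40, 40), (5, 5), (8, 8), (27, 27))
             for i in range(3)]
        )
        res = delta_analysis(table)
        assert (res.records.filter(like="delta_") == 0).all().all()
        assert res.restricted_mean["epiblast"] == 0.0

    def test_matches_absolute_differences(self, toy_pairs):
        res = delta_analysis(toy_pairs)
        rec = res.records.set_index("pair_id")
        assert rec.loc["p1", "delta_total"] == 4
        assert rec.loc["p1", "delta_epiblast"] == 2
        assert rec.loc["p4", "delta_epiblast"] == 3
        # pairs with delta_total == 0: p2 (|5-8|=3) and p4 (|3-6|=3)
        assert res.n_restricted == 2
        assert res.restricted_mean["epiblast"] == pytest.approx(3.0)
        assert res.restricted_range["epiblast"] == (3.0, 3.0)

    def test_undefined_without_matched_totals(self):
        table = make_pairs(
            [(f"p{i}", "NF", (40, 45 + i), (5, 6), (8, 8), (20, 20))
             for i in range(3)]
        )
        res = delta_analysis(table)
        assert res.restricted_mean["epiblast"] is None

    def test_window_widens_restriction(self, toy_pairs):
        res = delta_analysis(toy_pairs, window=4)
        assert res.n_restricted == 3  # p1 (delta 4), p2, p4


class TestFilterTpm:
    def test_strict_inequality_at_boundary(self):
        tpm = pd.DataFrame({f"s{i}": [1.0, 1.01] for i in range(5)},
                           index=["at_one", "above"])
        out = filter_tpm(tpm)
        assert list(out.index) == ["above"]

    def test_exactly_three_samples_kept(self):
        row = [5.0] * 3 + [0.0] * 17
        tpm = pd.DataFrame([row, [0.5] * 20],
                           index=["kept", "dropped"],
                           columns=[f"s{i}" for i in range(20)])
        out = filter_tpm(tpm)
        assert list(out.index) == ["kept"]

    def test_matches_row_scan_and_is_fixpoint(self, rng):
        tpm = pd.DataFrame(
            rng.lognormal(0, 2, (500, 10)),
            index=[f"g{i:03d}" for i in range(500)],
            columns=[f"s{i}" for i in range(10)],
        )
        out = filter_tpm(tpm)
        expected = {
            g for g in tpm.index if (tpm.loc[g] > 1).sum() >= 3
        }
        assert set(out.index) == expected
        assert set(out.index) <= set(tpm.index)
        pd.testing.assert_frame_equal(filter_tpm(out), out)

    def test_sorted_by_geometric_mean_descending(self, rng):
        tpm = pd.DataFrame(
            rng.lognormal(1, 1, (50, 6)),
            index=[f"g{i:02d}" for i in range(50)],
            columns=[f"s{i}" for i in range(6)],
        )
        out = filter_tpm(tpm)
        gmeans = np.exp(np.log(out).mean(axis=1))
        assert (np.diff(gmeans) <= 1e-12).all()


class TestDropIncompletePairs:
    def test_identity_without_failures(self, toy_pairs):
        out = drop_incomplete_pairs(toy_pairs)
        pd.testing.assert_frame_equal(out.data, toy_pairs.data)

    def test_cotwin_dropped_with_twin(self, toy_pairs):
        out = drop_incomplete_pairs(toy_pairs, failed_samples=["p2_1"])
        assert out.n_pairs == 3
        assert "p2" not in set(out.data["pair_id"])

    def test_matches_completeness_oracle(self, rng):
        records = [
            (f"p{i}", "NF", (40, 42), (5, 6), (8, 8), (20, 20))
            for i in range(10)
        ]
        table = make_pairs(records)
        failed = list(rng.choice(table.data["sample_id"], 5, replace=False))
        out = drop_incomplete_pairs(table, failed_samples=failed)
        bad_pairs = {
            s.rsplit("_", 1)[0] for s in failed
        }
        expected = [p for p in table.data["pair_id"].unique()
                    if p not in bad_pairs]
        assert list(out.data["pair_id"].unique()) == expected


class TestTpmRankingAndRatios:
    def make_tpm_table(self):
        records = [
            ("p1", "equatorial", (48, 52), (4, 6), (8, 8), (30, 32)),
            ("p2", "equatorial", (50, 51), (5, 8), (7, 7), (30, 30)),
        ]
        tpm = pd.DataFrame(
            {
                "p1_1": [10.0, 100.0, 5.0, 1000.0, 3.0],
                "p1_2": [12.0, 90.0, 5.0, 1010.0, 3.0],
                "p2_1": [11.0, 95.0, 6.0, 995.0, 3.0],
                "p2_2": [11.0, 105.0, 6.0, 1005.0, 3.0],
            },
            index=["g_small", "g_mid", "g_tiny", "g_big", "g_zero"],
        )
        return make_pairs(records, tpm=tpm)

    def test_rank_absolute_differences(self):
        table = self.make_tpm_table()
        ranked = rank_absolute_differences(table)
        # mean |diffs|: g_big (10+10)/2=10, g_mid (10+10)/2=10,
        # g_small (2+0)/2=1, g_tiny 0, g_zero 0 -> ties by symbol
        assert list(ranked.index) == ["g_big", "g_mid", "g_small",
                                      "g_tiny", "g_zero"]
        assert ranked.iloc[0] == pytest.approx(10.0)

    def test_all_zero_differences_sorted_by_symbol(self):
        records = [("p1", "NF", (40, 40), (5, 5), (8, 8), (20, 20))]
        tpm = pd.DataFrame({"p1_1": [1.0, 2.0, 3.0], "p1_2": [1.0, 2.0, 3.0]},
                           index=["c", "a", "b"])
        ranked = rank_absolute_differences(make_pairs(records, tpm=tpm))
        assert list(ranked.index) == ["a", "b", "c"]

    def test_normalized_group_means(self):
        tpm = pd.DataFrame(
            {
                "e1": [10.0, 40.0], "e2": [10.0, 40.0],
                "i1": [5.0, 40.0], "i2": [5.0, 40.0],
                "c1": [20.0, 80.0], "c2": [20.0, 80.0],
            },
            index=["Nanog", "Sox2"],
        )
        groups = pd.Series(
            {"e1": "equatorial", "e2": "equatorial", "i1": "ipsilateral",
             "i2": "ipsilateral", "c1": "contralateral", "c2": "contralateral"}
        )
        panel = load_panel("epiblast")
        ratios = normalized_group_means(tpm, groups, panel, "equatorial")
        assert (ratios["equatorial"] == 1.0).all()
        assert ratios.loc["Nanog", "ipsilateral"] == pytest.approx(0.5)
        assert ratios.loc["Sox2", "contralateral"] == pytest.approx(2.0)

    def test_normalized_group_means_oracle(self, rng):
        genes = list(load_panel("housekeeping"))
        samples = [f"s{i}" for i in range(9)]
        tpm = pd.DataFrame(rng.lognormal(3, 1, (len(genes), 9)),
                           index=genes, columns=samples)
        groups = pd.Series(dict(zip(samples, ["a", "b", "c"] * 3)))
        ratios = normalized_group_means(tpm, groups, load_panel("housekeeping"),
                                        "b")
        for g in genes:
            ref = tpm.loc[g, groups[groups == "b"].index].mean()
            for grp in ("a", "c"):
                expected = tpm.loc[g, groups[groups == grp].index].mean() / ref
                assert ratios.loc[g, grp] == pytest.approx(expected)

    def test_attach_actb_and_tpm_correlation(self):
        table = self.make_tpm_table()
        tpm = table.tpm.copy()
        tpm.loc["Actb"] = [4800.0, 5200.0, 5000.0, 5100.0]
        table = TwinPairTable(table.data, tpm)
        table = attach_actb(table)
        table = assign_ab(table, key="actb_tpm")
        res = tpm_pair_correlation(table)
        assert res.n == 12  # 6 genes x 2 pairs
        assert res.rho > 0.9


class TestModelFrontEnd:
    def test_fit_summary_runs(self, toy_pairs):
        model = TwinPairModel(toy_pairs)
        res = model.fit("epiblast", group="equatorial")
        assert res.n_pairs == 4
        text = res.summary()
        assert "Spearman" in text and "Wilcoxon" in text

    def test_from_dataframe(self, toy_pairs):
        model = TwinPairModel.from_dataframe(toy_pairs.data)
        assert model.table.n_pairs == 4
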