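from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bcl2panel import de, synth
from conftest import tiny_config
from oracles import fisher_exact_enumerate, rank_sum_exact


class TestRankSum:
    @pytest.mark.parametrize(
        "a, b, expected_p",
        [
            ([1, 2], [3, 4], 1 / 3),
            (list(range(1, 11)), list(range(11, 21)), 2 / comb(20, 10)),
        ],
    )
    def test_exact_worked_examples(self, a, b, expected_p):
        u, p = de.rank_sum_test(a, b)
        assert p == pytest.approx(expected_p, rel=1e-9)

    def test_identical_groups_give_p_one(self):
        _, p = de.rank_sum_test([1.0, 2.0, 5.0], [5.0, 1.0, 2.0])
        assert p == pytest.approx(1.0)

    def test_extreme_separation_statistic(self):
        u, _ = de.rank_sum_test(list(range(1, 11)), list(range(11, 21)))
        assert u == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            de.rank_sum_test([], [1.0])

    @pytest.mark.parametrize("na,nb", [(1, 2), (2, 2), (3, 3), (2, 5), (4, 4), (3, 5)])
    def test_matches_enumeration_oracle(self, na, nb, rng):
        for _ in range(5):
            pooled = rng.permutation(np.arange(na + nb, dtype=float) * 1.37)
            a, b = pooled[:na], pooled[na:]
            _, p_impl = de.rank_sum_test(a, b)
            _, p_oracle = rank_sum_exact(a, b)
            assert p_impl == pytest.approx(p_oracle, rel=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_p_in_unit_interval_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=rng.integers(2, 12))
        b = rng.normal(size=rng.integers(2, 12))
        _, p_ab = de.rank_sum_test(a, b)
        _, p_ba = de.rank_sum_test(b, a)
        assert 0 < p_ab <= 1
        assert p_ab == pytest.approx(p_ba, rel=1e-9)


class TestKruskalWallis:
    def test_balanced_mean_ranks_give_zero_h(self):
        h, p = de.kruskal_wallis_test([[1, 6], [2, 5], [3, 4]])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_h(self):
        # H = 12/(6*7) * (2*4 + 0 + 2*4) = 4.571...
        h, _ = de.kruskal_wallis_test([[1, 2], [3, 4], [5, 6]])
        assert h == pytest.approx(32 / 7, rel=1e-9)

    def test_all_identical_degenerates_to_null(self):
        h, p = de.kruskal_wallis_test([[2.0, 2.0], [2.0], [2.0, 2.0]])
        assert (h, p) == (0.0, 1.0)

    def test_shifting_one_group_raises_h(self, rng):
        groups = [list(rng.normal(size=8)) for _ in range(3)]
        h0, _ = de.kruskal_wallis_test(groups)
        shifted = [groups[0], groups[1], [x + 10 for x in groups[2]]]
        h1, _ = de.kruskal_wallis_test(shifted)
        assert h1 > h0

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValueError, match=">=3 groups"):
            de.kruskal_wallis_test([[1, 2], [3, 4]])


class TestFisherExact:
    def test_independence_gives_or_one_p_one(self):
        orr, p = de.fisher_exact_test([[5, 5], [5, 5]])
        assert orr == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_cross_product_odds_ratio(self):
        orr, _ = de.fisher_exact_test([[10, 2], [3, 15]])
        assert orr == pytest.approx(25.0)

    def test_diagonal_table_two_sided_p(self):
        # each extreme table has probability 1/C(6,3) = 1/20; both tails: 0.1
        orr, p = de.fisher_exact_test([[3, 0], [0, 3]])
        assert orr == float("inf")
        assert p == pytest.approx(0.1, rel=1e-9)

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            de.fisher_exact_test([[0, 0], [0, 0]])

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            de.ContingencyTable2x2(-1, 2, 3, 4)

    @given(
        st.tuples(
            st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12)
        ).filter(lambda t: 0 < sum(t) <= 40)
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_same_margin_enumeration(self, counts):
        a, b, c, d = counts
        or_impl, p_impl = de.fisher_exact_test([[a, b], [c, d]])
        or_oracle, p_oracle = fisher_exact_enumerate(a, b, c, d)
        assert p_impl == pytest.approx(p_oracle, rel=1e-8)
        if np.isfinite(or_oracle):
            assert or_impl == pytest.approx(or_oracle, rel=1e-12)


class TestStars:
    @pytest.mark.parametrize(
        "p, code",
        [
            (0.5, "ns"),
            (0.05, "ns"),
            (0.049, "*"),
            (0.01, "*"),
            (0.004, "**"),
            (0.0009, "***"),
            (5e-5, "****"),
        ],
    )
    def test_star_mapping(self, p, code):
        assert de.star_code(p) == code

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            de.star_code(0.0)


class TestCompareProfiles:
    def test_identity_contrast_all_ns(self, demo_run):
        _, _, ann, _, gt = demo_run
        sel = {"entity": "CLL"}
        table = de.compare_profiles(
            gt.latent.loc[["BCL2", "BAX"]], ann, [("self", sel, sel)]
        )
        assert (table["stars"] == "ns").all()

    def test_planted_shift_reaches_four_stars(self):
        hits = 0
        for seed in range(40):
            cfg = tiny_config(
                seed=seed,
                entities={"CLL": 50, "MemoryB": 50},
                entity_effects={"BCL2": {"CLL": 2.0}},
                tissue_effects={},
                noise_sd=0.5,
            )
            _, ann, _, gt = synth.generate_dataset(cfg)
            table = de.compare_profiles(
                gt.latent.loc[["BCL2"]],
                ann,
                [("CLL_vs_normal", {"entity": "CLL"}, {"entity": "MemoryB"})],
            )
            hits += table["p"].iloc[0] < 1e-4
        assert hits >= 38

    def test_empty_selector_yields_error_row(self, demo_run):
        _, _, ann, _, gt = demo_run
        table = de.compare_profiles(
            gt.latent.loc[["BCL2"]],
            ann,
            [("bad", {"entity": "NOPE"}, {"entity": "CLL"})],
        )
        assert table["error"].iloc[0].startswith("empty selector")

    def test_bh_flag_adds_adjusted_column(self, demo_run):
        _, _, ann, _, gt = demo_run
        table = de.compare_profiles(
            gt.latent.iloc[:6],
            ann,
            [("c", {"entity": "CLL"}, {"entity": "MM"})],
            bh_correct=True,
        )
        assert (table["p_adj"] >= table["p"] - 1e-15).all()


class TestMedianProfile:
    def test_order_statistic_by_hand(self):
        m = pd.DataFrame([[1.0, 2.0, 9.0]], index=["g"], columns=["a", "b", "c"])
        grouping = pd.Series({"a": "x", "b": "x", "c": "x"})
        out = de.median_profile(m, grouping)
        assert out.loc["g", "x"] == 2.0

    def test_constant_matrix_zscores_to_zero(self):
        m = pd.DataFrame(
            np.full((3, 6), 5.0),
            index=list("abc"),
            columns=[f"s{i}" for i in range(6)],
        )
        grouping = pd.Series({f"s{i}": f"g{i % 3}" for i in range(6)})
        out = de.median_profile(m, grouping, zscore=True)
        np.testing.assert_allclose(out.to_numpy(), 0.0)

    def test_zscored_rows_standardized(self, demo_run):
        _, _, ann, _, gt = demo_run
        out = de.median_profile(gt.latent.iloc[:8], ann["entity"], zscore=True)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-9)
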