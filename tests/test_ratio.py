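import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bcl2panel import ratio, synth
from conftest import tiny_config


def gene_frame(values: dict, samples):
    return pd.DataFrame(values, index=samples).T


class TestRatioScore:
    def test_equal_genes_give_three(self):
        m = gene_frame(
            {"BCL2": [5.0], "BCL2L11": [5.0], "BAX": [5.0], "BCL2L1": [5.0]}, ["s1"]
        )
        score = ratio.ratio_score(m, ratio.SENSITIVITY_RATIO)
        assert score["s1"] == pytest.approx(3.0)

    def test_worked_example(self):
        m = gene_frame(
            {"BCL2": [8.0], "BCL2L11": [6.0], "BAX": [7.0], "BCL2L1": [7.0]}, ["s1"]
        )
        assert ratio.ratio_score(m, ratio.SENSITIVITY_RATIO)["s1"] == pytest.approx(3.0)

    def test_missing_gene_rejected(self):
        m = gene_frame({"BCL2": [1.0]}, ["s1"])
        with pytest.raises(KeyError, match="absent"):
            ratio.ratio_score(m, ratio.SENSITIVITY_RATIO)

    def test_non_positive_denominator_names_sample(self):
        m = gene_frame(
            {"BCL2": [8.0], "BCL2L11": [6.0], "BAX": [7.0], "BCL2L1": [-1.0]}, ["bad1"]
        )
        with pytest.raises(ValueError, match="bad1"):
            ratio.ratio_score(m, ratio.SENSITIVITY_RATIO)

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_common_rescaling_leaves_score_invariant(self, c):
        m = gene_frame(
            {"BCL2": [8.0, 4.0], "BCL2L11": [6.0, 5.0], "BAX": [7.0, 6.0], "BCL2L1": [7.0, 3.0]},
            ["s1", "s2"],
        )
        base = ratio.ratio_score(m, ratio.SENSITIVITY_RATIO)
        scaled = ratio.ratio_score(m * c, ratio.SENSITIVITY_RATIO)
        np.testing.assert_allclose(base.to_numpy(), scaled.to_numpy(), rtol=1e-12)

    def test_linear_scale_option(self):
        m = gene_frame(
            {"BCL2": [3.0], "BCL2L11": [3.0], "BAX": [3.0], "BCL2L1": [3.0]}, ["s1"]
        )
        assert ratio.ratio_score(m, ratio.SENSITIVITY_RATIO, scale="linear")["s1"] == pytest.approx(3.0)


class TestEnumeration:
    def test_default_pools_give_49_candidates(self):
        specs = ratio.enumerate_ratio_specs()
        assert len(specs) == 49
        assert len(set(specs)) == 49

    def test_singleton_pools_give_one(self):
        specs = ratio.enumerate_ratio_specs(["BCL2"], ["BCL2L1"])
        assert specs == [ratio.RatioSpec(("BCL2",), ("BCL2L1",))]

    def test_reported_ratio_is_enumerated(self):
        assert ratio.SENSITIVITY_RATIO in ratio.enumerate_ratio_specs()

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ratio.enumerate_ratio_specs([], ["MCL1"])

    def test_empty_numerator_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ratio.RatioSpec((), ("BCL2L1",))


class TestRanking:
    def exact_linear_matrix(self):
        # entity medians exactly linear in ORR for the reported ratio
        entities = ["E1", "E2", "E3", "E4", "E5"]
        samples = [f"{e}_{i}" for e in entities for i in range(3)]
        ann = pd.DataFrame(
            {"entity": [s.split("_")[0] for s in samples]}, index=samples
        )
        rows = {g: [] for g in ("BCL2", "BCL2L11", "BAX", "MCL1", "BCL2L1", "BCL2A1")}
        rng = np.random.default_rng(7)
        base = {"E1": 6.0, "E2": 6.5, "E3": 7.0, "E4": 7.5, "E5": 8.0}
        for s in samples:
            e = s.split("_")[0]
            rows["BCL2"].append(base[e])
            rows["BCL2L11"].append(base[e] + rng.normal(0, 1e-9))
            rows["BAX"].append(base[e])
            rows["BCL2L1"].append(7.0)
            rows["MCL1"].append(7.0 + rng.normal(0, 0.3))
            rows["BCL2A1"].append(7.0 + rng.normal(0, 0.3))
        m = pd.DataFrame(rows, index=samples).T
        scores = ratio.ratio_score(m, ratio.SENSITIVITY_RATIO)
        med = scores.groupby(ann["entity"]).median()
        orr = {e: 10.0 + 25.0 * float(med[e]) for e in entities}
        return m, ann, orr

    def test_noise_free_linear_link_gives_r_one(self):
        m, ann, orr = self.exact_linear_matrix()
        ranking = ratio.rank_ratio_candidates(
            m, ann, orr, summary="median-per-entity"
        )
        row = ranking[
            (ranking["numerator"] == "BCL2+BCL2L11+BAX")
            & (ranking["denominator"] == "BCL2L1")
        ].iloc[0]
        assert row["r"] == pytest.approx(1.0, abs=1e-9)

    def test_ranks_are_a_permutation(self, demo_run):
        _, _, ann, _, gt = demo_run
        ranking = ratio.rank_ratio_candidates(gt.latent, ann, gt.implied_orr)
        assert sorted(ranking["rank"]) == list(range(1, 50))
        assert (ranking["r"].diff().dropna() <= 1e-12).all()

    def test_entities_without_orr_are_excluded_from_correlation(self, demo_run):
        _, _, ann, _, gt = demo_run
        orr = synth.default_orr_table()
        ranking = ratio.rank_ratio_candidates(gt.latent, ann, orr)
        n_with_orr = int(ann["entity"].isin(orr).sum())
        assert (ranking["n"] == n_with_orr).all()

    def test_fewer_than_three_entities_rejected(self, demo_run):
        _, _, ann, _, gt = demo_run
        with pytest.raises(ValueError, match=">=3 entities"):
            ratio.rank_ratio_candidates(gt.latent, ann, {"CLL": 79.0, "MM": 21.0})

    def test_ranking_invariant_to_candidate_order(self, demo_run):
        _, _, ann, _, gt = demo_run
        specs = ratio.enumerate_ratio_specs()
        fwd = ratio.rank_ratio_candidates(gt.latent, ann, gt.implied_orr, specs)
        rev = ratio.rank_ratio_candidates(gt.latent, ann, gt.implied_orr, specs[::-1])
        key = ["numerator", "denominator"]
        merged = fwd.merge(rev, on=key, suffixes=("_f", "_r"))
        ties = merged["r_f"].duplicated(keep=False)
        assert (merged.loc[~ties, "rank_f"] == merged.loc[~ties, "rank_r"]).all()


class TestGroupComparison:
    def test_identical_groups_not_significant(self, rng):
        scores = pd.Series(rng.normal(3, 0.1, 40), index=[f"s{i}" for i in range(40)])
        ann = pd.DataFrame(
            {"tissue": ["PB"] * 20 + ["LN"] * 20}, index=scores.index
        )
        ann_scores = scores.copy()
        ann_scores[20:] = ann_scores[:20].to_numpy()  # same values both groups
        out = ratio.compare_ratio_by_group(ann_scores, ann, "tissue")
        assert out["stars"].iloc[0] == "ns"

    def test_lymph_node_niche_lowers_the_ratio(self):
        hits = 0
        for seed in range(100):
            cfg = tiny_config(
                seed=seed,
                entities={"MCL": 60},
                tissue_mix={"MCL": {"PB": 0.5, "LN": 0.5, "BM": 0.0, "SPL": 0.0}},
            )
            _, ann, _, gt = synth.generate_dataset(cfg)
            scores = ratio.ratio_score(gt.latent, cfg.planted_ratio)
            out = ratio.compare_ratio_by_group(scores, ann, "tissue")
            row = out.iloc[0]
            med = {row["group_a"]: row["median_a"], row["group_b"]: row["median_b"]}
            hits += (med["LN"] < med["PB"]) and (row["p"] < 0.05)
        assert hits >= 90

    def test_ccnd1_myeloma_subgroup_has_top_ratio(self):
        hits = 0
        for seed in range(100):
            cfg = tiny_config(seed=seed, entities={"MM": 160})
            _, ann, _, gt = synth.generate_dataset(cfg)
            scores = ratio.ratio_score(gt.latent, cfg.planted_ratio)
            med = scores.groupby(ann["subtype"]).median()
            hits += med.idxmax() == "CCND1"
        assert hits >= 90

    def test_single_group_rejected(self, rng):
        scores = pd.Series(rng.normal(3, 0.1, 10), index=[f"s{i}" for i in range(10)])
        ann = pd.DataFrame({"tissue": ["PB"] * 10}, index=scores.index)
        with pytest.raises(ValueError, match="two groups"):
            ratio.compare_ratio_by_group(scores, ann, "tissue")
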