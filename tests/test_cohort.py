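from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mitoscatac.cohort import (
    aggregate_profile_correlation,
    burden_group_comparison,
    gene_activity_scores,
    mean_vaf_by_group,
    mutation_burden,
    pairwise_content_matrix,
    shared_variant_sets,
    significant_pair_fraction,
    signature_score,
    wilcoxon_rank_sum,
)


def enumerate_exact_p(x, y):
    """Oracle: full enumeration of group assignments of the pooled sample."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n, N = len(x), len(pooled)
    obs = ranks[:n].sum()
    sums = [ranks[list(c)].sum() for c in combinations(range(N), n)]
    sums = np.asarray(sums)
    le = (sums <= obs + 1e-9).mean()
    ge = (sums >= obs - 1e-9).mean()
    return min(1.0, 2 * min(le, ge))


class TestWilcoxon:
    def test_canonical_small_case(self):
        # {1,2} vs {3,4}: most extreme of C(4,2)=6 assignments, two-sided 1/3
        assert wilcoxon_rank_sum([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_multisets(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("n,m", [(1, 1), (2, 3), (4, 4), (5, 7), (8, 8), (1, 8)])
    def test_exact_matches_enumeration_oracle(self, n, m):
        rng = np.random.default_rng(n * 10 + m)
        x = rng.normal(size=n)
        y = rng.normal(0.5, size=m)
        assert wilcoxon_rank_sum(x, y) == pytest.approx(enumerate_exact_p(x, y))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_with_ties_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, size=5).astype(float)
        y = rng.integers(0, 4, size=6).astype(float)
        assert wilcoxon_rank_sum(x, y) == pytest.approx(enumerate_exact_p(x, y))

    def test_exact_agrees_with_scipy(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            x = rng.normal(size=6)
            y = rng.normal(size=7)
            ours = wilcoxon_rank_sum(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(ref)

    def test_normal_approx_close_to_exact_on_8v8(self):
        rng = np.random.default_rng(123)
        for _ in range(10):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            exact = wilcoxon_rank_sum(x, y)
            approx = wilcoxon_rank_sum(x, y, exact_cap=0)
            assert abs(exact - approx) < 0.01

    def test_one_sided_directions(self):
        x, y = [1.0, 2.0], [3.0, 4.0]
        assert wilcoxon_rank_sum(x, y, "less") < wilcoxon_rank_sum(x, y, "greater")


class TestPairwiseMatrix:
    def test_bookkeeping_fractions(self):
        assert significant_pair_fraction(45, 11) == 0.82
        assert significant_pair_fraction(30, 9) == 0.83

    def test_matrix_shape_symmetry_and_total(self):
        rng = np.random.default_rng(4)
        types = rng.choice(["B", "T", "NK", "mono"], size=200)
        vals = pd.Series(rng.normal(size=200))
        mat = pairwise_content_matrix(vals, pd.Series(types))
        assert mat.total_pairs == 6
        assert (mat.p_values.to_numpy() == mat.p_values.to_numpy().T).all()
        assert mat.fraction_significant == mat.n_significant / 6

    def test_null_calibration(self):
        # identical distributions: expected significant fraction ~= alpha
        rng = np.random.default_rng(12)
        hits = 0
        total = 0
        for _ in range(60):
            types = np.repeat(["a", "b", "c"], 30)
            vals = pd.Series(rng.normal(size=90))
            mat = pairwise_content_matrix(vals, pd.Series(types), alpha=0.05)
            hits += mat.n_significant
            total += mat.total_pairs
        rate = hits / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert abs(rate - 0.05) < 4 * se + 0.01

    def test_separated_types_all_significant(self):
        rng = np.random.default_rng(2)
        vals = pd.Series(np.concatenate([rng.normal(0, 1, 50), rng.normal(5, 1, 50)]))
        types = pd.Series(["lo"] * 50 + ["hi"] * 50)
        mat = pairwise_content_matrix(vals, types)
        assert mat.n_significant == 1


class TestBurden:
    def test_missing_excluded(self):
        alt = pd.DataFrame({"v1": [0], "v2": [1], "v3": [np.nan]}, index=["c1"])
        assert mutation_burden(alt)["c1"] == 1

    def test_all_zero(self):
        alt = pd.DataFrame(np.zeros((5, 3)), index=[f"c{i}" for i in range(5)])
        assert (mutation_burden(alt) == 0).all()

    def test_monotone_in_min_alt_reads(self):
        rng = np.random.default_rng(5)
        alt = pd.DataFrame(rng.poisson(1.0, size=(50, 8)))
        b1 = mutation_burden(alt, min_alt_reads=1)
        b2 = mutation_burden(alt, min_alt_reads=2)
        assert (b2 <= b1).all()

    def test_planted_group_shift_detected(self):
        rng = np.random.default_rng(31)
        hits = 0
        for rep in range(10):
            aged = rng.poisson(1.5, size=300)
            young = rng.poisson(1.0, size=300)
            p = wilcoxon_rank_sum(aged, young)
            hits += p < 0.01
        assert hits >= 9

    def test_group_comparison_table(self):
        rng = np.random.default_rng(3)
        n = 200
        ann = pd.DataFrame({
            "barcode": [f"c{i}" for i in range(n)],
            "cell_type": np.repeat(["B", "T"], n // 2),
            "age_group": np.tile(["young", "aged"], n // 2),
        })
        alt = pd.DataFrame(
            rng.poisson(1.0, size=(n, 5)), index=ann["barcode"]
        )
        res = burden_group_comparison(mutation_burden(alt), ann)
        assert set(res["cell_type"]) == {"B", "T"}
        assert ((res["p_value"] >= 0) & (res["p_value"] <= 1)).all()


class TestMeanVaf:
    def test_single_cell_mean(self):
        vaf = pd.DataFrame({"v1": [0.5]}, index=["c1"])
        ann = pd.DataFrame({"barcode": ["c1", "c2"], "cell_type": ["B", "B"],
                            "age_group": ["young", "aged"]})
        vaf2 = pd.DataFrame({"v1": [0.5, 0.5]}, index=["c1", "c2"])
        res = mean_vaf_by_group(vaf2, ann)
        assert res.iloc[0]["mean_a"] == pytest.approx(0.5)
        assert res.iloc[0]["p_value"] == 1.0

    def test_planted_direction_recovered(self):
        rng = np.random.default_rng(21)
        n = 300
        ann = pd.DataFrame({
            "barcode": [f"c{i}" for i in range(n)],
            "cell_type": "B",
            "age_group": np.repeat(["aged", "young"], n // 2),
        })
        vaf = pd.DataFrame({
            "v": np.concatenate([rng.beta(3, 20, n // 2), rng.beta(1, 30, n // 2)])
        }, index=ann["barcode"])
        res = mean_vaf_by_group(vaf, ann)
        assert res.iloc[0]["mean_a"] > res.iloc[0]["mean_b"]  # aged > young
        assert res.iloc[0]["p_value"] < 0.01


class TestSharedVariants:
    def test_identical_singletons(self):
        out = shared_variant_sets({"a": [(1, "A", "C")], "b": [(1, "A", "C")]})
        assert out["counts"][frozenset({"a", "b"})] == 1

    def test_disjoint(self):
        out = shared_variant_sets({"a": [(1, "A", "C")], "b": [(2, "C", "T")]})
        assert out["counts"][frozenset({"a", "b"})] == 0
        assert out["counts"][frozenset({"a"})] == 1

    def test_spleen_shared_pair(self):
        # the two D-loop sites shared between young and aged spleen samples
        young = {"m.15984C>T", "m.15728C>T", "m.100A>G"}
        aged = {"m.15984C>T", "m.15728C>T", "m.200G>A"}
        out = shared_variant_sets({"young_spleen": young, "aged_spleen": aged})
        assert out["regions"][frozenset({"young_spleen", "aged_spleen"})] == {
            "m.15984C>T", "m.15728C>T"
        }

    def test_three_way_regions_partition_union(self):
        rng = np.random.default_rng(9)
        sets = {k: set(rng.integers(0, 30, size=12).tolist()) for k in "abc"}
        out = shared_variant_sets(sets)
        assert sum(out["counts"].values()) == len(out["union"])


class TestGeneActivity:
    def _genes(self):
        return pd.DataFrame(
            [("chr1", 10_000, 12_000, "+", "g1"), ("chr1", 30_000, 31_000, "-", "g2")],
            columns=["chrom", "start", "end", "strand", "gene"],
        )

    def test_fragment_in_gene_body(self):
        frags = pd.DataFrame([("chr1", 10_500, 10_700, "c1", 1)],
                             columns=["chrom", "start", "end", "barcode", "support"])
        act = gene_activity_scores(frags, self._genes())
        assert act.loc["c1", "g1"] == 1

    def test_fragment_beyond_upstream_window(self):
        frags = pd.DataFrame([("chr1", 7_800, 7_999, "c1", 1)],
                             columns=["chrom", "start", "end", "barcode", "support"])
        act = gene_activity_scores(frags, self._genes())
        assert act.loc["c1", "g1"] == 0  # ends 2,001 bp upstream of start

    def test_matches_brute_force_overlap(self):
        rng = np.random.default_rng(14)
        n = 1_000
        start = rng.integers(0, 50_000, size=n)
        frags = pd.DataFrame({
            "chrom": "chr1", "start": start,
            "end": start + rng.integers(50, 400, size=n),
            "barcode": rng.choice(["a", "b"], size=n), "support": 1,
        })
        genes = self._genes()
        act = gene_activity_scores(frags, genes)
        for _, g in genes.iterrows():
            lo = g["start"] - 2000 if g["strand"] == "+" else g["start"]
            hi = g["end"] if g["strand"] == "+" else g["end"] + 2000
            brute = frags[(frags["start"] < hi) & (frags["end"] > lo)].groupby("barcode").size()
            for bc in ("a", "b"):
                assert act.loc[bc, g["gene"]] == brute.get(bc, 0)


class TestSignature:
    def test_constant_matrix_all_zero(self):
        act = pd.DataFrame(np.full((10, 3), 7.0), columns=list("xyz"))
        assert (signature_score(act, ["x", "y"]) == 0).all()

    def test_single_gene_equals_zscore(self):
        rng = np.random.default_rng(6)
        act = pd.DataFrame({"g": rng.normal(size=20)})
        z = (act["g"] - act["g"].mean()) / act["g"].std(ddof=0)
        pd.testing.assert_series_equal(
            signature_score(act, ["g"]), z, check_names=False
        )

    def test_planted_subpopulation_recovered(self):
        rng = np.random.default_rng(16)
        n = 200
        act = pd.DataFrame(rng.poisson(5, size=(n, 10)),
                           columns=[f"g{i}" for i in range(10)])
        act.iloc[:50, :4] += 5  # high-signature subpopulation, genes g0-g3
        score = signature_score(act, ["g0", "g1", "g2", "g3"])
        p = wilcoxon_rank_sum(score[:50], score[50:])
        assert p < 0.01


class TestAggregateCorrelation:
    def test_self_correlation(self):
        a = pd.Series([1.0, 5, 9, 2], index=list("wxyz"))
        assert aggregate_profile_correlation(a, a) == pytest.approx(1.0)

    def test_scaling_invariance_raw(self):
        a = pd.Series([1.0, 5, 9, 2], index=list("wxyz"))
        assert aggregate_profile_correlation(a, 2 * a, log_transform=False) == pytest.approx(1.0)

    def test_noisy_replicates_within_predicted_band(self):
        rng = np.random.default_rng(18)
        mu = rng.gamma(2.0, 50.0, size=2_000)
        a = pd.Series(rng.poisson(mu), index=range(2_000))
        b = pd.Series(rng.poisson(mu), index=range(2_000))
        r = aggregate_profile_correlation(a, b)
        assert 0.8 < r < 1.0
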