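"""Rank-sum enrichment: exact null by enumeration, scipy cross-check, FDR."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from clinetile import enrichment as en
from clinetile.annotation import GenomeAnnotation


def make_ranked(n, prefix="g"):
    return pd.DataFrame({"gene_id": [f"{prefix}{i}" for i in range(n)],
                         "gene_t": np.linspace(5, -5, n),
                         "rank": np.arange(1, n + 1)})


class TestRankGenes:
    @staticmethod
    def _stats_labels():
        stats = pd.DataFrame({"t": [3.0, -3.0, 1.0, -0.5]},
                             index=["p1", "p2", "p3", "p4"])
        labels = pd.DataFrame({"probe_id": ["p1", "p2", "p3", "p4"],
                               "gene_id": ["gA", "gB", "gB", None]})
        return stats, labels

    def test_single_gene_rank_one(self):
        stats = pd.DataFrame({"t": [2.0]}, index=["p1"])
        labels = pd.DataFrame({"probe_id": ["p1"], "gene_id": ["gX"]})
        ranked = en.rank_genes(stats, labels)
        assert list(ranked["rank"]) == [1]

    def test_sign_ordering_and_max_abs_summary(self):
        stats, labels = self._stats_labels()
        ranked = en.rank_genes(stats, labels, direction="up_in_north")
        # gB is summarized by its max-|t| probe (t = -3), so gA (+3) ranks first
        assert list(ranked["gene_id"]) == ["gA", "gB"]
        assert list(ranked["gene_t"]) == [3.0, -3.0]

    def test_direction_reversal_reverses_order(self):
        stats, labels = self._stats_labels()
        north = en.rank_genes(stats, labels, direction="up_in_north")
        south = en.rank_genes(stats, labels, direction="up_in_south")
        assert list(north["gene_id"]) == list(reversed(list(south["gene_id"])))

    def test_mean_summary_option(self):
        stats, labels = self._stats_labels()
        ranked = en.rank_genes(stats, labels, summary="mean_t")
        assert ranked.set_index("gene_id").loc["gB", "gene_t"] == pytest.approx(-1.0)

    def test_empty_raises(self):
        stats = pd.DataFrame({"t": [1.0]}, index=["p1"])
        labels = pd.DataFrame({"probe_id": ["p1"], "gene_id": [None]})
        with pytest.raises(ValueError):
            en.rank_genes(stats, labels)


class TestCategoryScore:
    def test_top_two_of_five(self):
        ranked = make_ranked(5)
        m, W, p = en.category_score(ranked, ["g0", "g1"], method="exact")
        assert (m, W) == (2, 3)
        assert p == pytest.approx(0.1)  # 1 / C(5,2)

    def test_bottom_ranks_give_p_one(self):
        ranked = make_ranked(6)
        _, _, p = en.category_score(ranked, ["g3", "g4", "g5"], method="exact")
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("N,m", [(5, 2), (8, 3), (12, 6), (12, 1)])
    def test_exact_matches_full_enumeration(self, N, m):
        ranked = make_ranked(N)
        for members in itertools.combinations(range(N), m):
            W = sum(r + 1 for r in members)
            count = sum(
                1 for sub in itertools.combinations(range(1, N + 1), m)
                if sum(sub) <= W
            )
            expected = count / math.comb(N, m)
            _, _, p = en.category_score(ranked, [f"g{i}" for i in members],
                                        method="exact")
            assert p == pytest.approx(expected, rel=1e-12)

    def test_exact_matches_scipy_rank_sum(self):
        # Wilcoxon rank-sum connection: P(W' <= W) equals the one-sided
        # exact Mann-Whitney p of members vs non-members
        N, m = 10, 4
        ranked = make_ranked(N)
        members = ["g1", "g4", "g5", "g8"]
        _, W, p = en.category_score(ranked, members, method="exact")
        ranks = ranked.set_index("gene_id")["rank"]
        x = ranks.loc[members].to_numpy()
        y = ranks.drop(members).to_numpy()
        mw = sps.mannwhitneyu(x, y, alternative="less", method="exact")
        assert p == pytest.approx(mw.pvalue, rel=1e-12)

    def test_normal_close_to_exact_mid_size(self):
        # moderately enriched category (exact p ~ 0.1): the continuity-
        # corrected normal should be close in relative terms
        ranked = make_ranked(60)
        members = [f"g{r - 1}" for r in (4, 8, 12, 16, 20, 24, 28, 32, 40, 56)]
        _, _, p_exact = en.category_score(ranked, members, method="exact")
        _, _, p_norm = en.category_score(ranked, members, method="normal")
        assert p_norm == pytest.approx(p_exact, rel=0.1)

    def test_whole_list_category_raises(self):
        ranked = make_ranked(4)
        with pytest.raises(ValueError):
            en.category_score(ranked, [f"g{i}" for i in range(4)])

    def test_unknown_member_raises(self):
        with pytest.raises(ValueError, match="absent"):
            en.category_score(make_ranked(4), ["nope"])

    def test_w_bounds_invariant(self):
        rng = np.random.default_rng(3)
        ranked = make_ranked(50)
        for _ in range(20):
            m = int(rng.integers(1, 20))
            members = [f"g{i}" for i in rng.choice(50, size=m, replace=False)]
            m_out, W, p = en.category_score(ranked, members, method="normal")
            assert m * (m + 1) / 2 <= W <= m * 50 - m * (m - 1) / 2
            assert 0.0 <= p <= 1.0


class TestPermutationFdr:
    def test_planted_category_low_fdr(self):
        rng = np.random.default_rng(7)
        N = 5000
        ranked = make_ranked(N)
        categories = {"planted": [f"g{i}" for i in range(25)]}  # all in top 1%
        for j in range(40):
            categories[f"null{j}"] = [
                f"g{i}" for i in rng.choice(N, size=25, replace=False)]
        scored = en.score_categories(ranked, categories)
        result = en.permutation_fdr(scored, ranked, categories,
                                    n_permutations=200, seed=1)
        planted_fdr = result.set_index("category_id").loc["planted", "fdr"]
        assert planted_fdr < 0.1

    def test_null_categories_rarely_pass(self):
        rng = np.random.default_rng(8)
        N = 1000
        perm_rank = rng.permutation(N) + 1
        ranked = pd.DataFrame({"gene_id": [f"g{i}" for i in range(N)],
                               "gene_t": 0.0, "rank": perm_rank}
                              ).sort_values("rank").reset_index(drop=True)
        categories = {f"c{j}": [f"g{i}" for i in rng.choice(N, 20, replace=False)]
                      for j in range(200)}
        scored = en.score_categories(ranked, categories)
        result = en.permutation_fdr(scored, ranked, categories,
                                    n_permutations=200, seed=2)
        assert (result["fdr"] < 0.1).mean() <= 0.05

    def test_more_permutations_consistent(self):
        rng = np.random.default_rng(9)
        N = 500
        ranked = make_ranked(N)
        categories = {f"c{j}": [f"g{i}" for i in rng.choice(N, 15, replace=False)]
                      for j in range(30)}
        scored = en.score_categories(ranked, categories)
        f1 = en.permutation_fdr(scored, ranked, categories, 200, seed=3)["fdr"]
        f2 = en.permutation_fdr(scored, ranked, categories, 400, seed=4)["fdr"]
        # Monte-Carlo consistency: no estimate moves by more than ~2 SE
        assert (np.abs(f1 - f2) < 0.2).all()

    def test_too_few_permutations_rejected(self):
        ranked = make_ranked(10)
        categories = {"c": ["g1"]}
        scored = en.score_categories(ranked, categories)
        with pytest.raises(ValueError):
            en.permutation_fdr(scored, ranked, categories, n_permutations=10)


class TestNullUniformity:
    def test_category_p_uniform_under_shuffled_ranking(self):
        rng = np.random.default_rng(12)
        N = 2000
        ranked = make_ranked(N)
        pvals = []
        for _ in range(2000):
            members = [f"g{i}" for i in rng.choice(N, size=20, replace=False)]
            _, _, p = en.category_score(ranked, members, method="normal")
            pvals.append(p)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestPositionalCategory:
    @staticmethod
    def _ann():
        genes = pd.DataFrame(
            [{"gene_id": "in", "chrom": "c", "start": 100, "end": 200, "strand": "+"},
             {"gene_id": "out", "chrom": "c", "start": 500, "end": 600, "strand": "+"},
             {"gene_id": "straddle", "chrom": "c", "start": 240, "end": 320,
              "strand": "+"}])
        return GenomeAnnotation(chrom_lengths={"c": 1000}, genes=genes)

    def test_membership_rules(self):
        ann = self._ann()
        members = en.positional_category(ann, "c", 50, 250)
        assert members == ["in", "straddle"]  # >= 1 bp overlap counts

    def test_unknown_chromosome(self):
        with pytest.raises(ValueError):
            en.positional_category(self._ann(), "zz", 1, 10)
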