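"""Window counting, permutation CIs, smoothing, gene counts, combination."""

import numpy as np
import pandas as pd
import pytest

from genewin import enrich
from genewin.enrich import EXON, EnrichConfig


def make_assignments(rows):
    return pd.DataFrame(rows, columns=["snp_id", "gene_id", "window_index",
                                       "in_exon", "distance_bp"])


@pytest.fixture()
def toy():
    """120 SNPs: 100 in window 0 (20 exonic), 10 in -1, 10 unassigned."""
    rows = []
    for i in range(100):
        rows.append((f"s{i:03d}", "ga", 0, i < 20, 0))
    for i in range(100, 110):
        rows.append((f"s{i:03d}", "ga", -1, False, 5000))
    assignments = make_assignments(rows)
    pvals = pd.Series(1.0, index=[f"s{i:03d}" for i in range(120)])
    return assignments, pvals


class TestWindowCounts:
    def test_proportion_is_ratio_of_counts(self, toy):
        assignments, pvals = toy
        pvals.iloc[:10] = 0.05  # 10 suggestive in window 0 (all exonic subset)
        obs = enrich.window_counts(assignments, pvals, alphas=(0.1,))
        assert obs.loc[0, "n_total"] == 100
        assert obs.loc[0, "n_below_0.1"] == 10
        assert obs.loc[0, "n_below_0.1"] / obs.loc[0, "n_total"] == 0.10

    def test_p_equal_to_alpha_not_counted(self, toy):
        assignments, pvals = toy
        pvals.iloc[0] = 0.1
        obs = enrich.window_counts(assignments, pvals, alphas=(0.1,))
        assert obs.loc[0, "n_below_0.1"] == 0

    def test_exon_subset_of_gene_window(self, toy):
        assignments, pvals = toy
        pvals.iloc[:30] = 0.001
        obs = enrich.window_counts(assignments, pvals, alphas=(0.1,))
        assert obs.loc[EXON, "n_total"] == 20
        assert obs.loc[EXON, "n_total"] <= obs.loc[0, "n_total"]
        assert obs.loc[EXON, "n_below_0.1"] <= obs.loc[0, "n_below_0.1"]

    def test_unassigned_snps_ignored(self, toy):
        assignments, pvals = toy
        obs = enrich.window_counts(assignments, pvals, alphas=(0.1,))
        assert obs["n_total"].sum() == 110 + 20  # exon row double-counts

    def test_matches_groupby_recount(self, rng, toy):
        assignments, pvals = toy
        pvals.iloc[:] = rng.random(len(pvals))
        obs = enrich.window_counts(assignments, pvals, alphas=(0.1, 0.01))
        merged = assignments.merge(pvals.rename("p"), left_on="snp_id",
                                   right_index=True)
        for a in (0.1, 0.01):
            by_win = merged.groupby("window_index")["p"].agg(lambda x: (x < a).sum())
            for w, cnt in by_win.items():
                assert obs.loc[w, f"n_below_{a:g}"] == cnt
            exon_cnt = (merged[merged.in_exon]["p"] < a).sum()
            assert obs.loc[EXON, f"n_below_{a:g}"] == exon_cnt

    def test_alpha_monotonicity(self, rng, toy):
        assignments, pvals = toy
        pvals.iloc[:] = rng.random(len(pvals))
        obs = enrich.window_counts(assignments, pvals, alphas=(0.001, 0.01, 0.1))
        assert (obs["n_below_0.001"] <= obs["n_below_0.01"]).all()
        assert (obs["n_below_0.01"] <= obs["n_below_0.1"]).all()

    def test_invalid_alpha_rejected(self, toy):
        assignments, pvals = toy
        with pytest.raises(ValueError):
            enrich.window_counts(assignments, pvals, alphas=(1.5,))


class TestNearestRankCi:
    def test_degenerate_distribution(self):
        lo, hi = enrich.nearest_rank_ci(np.full((50, 1), 7))
        assert lo[0] == 7 and hi[0] == 7

    def test_one_to_hundred(self):
        lo, hi = enrich.nearest_rank_ci(np.arange(1, 101)[:, None], 0.95)
        assert lo[0] == 3 and hi[0] == 98

    def test_needs_two_permutations(self):
        with pytest.raises(ValueError):
            enrich.nearest_rank_ci(np.ones((1, 2)))


class TestSmoothing:
    def test_five_bin_mean(self):
        out = enrich.smooth_profile([0, 0, 10, 0, 0])
        assert out[2] == 2.0

    def test_constant_profile_unchanged(self):
        out = enrich.smooth_profile([3.0] * 9)
        np.testing.assert_allclose(out, 3.0)

    def test_edges_truncate(self):
        v = list(range(12))
        out = enrich.smooth_profile(v)
        assert out[0] == np.mean(v[:3])
        assert out[-1] == np.mean(v[-3:])

    def test_even_span_rejected_with_suggestion(self):
        with pytest.raises(ValueError, match="50000"):
            enrich.smooth_profile([1, 2, 3], smooth_span_bp=40_000)


class TestEnrichmentTable:
    def test_flags_and_ci_containment(self, rng, toy):
        assignments, pvals = toy
        pvals.iloc[:] = rng.random(len(pvals))
        obs = enrich.window_counts(assignments, pvals, alphas=(0.1,))
        perm = {0.1: rng.binomial(100, 0.1, size=(200, 22))}
        table = enrich.build_enrichment_table(obs, perm, EnrichConfig(alphas=(0.1,)))
        assert (table["ci_low"] <= table["ci_high"]).all()
        nonzero = table["n_total"] > 0
        np.testing.assert_allclose(
            table.loc[nonzero, "proportion"],
            table.loc[nonzero, "n_below"] / table.loc[nonzero, "n_total"])
        exon_row = table[table["window"].astype(str) == EXON]
        assert np.isnan(exon_row["smoothed"]).all()  # exon stratum never smoothed


class TestGeneCounts:
    def test_gene_counted_once_per_stratum(self, rng):
        rows = [("s0", "ga", 0, True, 0), ("s1", "ga", 0, False, 0),
                ("s2", "ga", 1, False, 100), ("s3", "gb", 0, False, 0)]
        assignments = make_assignments(rows)
        pvals = pd.Series([0.001, 0.002, 0.003, 0.9], index=["s0", "s1", "s2", "s3"])
        perm = rng.random((50, 4))
        table = enrich.count_suggestive_genes(assignments, pvals, perm, alphas=(0.01,))
        t = table.set_index("stratum")
        # ga has 3 suggestive SNPs but counts once; gb has none
        assert t.loc["gene_100kb", "observed"] == 1
        assert t.loc["gene_100kb", "total_genes"] == 2
        # ga's exonic SNP is suggestive -> counted in both strata
        assert t.loc["exon", "observed"] == 1
        assert t.loc["exon", "total_genes"] == 1

    def test_matches_brute_force_any(self, rng, small_annotation):
        from genewin import genemap

        genes, snps = small_annotation
        assignments = genemap.assign_all(snps, genes)
        ids = list(assignments["snp_id"])
        pvals = pd.Series(rng.random(len(ids)), index=ids)
        perm = rng.random((30, len(ids)))
        table = enrich.count_suggestive_genes(assignments, pvals, perm,
                                              alphas=(0.1,))
        merged = assignments.merge(pvals.rename("p"), left_on="snp_id",
                                   right_index=True)
        expect_gene = merged.groupby("gene_id")["p"].agg(lambda x: (x < 0.1).any()).sum()
        ex = merged[merged.in_exon]
        expect_exon = ex.groupby("gene_id")["p"].agg(lambda x: (x < 0.1).any()).sum()
        t = table.set_index("stratum")
        assert t.loc["gene_100kb", "observed"] == expect_gene
        assert t.loc["exon", "observed"] == expect_exon


class TestCombineTraits:
    def _obs(self, n_below, n_total=100):
        idx = pd.Index(enrich.window_keys(), name="window")
        df = pd.DataFrame(index=idx)
        df["n_total"] = n_total
        df["n_below_0.1"] = n_below
        return df

    def test_identical_traits_idempotent(self, rng):
        obs = self._obs(10)
        perm = {0.1: rng.binomial(100, 0.1, (100, 22))}
        combined = enrich.combine_traits([obs, obs], [perm, perm],
                                         EnrichConfig(alphas=(0.1,)))
        single = enrich.build_enrichment_table(obs, perm, EnrichConfig(alphas=(0.1,)))
        np.testing.assert_allclose(combined["proportion"], single["proportion"])
        np.testing.assert_allclose(combined["ci_low"], single["ci_low"])

    def test_mean_of_counts(self, rng):
        perm = {0.1: rng.binomial(100, 0.15, (100, 22))}
        combined = enrich.combine_traits([self._obs(10), self._obs(20)],
                                         [perm, perm], EnrichConfig(alphas=(0.1,)))
        assert np.allclose(combined["proportion"], 0.15)

    def test_mismatched_structures_rejected(self, rng):
        perm = {0.1: rng.binomial(100, 0.1, (100, 22))}
        short = self._obs(10).iloc[:-2]
        with pytest.raises(ValueError):
            enrich.combine_traits([self._obs(10), short], [perm, perm],
                                  EnrichConfig(alphas=(0.1,)))

    def test_combination_narrows_ci(self, rng):
        """Averaging independent traits reduces permutation spread in
        most windows."""
        perms = [{0.1: rng.binomial(100, 0.1, (200, 22))} for _ in range(4)]
        obs = [self._obs(int(k)) for k in rng.integers(5, 15, 4)]
        combined = enrich.combine_traits(obs, perms, EnrichConfig(alphas=(0.1,)))
        widths_combined = combined["ci_high"] - combined["ci_low"]
        single = enrich.build_enrichment_table(obs[0], perms[0],
                                               EnrichConfig(alphas=(0.1,)))
        widths_single = single["ci_high"] - single["ci_low"]
        assert (widths_combined.to_numpy() < widths_single.to_numpy()).mean() >= 0.9
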