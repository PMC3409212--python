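"""Gene-level summaries, dosage concordance and pathway enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from cnakit.dosage import (
    cis_concordance,
    gene_level_cn,
    jonckheere_terpstra,
    pathway_enrichment,
)
from cnakit.io import GeneModel, GeneSetCollection
from cnakit.genome import GenomicInterval

from conftest import make_segments


def gene(gid, chrom, start, end):
    return GeneModel(gid, gid, GenomicInterval(chrom, start, end))


class TestGeneLevelCn:
    def test_single_segment_identity(self):
        seg = make_segments([("S1", "1", 0, 1000, 10, 3.1)])
        out = gene_level_cn(seg, [gene("G1", "1", 100, 300)])
        assert out.loc["G1", "S1"] == pytest.approx(3.1)

    def test_spanning_gene_takes_unweighted_mean(self):
        seg = make_segments(
            [("S1", "1", 0, 500, 5, 2.0), ("S1", "1", 500, 1000, 5, 4.0)]
        )
        # gene covers 400 bp of the first segment, 100 of the second: the
        # stated method averages segment means without length weighting
        out = gene_level_cn(seg, [gene("G1", "1", 100, 600)])
        assert out.loc["G1", "S1"] == pytest.approx(3.0)
        weighted = gene_level_cn(seg, [gene("G1", "1", 100, 600)], weighted=True)
        assert weighted.loc["G1", "S1"] == pytest.approx((2.0 * 400 + 4.0 * 100) / 500)

    def test_uncovered_gene_is_missing(self):
        seg = make_segments([("S1", "1", 0, 1000, 10, 2.0)])
        out = gene_level_cn(seg, [gene("G1", "2", 0, 100)])
        assert np.isnan(out.loc["G1", "S1"])

    def test_segment_refinement_invariance(self):
        coarse = make_segments([("S1", "1", 0, 1000, 10, 2.7)])
        fine = make_segments(
            [("S1", "1", 0, 400, 4, 2.7), ("S1", "1", 400, 1000, 6, 2.7)]
        )
        g = [gene("G1", "1", 100, 900)]
        assert gene_level_cn(coarse, g).loc["G1", "S1"] == pytest.approx(
            gene_level_cn(fine, g).loc["G1", "S1"]
        )


class TestJonckheereTerpstra:
    def brute_force_p(self, groups, n_perm=4000, seed=0):
        """Permutation oracle for the two-sided trend p-value."""
        rng = np.random.default_rng(seed)
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]

        def j_stat(gs):
            j = 0.0
            for a in range(len(gs)):
                for b in range(a + 1, len(gs)):
                    j += np.sum(gs[b][None, :] > gs[a][:, None]) + 0.5 * np.sum(
                        gs[b][None, :] == gs[a][:, None]
                    )
            return j

        mean = (pooled.size**2 - sum(s * s for s in sizes)) / 4.0
        obs = abs(j_stat([np.asarray(g, float) for g in groups]) - mean)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            gs, k = [], 0
            for s in sizes:
                gs.append(perm[k : k + s])
                k += s
            if abs(j_stat(gs) - mean) >= obs - 1e-12:
                hits += 1
        return (hits + 1) / (n_perm + 1)

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(0, 1, 8), rng.normal(0.8, 1, 9), rng.normal(1.6, 1, 7)]
        _, _, p = jonckheere_terpstra(groups)
        p_oracle = self.brute_force_p(groups)
        assert abs(p - p_oracle) < 0.03

    def test_strong_trend_is_significant(self):
        groups = [np.arange(5), np.arange(10, 15), np.arange(20, 25)]
        _, z, p = jonckheere_terpstra(groups)
        assert z > 0
        assert p < 1e-4

    def test_needs_two_groups(self):
        with pytest.raises(ValueError, match=">= 2"):
            jonckheere_terpstra([np.arange(5)])


class TestCisConcordance:
    def test_monotone_identity_gives_unit_spearman(self):
        samples = [f"S{i}" for i in range(20)]
        cn = pd.Series(np.linspace(0.4, 5.0, 20), index=samples)
        expr = pd.Series(np.linspace(0.4, 5.0, 20), index=samples)
        r = cis_concordance("G1", cn, expr)
        assert r.spearman_rho == pytest.approx(1.0)
        assert r.testable

    def test_independent_expression_gives_small_rho(self):
        rng = np.random.default_rng(2)
        samples = [f"S{i}" for i in range(213)]
        hits = 0
        for rep in range(60):
            cn = pd.Series(rng.choice([1.0, 2.0, 3.0], 213), index=samples)
            expr = pd.Series(rng.normal(0, 1, 213), index=samples)
            r = cis_concordance("G", cn, expr)
            if abs(r.spearman_rho) < 0.2:
                hits += 1
        assert hits >= 57  # >= 95%

    def test_amplified_subset_raises_class_mean_and_trend(self):
        rng = np.random.default_rng(3)
        samples = [f"S{i}" for i in range(100)]
        cn = np.full(100, 2.0)
        cn[:15] = 6.0  # amplified subset
        expr = 0.5 * cn + rng.normal(0, 0.3, 100)
        r = cis_concordance("G", pd.Series(cn, index=samples), pd.Series(expr, index=samples))
        assert r.class_means["amplified"] > r.class_means["unchanged"]
        assert r.trend_p < 0.01

    def test_single_class_flagged_untestable(self):
        samples = [f"S{i}" for i in range(10)]
        r = cis_concordance(
            "G",
            pd.Series(np.full(10, 2.0), index=samples),
            pd.Series(np.random.default_rng(0).normal(size=10), index=samples),
        )
        assert not r.testable


class TestPathwayEnrichment:
    def _universe(self, n=1000):
        return [f"G{i:04d}" for i in range(n)]

    def test_disjoint_set_scores_null(self):
        # expected overlap well below 1, so zero overlap is unremarkable
        uni = self._universe(500)
        coll = GeneSetCollection(sets={"S": uni[100:112]})
        out = pathway_enrichment(uni[:10], coll, uni, n_perm=20, seed=0)
        row = out.iloc[0]
        assert row["overlap"] == 0
        assert row["fold_enrichment"] == 0.0
        assert row["fisher_p"] > 0.95

    def test_worked_example_fold_and_exact_p(self):
        uni = self._universe(1000)
        coll = GeneSetCollection(sets={"S": uni[:100]})
        hits = uni[:20] + uni[100:130]  # 50 hits, 20 in the set
        out = pathway_enrichment(hits, coll, uni, n_perm=20, seed=0)
        row = out.iloc[0]
        assert row["fold_enrichment"] == pytest.approx(4.0)
        # oracle: exact two-sided hypergeometric enumeration
        rv = hypergeom(1000, 100, 50)
        support = np.arange(0, 51)
        probs = rv.pmf(support)
        expected = probs[probs <= rv.pmf(20) * (1 + 1e-12)].sum()
        assert row["fisher_p"] == pytest.approx(expected, abs=1e-12)

    def test_small_sets_excluded(self):
        uni = self._universe(100)
        coll = GeneSetCollection(sets={"SMALL": uni[:9], "OK": uni[10:30]})
        out = pathway_enrichment(uni[:5], coll, uni, n_perm=10, seed=0)
        assert list(out["set_name"]) == ["OK"]

    def test_hits_outside_universe_rejected(self):
        uni = self._universe(50)
        coll = GeneSetCollection(sets={"S": uni[:20]})
        with pytest.raises(ValueError, match="not present"):
            pathway_enrichment(["NOT_A_GENE"], coll, uni, n_perm=10)

    def test_null_hits_calibrated(self):
        rng = np.random.default_rng(4)
        uni = self._universe(400)
        sets = {f"S{k}": list(rng.choice(uni, 30, replace=False)) for k in range(10)}
        coll = GeneSetCollection(sets=sets)
        sig = 0
        total = 0
        for rep in range(25):
            hits = list(rng.choice(uni, 40, replace=False))
            out = pathway_enrichment(hits, coll, uni, n_perm=5, seed=rep)
            sig += int((out["fisher_p"] < 0.05).sum())
            total += len(out)
        assert sig / total < 0.12  # around the nominal 5%
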