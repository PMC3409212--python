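"""Group comparisons, burden tests, clustering and label enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, kstest

from cnakit.compare import (
    burden_ttest,
    cluster_cohort,
    compare_frequencies,
    label_enrichment,
)


def fisher_two_sided_oracle(k_a, n_a, k_b, n_b):
    """Exact two-sided Fisher p by hypergeometric enumeration."""
    total_k = k_a + k_b
    n = n_a + n_b
    rv = hypergeom(n, total_k, n_a)
    support = np.arange(max(0, total_k - n_b), min(n_a, total_k) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(k_a)
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


class TestCompareFrequencies:
    def _grid(self, m):
        return np.full(m, "1", dtype=object), np.arange(m) * 100

    def test_identical_groups_never_significant(self):
        codes = np.zeros((10, 20), dtype=np.int8)
        codes[:4, 5:10] = -1
        chroms, pos = self._grid(20)
        out = compare_frequencies(codes, codes.copy(), chroms, pos, "loss")
        assert not out["significant"].any()

    def test_fisher_p_matches_hypergeometric_oracle(self):
        # the worked two-group table: 8/33 carriers vs 19/269
        codes_a = np.zeros((33, 1), dtype=np.int8)
        codes_a[:8, 0] = -1
        codes_b = np.zeros((269, 1), dtype=np.int8)
        codes_b[:19, 0] = -1
        chroms, pos = self._grid(1)
        out = compare_frequencies(codes_a, codes_b, chroms, pos, "loss")
        expected = fisher_two_sided_oracle(8, 33, 19, 269)
        assert out["fisher_p"].iloc[0] == pytest.approx(expected, abs=1e-12)
        assert out["diff_points"].iloc[0] == pytest.approx(24.24 - 7.06, abs=0.1)
        assert bool(out["significant"].iloc[0]) == (expected < 0.01)

    def test_oracle_agreement_on_table_grid(self):
        chroms, pos = self._grid(1)
        for n_a, n_b in [(10, 15), (30, 25), (150, 150)]:
            for k_a in range(0, n_a + 1, max(1, n_a // 4)):
                for k_b in range(0, n_b + 1, max(1, n_b // 4)):
                    ca = np.zeros((n_a, 1), dtype=np.int8)
                    ca[:k_a, 0] = 1
                    cb = np.zeros((n_b, 1), dtype=np.int8)
                    cb[:k_b, 0] = 1
                    out = compare_frequencies(ca, cb, chroms, pos, "gain")
                    assert out["fisher_p"].iloc[0] == pytest.approx(
                        fisher_two_sided_oracle(k_a, n_a, k_b, n_b), abs=1e-12
                    )

    def test_rules_are_independently_toggleable(self):
        # large difference but tiny cohort: passes the 15-point rule only
        ca = np.zeros((4, 1), dtype=np.int8)
        ca[:3, 0] = 1
        cb = np.zeros((4, 1), dtype=np.int8)
        chroms, pos = self._grid(1)
        strict = compare_frequencies(ca, cb, chroms, pos, "gain")
        assert not strict["significant"].iloc[0]  # Fisher p too large at n=4
        lax = compare_frequencies(
            ca, cb, chroms, pos, "gain", p_threshold=1.0
        )
        assert lax["significant"].iloc[0]  # with the p-rule disabled
        no_diff_rule = compare_frequencies(
            ca, cb, chroms, pos, "gain", diff_threshold=200.0, p_threshold=1.0
        )
        assert not no_diff_rule["significant"].iloc[0]

    def test_empty_group_rejected(self):
        chroms, pos = self._grid(1)
        with pytest.raises(ValueError, match="non-empty"):
            compare_frequencies(
                np.zeros((0, 1), dtype=np.int8),
                np.zeros((3, 1), dtype=np.int8),
                chroms,
                pos,
            )


class TestBurden:
    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(500):
            a = rng.normal(10, 3, 40)
            b = rng.normal(10, 3, 40)
            ps.append(burden_ttest(a, b)[1])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_separated_group_moments_detected(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(100):
            a = rng.normal(33.2, 17.6, 269)
            b = rng.normal(10.2, 6.5, 33)
            if burden_ttest(a, b)[1] < 0.01:
                hits += 1
        assert hits >= 95

    def test_equal_constant_groups_give_zero_statistic(self):
        t, p, _, _ = burden_ttest([5, 5, 5], [5, 5, 5])
        assert t == 0.0
        assert p == 1.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            burden_ttest([1], [2, 3])


class TestClustering:
    def _planted(self):
        rng = np.random.default_rng(2)
        genes = [f"G{i}" for i in range(30)]
        cols, truth = {}, {}
        for s in range(24):
            profile = np.full(30, 2.0)
            if s < 8:
                profile[:10] = 4.0  # amplified block
                truth[f"S{s:02d}"] = 0
            elif s < 16:
                truth[f"S{s:02d}"] = 1  # quiet
            else:
                profile[10:25] = 1.0  # deleted pattern
                truth[f"S{s:02d}"] = 2
            cols[f"S{s:02d}"] = profile + rng.normal(0, 0.05, 30)
        return pd.DataFrame(cols, index=genes), truth

    def test_planted_clusters_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        gene_cn, truth = self._planted()
        labels = cluster_cohort(gene_cn, k=3)
        ari = adjusted_rand_score(
            [truth[s] for s in labels.index], labels.to_numpy()
        )
        assert ari == pytest.approx(1.0)

    def test_sample_order_invariance(self):
        gene_cn, _ = self._planted()
        shuffled = gene_cn[list(gene_cn.columns[::-1])]
        a = cluster_cohort(gene_cn, k=3)
        b = cluster_cohort(shuffled, k=3)
        pd.testing.assert_series_equal(a, b)

    def test_sex_chromosome_genes_rejected(self):
        gene_cn, _ = self._planted()
        chrom_of = {g: "1" for g in gene_cn.index}
        chrom_of["G5"] = "X"
        with pytest.raises(ValueError, match="sex-chromosome"):
            cluster_cohort(gene_cn, k=3, gene_chromosomes=chrom_of)

    def test_k_equal_n_gives_singletons(self):
        gene_cn, _ = self._planted()
        sub = gene_cn.iloc[:, :5]
        labels = cluster_cohort(sub, k=5)
        assert labels.nunique() == 5

    def test_k_larger_than_n_rejected(self):
        gene_cn, _ = self._planted()
        with pytest.raises(ValueError, match="exceeds"):
            cluster_cohort(gene_cn.iloc[:, :3], k=5)


class TestLabelEnrichment:
    def test_pure_cluster_matches_hypergeometric_point_mass(self):
        assignment = pd.Series([1] * 5 + [2] * 10, index=[f"S{i}" for i in range(15)])
        labels = pd.Series(
            ["pos"] * 5 + ["neg"] * 10, index=[f"S{i}" for i in range(15)]
        )
        out = label_enrichment(assignment, labels)
        row = out[(out["cluster"] == 1) & (out["label"] == "pos")].iloc[0]
        expected = fisher_two_sided_oracle(5, 5, 0, 10)
        assert row["fisher_p"] == pytest.approx(expected, abs=1e-12)

    def test_independent_labels_rarely_significant(self):
        rng = np.random.default_rng(3)
        min_ps = []
        for _ in range(30):
            assignment = pd.Series(
                rng.integers(1, 4, 200), index=[f"S{i}" for i in range(200)]
            )
            labels = pd.Series(
                rng.choice(["a", "b"], 200), index=assignment.index
            )
            out = label_enrichment(assignment, labels)
            min_ps.append(out["fisher_p"].min())
        # with 6 tests per rep, a min-p below 1e-4 should be very rare
        assert np.mean(np.array(min_ps) < 1e-4) < 0.1

    def test_single_level_label_warns_and_returns_empty(self):
        assignment = pd.Series([1, 1, 2], index=["a", "b", "c"])
        labels = pd.Series(["x", "x", "x"], index=["a", "b", "c"])
        with pytest.warns(UserWarning, match="fewer than two"):
            out = label_enrichment(assignment, labels)
        assert out.empty

    def test_missing_labels_excluded_pairwise(self):
        assignment = pd.Series([1, 1, 2, 2], index=list("abcd"))
        labels = pd.Series(["x", None, "y", "y"], index=list("abcd"))
        out = label_enrichment(assignment, labels)
        assert (out["cluster_size"] <= 2).all()
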