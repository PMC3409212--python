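"""Gene-level copy-number summaries, cis dosage-expression concordance and
pathway enrichment with a permutation FDR.

Gene-level copy number is the unweighted mean of the mean copy numbers of all
segments overlapping the gene body (a length-weighted variant is available).
Concordance of a gene's mRNA with its own copy number is assessed two ways:
a Jonckheere-Terpstra trend test across the ordered aberration classes
(homozygous deletion < deletion < unchanged < gain < amplification) and the
Spearman correlation between numeric copy number and expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calling import BinThresholds, DEFAULT_BINS, CLASS_NAMES

__all__ = [
    "gene_level_cn",
    "cis_concordance",
    "jonckheere_terpstra",
    "pathway_enrichment",
    "ConcordanceResult",
]


def gene_level_cn(
    segments: pd.DataFrame, gene_models: list, weighted: bool = False
) -> pd.DataFrame:
    """Genes × samples copy-number matrix from cohort segmentations.

    A gene overlapping several segments takes the unweighted mean of their
    mean copy numbers (``weighted=True`` weights by overlap length).  Genes
    with no covering segment are missing (NaN).
    """
    samples = sorted(segments["sample"].unique())
    gene_ids = [g.gene_id for g in gene_models]
    out = np.full((len(gene_ids), len(samples)), np.nan)

    genes_by_chrom: dict = {}
    for gi, g in enumerate(gene_models):
        genes_by_chrom.setdefault(g.interval.chromosome, []).append(gi)

    for si, (_, gseg) in enumerate(segments.groupby("sample", sort=True)):
        for chrom, cseg in gseg.groupby("chrom", sort=False):
            gidx = genes_by_chrom.get(chrom)
            if not gidx:
                continue
            cseg = cseg.sort_values("start")
            seg_start = cseg["start"].to_numpy()
            seg_end = cseg["end"].to_numpy()
            seg_cn = cseg["mean_cn"].to_numpy()
            for gi in gidx:
                iv = gene_models[gi].interval
                lo = np.searchsorted(seg_end, iv.start, side="right")
                hi = np.searchsorted(seg_start, iv.end, side="left")
                if hi <= lo:
                    continue
                if weighted:
                    ov = np.minimum(seg_end[lo:hi], iv.end) - np.maximum(
                        seg_start[lo:hi], iv.start
                    )
                    out[gi, si] = np.average(seg_cn[lo:hi], weights=ov)
                else:
                    out[gi, si] = seg_cn[lo:hi].mean()
    return pd.DataFrame(out, index=gene_ids, columns=samples)


def jonckheere_terpstra(groups: list):
    """Jonckheere-Terpstra test for an ordered trend across k groups.

    ``groups`` is a list of 1-D arrays in the hypothesized increasing order.
    Returns ``(J, z, p)`` with a two-sided normal-approximation p-value
    (ties counted half in J; variance uses the no-ties formula, adequate for
    continuous expression values).
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty groups")
    j_stat = 0.0
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            x, y = groups[a], groups[b]
            j_stat += np.sum(y[None, :] > x[:, None]) + 0.5 * np.sum(
                y[None, :] == x[:, None]
            )
    sizes = np.array([len(g) for g in groups])
    n = sizes.sum()
    mean = (n * n - np.sum(sizes**2)) / 4.0
    var = (n * n * (2 * n + 3) - np.sum(sizes**2 * (2 * sizes + 3))) / 72.0
    if var <= 0:
        return float(j_stat), 0.0, 1.0
    z = (j_stat - mean) / np.sqrt(var)
    return float(j_stat), float(z), float(2 * stats.norm.sf(abs(z)))


@dataclass
class ConcordanceResult:
    gene_id: str
    class_means: dict  # class name -> mean centered expression
    class_counts: dict
    trend_stat: float
    trend_p: float
    spearman_rho: float
    spearman_p: float
    testable: bool


def cis_concordance(
    gene_id: str,
    cn_row: pd.Series,
    expr_row: pd.Series,
    thresholds: BinThresholds = DEFAULT_BINS,
    min_per_class: int = 2,
) -> ConcordanceResult:
    """Concordance of one gene's expression with its own copy number.

    Expression is centered (per probeset) before summarizing by class.  The
    result is flagged untestable when fewer than two aberration classes have
    at least ``min_per_class`` samples.
    """
    common = cn_row.dropna().index.intersection(expr_row.dropna().index)
    cn = cn_row[common].to_numpy(dtype=float)
    expr = expr_row[common].to_numpy(dtype=float)
    expr = expr - expr.mean()
    codes = thresholds.codes(cn)
    class_means, class_counts, ordered_groups = {}, {}, []
    for code in (-2, -1, 0, 1, 2):
        vals = expr[codes == code]
        if vals.size:
            class_means[CLASS_NAMES[code]] = float(vals.mean())
            class_counts[CLASS_NAMES[code]] = int(vals.size)
        if vals.size >= min_per_class:
            ordered_groups.append(vals)
    testable = len(ordered_groups) >= 2
    if testable:
        j, _, trend_p = jonckheere_terpstra(ordered_groups)
        rho, rho_p = stats.spearmanr(cn, expr)
    else:
        j, trend_p, rho, rho_p = float("nan"), float("nan"), float("nan"), float("nan")
    return ConcordanceResult(
        gene_id, class_means, class_counts, j, trend_p, float(rho), float(rho_p), testable
    )


def concordance_table(results: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "testable": r.testable,
                "trend_p": r.trend_p,
                "spearman_rho": r.spearman_rho,
                "spearman_p": r.spearman_p,
                **{f"mean_{k}": v for k, v in r.class_means.items()},
            }
            for r in results
        ]
    )


def pathway_enrichment(
    hits: list,
    gene_sets,
    universe: list,
    n_perm: int = 100,
    size_bounds: tuple = (10, 500),
    seed: int = 0,
) -> pd.DataFrame:
    """Over-representation of ``hits`` in each gene set, with permutation FDR.

    Per set: overlap k, two-sided Fisher exact p on the (hit × in-set) 2x2
    table, and fold enrichment (k/|hits|) / (|set ∩ universe|/|universe|).
    The FDR per set is estimated from ``n_perm`` permutations in which every
    set is replaced by a random draw of the same size from the universe:
    FDR(s) = mean permutation count of sets with p' <= p(s), divided by the
    observed count of sets with p <= p(s).
    """
    universe = list(dict.fromkeys(universe))
    uni_set = set(universe)
    offenders = [h for h in hits if h not in uni_set]
    if offenders:
        raise ValueError(f"hits not present in the universe: {offenders[:10]}")
    hits_set = set(hits)
    n_uni, n_hits = len(universe), len(hits_set)
    filtered = gene_sets.filter_by_size(*size_bounds, universe=universe)

    def fisher_p(k, set_size):
        table = [
            [k, n_hits - k],
            [set_size - k, n_uni - n_hits - set_size + k],
        ]
        return stats.fisher_exact(table, alternative="two-sided")[1]

    names, sizes, overlaps, pvals, folds = [], [], [], [], []
    for name, members in filtered:
        mset = set(members)
        k = len(mset & hits_set)
        size = len(mset)
        names.append(name)
        sizes.append(size)
        overlaps.append(k)
        pvals.append(fisher_p(k, size))
        folds.append((k / n_hits) / (size / n_uni) if n_hits and size else 0.0)
    pvals = np.array(pvals)

    rng = np.random.default_rng(seed)
    uni_arr = np.array(universe, dtype=object)
    null_ps = np.empty((n_perm, len(names)))
    for b in range(n_perm):
        for s, size in enumerate(sizes):
            draw = set(rng.choice(uni_arr, size=size, replace=False))
            null_ps[b, s] = fisher_p(len(draw & hits_set), size)
    fdr = np.ones(len(names))
    for s, p in enumerate(pvals):
        observed = np.sum(pvals <= p)
        expected = (null_ps <= p).sum(axis=1).mean()
        fdr[s] = min(1.0, expected / observed) if observed else 1.0
    out = pd.DataFrame(
        {
            "set_name": names,
            "set_size": sizes,
            "overlap": overlaps,
            "fold_enrichment": folds,
            "fisher_p": pvals,
            "perm_fdr": fdr,
        }
    )
    return out.sort_values("fisher_p").reset_index(drop=True)
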