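"""Group frequency comparisons, burden tests, clustering and label enrichment.

A marker is differentially aberrant between two groups when both of two
independent rules hold: the carrier-frequency difference exceeds 15
percentage points and a two-sided Fisher exact test on the 2x2 carrier table
gives p < 0.01.  Both rules are exposed separately; a Benjamini-Hochberg
column is emitted alongside the unadjusted p for transparency, but the
significance flag follows the unadjusted rule pair.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .genome import SEX_CHROMOSOMES

__all__ = [
    "compare_frequencies",
    "merge_flagged_markers",
    "burden_ttest",
    "cluster_cohort",
    "label_enrichment",
]


def compare_frequencies(
    codes_a: np.ndarray,
    codes_b: np.ndarray,
    marker_chroms: np.ndarray,
    marker_positions: np.ndarray,
    direction: str = "loss",
    diff_threshold: float = 15.0,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-marker two-group carrier comparison.

    ``codes_a``/``codes_b`` are (samples × markers) class-code matrices for
    the two groups; ``direction`` is 'gain' or 'loss'.  ``diff_threshold`` is
    in percentage points.
    """
    if codes_a.shape[0] == 0 or codes_b.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    sign = {"gain": 1, "loss": -1}[direction]
    n_a, n_b = codes_a.shape[0], codes_b.shape[0]
    k_a = (np.sign(codes_a) == sign).sum(axis=0)
    k_b = (np.sign(codes_b) == sign).sum(axis=0)
    freq_a, freq_b = k_a / n_a, k_b / n_b
    diff = (freq_a - freq_b) * 100.0
    pvals = np.ones(k_a.size)
    cache: dict = {}
    # Fisher p is needed only where the table is non-degenerate; identical
    # tables share one exact computation.
    for m in range(k_a.size):
        key = (int(k_a[m]), int(k_b[m]))
        if key not in cache:
            table = [[key[0], n_a - key[0]], [key[1], n_b - key[1]]]
            cache[key] = stats.fisher_exact(table, alternative="two-sided")[1]
        pvals[m] = cache[key]
    out = pd.DataFrame(
        {
            "chrom": np.asarray(marker_chroms, dtype=object),
            "pos": np.asarray(marker_positions, dtype=np.int64),
            "direction": direction,
            "freq_a": freq_a,
            "freq_b": freq_b,
            "diff_points": diff,
            "fisher_p": pvals,
        }
    )
    out["fisher_p_bh"] = multipletests(pvals, method="fdr_bh")[1]
    out["significant"] = (np.abs(diff) > diff_threshold) & (pvals < p_threshold)
    return out


def merge_flagged_markers(comparison: pd.DataFrame) -> pd.DataFrame:
    """Merge runs of adjacent significant markers into regions."""
    rows = []
    for chrom, g in comparison.groupby("chrom", sort=False):
        g = g.sort_values("pos").reset_index(drop=True)
        sig = g["significant"].to_numpy()
        if not sig.any():
            continue
        idx = np.flatnonzero(sig)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        for block in np.split(idx, breaks + 1):
            sub = g.iloc[block]
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(sub["pos"].iloc[0]),
                    "end": int(sub["pos"].iloc[-1]) + 1,
                    "direction": sub["direction"].iloc[0],
                    "n_markers": len(sub),
                    "max_diff_points": float(
                        sub["diff_points"].abs().max()
                        * np.sign(sub["diff_points"].iloc[0])
                    ),
                    "min_fisher_p": float(sub["fisher_p"].min()),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "direction",
            "n_markers",
            "max_diff_points",
            "min_fisher_p",
        ],
    )


def burden_ttest(counts_a, counts_b):
    """Welch two-sample t-test on per-tumor event counts.

    Returns ``(t, p, (mean_a, sd_a), (mean_b, sd_b))``.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 samples for a t-test")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # degenerate constant groups: no variance, no evidence either way
        t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return (
        float(t),
        float(p),
        (float(a.mean()), float(a.std(ddof=1))),
        (float(b.mean()), float(b.std(ddof=1))),
    )


def cluster_cohort(
    gene_cn: pd.DataFrame,
    k: int = 3,
    gene_chromosomes: dict | None = None,
    metric: str = "euclidean",
) -> pd.Series:
    """Complete-linkage hierarchical clustering of samples on gene-level CN.

    ``gene_cn`` is genes × samples.  Sex-chromosome genes must be excluded
    upstream; passing ``gene_chromosomes`` (gene_id -> chromosome) enforces
    this.  ``metric`` is 'euclidean' or 'correlation' (1 - Pearson).
    """
    if gene_chromosomes is not None:
        sexy = [
            g
            for g in gene_cn.index
            if gene_chromosomes.get(g) in SEX_CHROMOSOMES
        ]
        if sexy:
            raise ValueError(
                f"sex-chromosome genes must be excluded before clustering: {sexy[:5]}"
            )
    n = gene_cn.shape[1]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    # sample-order invariance: cluster on id-sorted columns
    cols = sorted(gene_cn.columns)
    x = gene_cn[cols].T.to_numpy()
    z = linkage(pdist(x, metric=metric), method="complete")
    labels = fcluster(z, t=k, criterion="maxclust")
    return pd.Series(labels, index=cols, name="cluster")


def label_enrichment(assignment: pd.Series, labels: pd.Series) -> pd.DataFrame:
    """Fisher tests of label-level membership inside each cluster vs the rest.

    Missing labels are excluded pairwise.  A label column with a single level
    is skipped with a warning.
    """
    joined = pd.DataFrame({"cluster": assignment, "label": labels}).dropna()
    levels = joined["label"].unique()
    if joined.empty or len(levels) < 2:
        warnings.warn("label has fewer than two observed levels; nothing to test")
        return pd.DataFrame(
            columns=["cluster", "label", "in_cluster", "cluster_size", "fisher_p"]
        )
    rows = []
    for cl in sorted(joined["cluster"].unique()):
        in_cl = joined["cluster"] == cl
        for lv in sorted(levels):
            has = joined["label"] == lv
            table = [
                [int((in_cl & has).sum()), int((in_cl & ~has).sum())],
                [int((~in_cl & has).sum()), int((~in_cl & ~has).sum())],
            ]
            p = stats.fisher_exact(table, alternative="two-sided")[1]
            rows.append(
                {
                    "cluster": cl,
                    "label": lv,
                    "in_cluster": table[0][0],
                    "cluster_size": int(in_cl.sum()),
                    "fisher_p": float(p),
                }
            )
    return pd.DataFrame(rows)
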