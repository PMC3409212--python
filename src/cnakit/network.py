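"""Gene-gene copy-number correlation networks and their randomization null.

Physically linked genes (same chromosome) are trivially correlated through
shared segments; the interesting signal is correlation between unlinked loci,
which indicates co-selection.  The randomization null therefore shuffles
sample labels independently per chromosome: within-chromosome correlations
are left exactly invariant while any cross-chromosome structure is destroyed.
The observed inter-chromosome degree distribution is compared with the null
by a two-sample Kolmogorov-Smirnov statistic, and the hub structure is
summarized by the log-log slope of the degree histogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "pairwise_correlations",
    "edge_graph",
    "degree_distribution",
    "randomization_null",
    "DegreeDistribution",
]


def pairwise_correlations(gene_cn: pd.DataFrame, min_obs: int = 3) -> pd.DataFrame:
    """Pearson correlation between all gene pairs (genes × genes).

    Missing cells are excluded pairwise; a pair with fewer than ``min_obs``
    complete observations, or a constant gene, yields NaN.
    """
    if gene_cn.shape[1] < 3:
        raise ValueError("need >= 3 samples for pairwise correlations")
    corr = gene_cn.T.corr(method="pearson", min_periods=min_obs)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def edge_graph(
    corr: pd.DataFrame,
    gene_chromosomes: dict,
    r_threshold: float = 0.3,
    unlinked_only: bool = False,
) -> nx.Graph:
    """Graph of gene pairs with |r| >= threshold.

    ``unlinked_only`` keeps only inter-chromosome (unlinked) edges.
    """
    genes = list(corr.index)
    g = nx.Graph()
    g.add_nodes_from(genes)
    r = corr.to_numpy()
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    vals = r[iu, ju]
    keep = np.abs(vals) >= r_threshold
    keep &= np.isfinite(vals)
    for a, b, v in zip(iu[keep], ju[keep], vals[keep]):
        ga, gb = genes[a], genes[b]
        if unlinked_only and gene_chromosomes[ga] == gene_chromosomes[gb]:
            continue
        g.add_edge(ga, gb, r=float(v))
    return g


@dataclass
class DegreeDistribution:
    degrees: pd.Series  # per gene
    bin_centers: np.ndarray
    bin_counts: np.ndarray
    loglog_slope: float


def degree_distribution(graph: nx.Graph) -> DegreeDistribution:
    """Degree histogram and OLS log-log slope over nonzero-count bins."""
    deg = pd.Series(dict(graph.degree()), name="degree").sort_index()
    positive = deg[deg > 0]
    if positive.empty:
        return DegreeDistribution(deg, np.array([]), np.array([]), float("nan"))
    values, counts = np.unique(positive.to_numpy(), return_counts=True)
    if values.size >= 2:
        slope = float(
            np.polyfit(np.log(values.astype(float)), np.log(counts.astype(float)), 1)[0]
        )
    else:
        slope = float("nan")
    return DegreeDistribution(deg, values.astype(float), counts, slope)


def randomization_null(
    gene_cn: pd.DataFrame,
    gene_chromosomes: dict,
    n_perm: int = 20,
    r_threshold: float = 0.3,
    seed: int = 0,
):
    """Null degree distributions under per-chromosome sample-label shuffling.

    Returns ``(null_degrees, ks_stat, ks_p)`` where ``null_degrees`` is a
    list of per-permutation degree arrays for the inter-chromosome edge graph
    and the KS statistic compares the observed inter-chromosome degrees
    against the pooled null.
    """
    if n_perm < 10:
        warnings.warn(f"randomization null with n_perm={n_perm} < 10 is coarse")
    chroms = np.array([gene_chromosomes[g] for g in gene_cn.index], dtype=object)
    if len(set(chroms)) < 2:
        warnings.warn("single-chromosome matrix: no inter-chromosome pairs to test")
        empty = np.zeros(gene_cn.shape[0])
        return [empty] * n_perm, float("nan"), float("nan")

    corr_obs = pairwise_correlations(gene_cn)
    g_obs = edge_graph(corr_obs, gene_chromosomes, r_threshold, unlinked_only=True)
    obs_deg = np.array([d for _, d in g_obs.degree()], dtype=float)

    rng = np.random.default_rng(seed)
    x = gene_cn.to_numpy()
    n_samples = x.shape[1]
    null_degrees = []
    for _ in range(n_perm):
        xp = x.copy()
        for c in pd.unique(chroms):
            rows = np.flatnonzero(chroms == c)
            xp[rows] = xp[np.ix_(rows, rng.permutation(n_samples))]
        perm_df = pd.DataFrame(xp, index=gene_cn.index, columns=gene_cn.columns)
        corr_p = pairwise_correlations(perm_df)
        g_p = edge_graph(corr_p, gene_chromosomes, r_threshold, unlinked_only=True)
        null_degrees.append(np.array([d for _, d in g_p.degree()], dtype=float))
    pooled = np.concatenate(null_degrees)
    ks_stat, ks_p = stats.ks_2samp(obs_deg, pooled)
    return null_degrees, float(ks_stat), float(ks_p)
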