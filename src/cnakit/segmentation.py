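"""Circular binary segmentation of per-probe copy-number profiles.

Each chromosome is partitioned recursively: at every step the circular
two-sample statistic is maximized over all arcs (i, j] of the current
interval, comparing probes inside the arc against the rest.  A split is
accepted when its p-value falls at or below ``alpha``; accepted arcs cut the
interval into up to three pieces which are segmented recursively.  Adjacent
segments whose means differ by less than ``merge_tol`` copies are merged
afterwards.

An optional rank transform of probe values within the current interval is
available (``rank=True``) for heavy-tailed outliers; it is off by default
because ranking equalizes the within-level spread when one copy-number level
dominates a chromosome, which blunts sensitivity to short events at very
small alpha.  Segment means are always computed on the raw copy-number
scale.

P-values use a hybrid rule.  A Bonferroni bound over all candidate arcs on
the Gaussian tail of the max statistic is computed first: if the bound is
already <= alpha the split is accepted, and when alpha is below the
resolution a permutation test could ever reach (alpha < 1/(n_perm+1), as with
the default alpha = 1e-6) the bound alone decides.  Otherwise a permutation
test (values permuted within the interval, early stopping) supplies the
p-value.  The bound is conservative, so a split it accepts would also be
accepted by an exhaustive permutation test.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import erfc

_SQRT2 = math.sqrt(2.0)

from .io import ProbeProfile

__all__ = ["cbs_segment", "segment_cohort", "max_arc_statistic"]

SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "n_probes", "mean_cn"]


def _robust_sigma(x: np.ndarray) -> float:
    """Probe-noise scale from consecutive differences.

    For i.i.d. Gaussian noise, |x[i+1]-x[i]| has median sigma*sqrt(2)*0.6745;
    true copy-number steps contribute only a handful of differences and are
    ignored by the median, so the estimate is not inflated by the change
    points the statistic is trying to find.
    """
    d = np.abs(np.diff(x))
    # lower-quartile estimator: for Gaussian noise |d| ~ HalfNormal(sigma*sqrt2)
    # whose 0.25 quantile is 0.45049*sigma; tolerates up to 75% of the
    # differences being true steps (heavily rearranged genomes)
    kth = (d.size - 1) // 4
    part = np.partition(d, kth)
    q25 = float(part[kth]) / 0.45049
    # the quartile estimator can collapse on short intervals (order statistics
    # of a handful of differences); half the median-based estimate floors it
    med = float(np.median(d)) / 0.95387
    sigma = max(q25, 0.5 * med)
    if sigma > 0:
        return sigma
    # noiseless or near-noiseless data: fall back to a fraction of the spread
    return max(1e-3 * float(np.std(x)), 1e-12 if np.ptp(x) > 0 else 0.0)


try:  # JIT arc search; the numpy path below is the reference implementation
    from numba import njit as _njit

    @_njit(cache=False)
    def _arc_search(s, n, fac):  # pragma: no cover - exercised via wrapper
        total = s[n]
        best = -1.0
        bi, bj = 0, n
        for i in range(n):
            si = s[i]
            for j in range(i + 1, n + 1):
                k = j - i
                if k == n:
                    continue
                arc = s[j] - si
                t = arc / k - (total - arc) / (n - k)
                if t < 0:
                    t = -t
                t *= fac[k]
                if t > best:
                    best = t
                    bi, bj = i, j
        return best, bi, bj

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _arc_search_numpy(s, n, fac):
    i_idx = np.arange(n + 1)
    arc = s[None, :] - s[:, None]  # arc sums S[j]-S[i]
    k = i_idx[None, :] - i_idx[:, None]
    valid = (k >= 1) & (k <= n - 1)
    total = s[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(arc / k - (total - arc) / (n - k)) * fac[np.clip(k, 1, n - 1)]
    t[~valid] = -np.inf
    flat = int(np.argmax(t))
    i, j = divmod(flat, n + 1)
    return float(t[i, j]), int(i), int(j)


def max_arc_statistic(x: np.ndarray):
    """Maximal circular two-sample statistic over all arcs of ``x``.

    Returns ``(t_max, i, j)`` where the best arc is ``x[i:j]`` compared
    against the complement.  The statistic is the absolute standardized mean
    difference scaled by a robust consecutive-difference noise estimate.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        return 0.0, 0, n
    sigma = _robust_sigma(x)
    if sigma == 0:
        return 0.0, 0, n
    s = np.concatenate([[0.0], np.cumsum(x)])
    k = np.arange(1, n)
    fac = np.empty(n)
    fac[0] = 0.0
    fac[1:] = 1.0 / (sigma * np.sqrt(1.0 / k + 1.0 / (n - k)))
    if _HAVE_NUMBA:
        t, i, j = _arc_search(s, n, fac)
        return float(t), int(i), int(j)
    return _arc_search_numpy(s, n, fac)


def _split_p_value(x, t_max, alpha, n_perm, rng):
    """Hybrid p-value for the best split of interval ``x``."""
    n = x.size
    n_pairs = n * (n - 1) / 2.0
    # sf of the standard normal via erfc: cheap and accurate far in the tail
    p_bonf = min(1.0, n_pairs * erfc(t_max / _SQRT2))
    if p_bonf <= alpha:
        return p_bonf
    if alpha < 1.0 / (n_perm + 1):
        return p_bonf  # permutations cannot resolve below their granularity
    if p_bonf > max(0.2, 50 * alpha):
        return p_bonf
    # permutation with early stopping: once the exceedance count rules out
    # p <= alpha, further permutations cannot change the decision
    limit = int(np.floor(alpha * (n_perm + 1))) - 1
    exceed = 0
    for b in range(n_perm):
        t_b, _, _ = max_arc_statistic(rng.permutation(x))
        if t_b >= t_max:
            exceed += 1
            if exceed > limit:
                break
    return (1.0 + exceed) / (n_perm + 1.0)


def _segment_chromosome(values, alpha, n_perm, min_probes, rank, rng):
    """Recursive CBS on one chromosome; returns list of (lo, hi) probe slices."""
    n = values.size
    out = []
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        seg = values[lo:hi]
        if hi - lo < max(2 * min_probes, 4):
            out.append((lo, hi))
            continue
        x = stats.rankdata(seg) if rank else seg
        t_max, i, j = max_arc_statistic(x)
        if t_max <= 0:
            out.append((lo, hi))
            continue
        p = _split_p_value(x, t_max, alpha, n_perm, rng)
        if p > alpha:
            out.append((lo, hi))
            continue
        cuts = [c for c in (i, j) if 0 < c < hi - lo]
        edges = [0] + cuts + [hi - lo]
        for a, b in zip(edges[:-1], edges[1:]):
            stack.append((lo + a, lo + b))
    return sorted(out)


def _merge_segments(pieces, values, merge_tol):
    """Merge adjacent pieces whose raw means differ by < merge_tol copies."""
    pieces = list(pieces)
    means = [values[a:b].mean() for a, b in pieces]
    merged = True
    while merged and len(pieces) > 1:
        merged = False
        diffs = [abs(means[k + 1] - means[k]) for k in range(len(pieces) - 1)]
        k = int(np.argmin(diffs))
        if diffs[k] < merge_tol:
            a, _ = pieces[k]
            _, b = pieces[k + 1]
            pieces[k : k + 2] = [(a, b)]
            means[k : k + 2] = [values[a:b].mean()]
            merged = True
    return pieces, means


def cbs_segment(
    profile: ProbeProfile,
    alpha: float = 1e-6,
    n_perm: int = 10_000,
    min_probes: int = 3,
    merge_tol: float = 0.3,
    rank: bool = False,
    genome=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Segment one centered profile into piecewise-constant copy-number runs.

    Returns a segment table (columns ``sample, chrom, start, end, n_probes,
    mean_cn``) whose segments tile each chromosome.  Segment boundaries fall
    midway between flanking probes; chromosome ends come from ``genome`` when
    given, otherwise from the probe span padded by the median probe spacing.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    col_chrom, col_start, col_end, col_np, col_cn = [], [], [], [], []
    for chrom, idx in profile.chromosome_index().items():
        vals = profile.values[idx]
        pos = profile.starts[idx]
        if vals.size < min_probes:
            pieces = [(0, vals.size)]
        else:
            pieces = _segment_chromosome(vals, alpha, n_perm, min_probes, rank, rng)
        pieces, means = _merge_segments(pieces, vals, merge_tol)
        spacing = int(np.median(np.diff(pos))) if pos.size > 1 else 1
        if genome is not None:
            chrom_start, chrom_end = 0, genome.lengths[chrom]
        else:
            chrom_start, chrom_end = int(pos[0]), int(pos[-1]) + spacing
        for (a, b), m in zip(pieces, means):
            col_chrom.append(chrom)
            col_start.append(
                chrom_start if a == 0 else int((pos[a - 1] + pos[a]) // 2)
            )
            col_end.append(
                chrom_end if b == vals.size else int((pos[b - 1] + pos[b]) // 2)
            )
            col_np.append(b - a)
            col_cn.append(float(m))
    return pd.DataFrame(
        {
            "sample": profile.sample_id,
            "chrom": np.array(col_chrom, dtype=object),
            "start": np.array(col_start, dtype=np.int64),
            "end": np.array(col_end, dtype=np.int64),
            "n_probes": np.array(col_np, dtype=np.int64),
            "mean_cn": np.array(col_cn, dtype=float),
        }
    )


def segment_cohort(profiles, progress: bool = False, **kwargs) -> pd.DataFrame:
    """Segment every profile; one concatenated segment table."""
    tables = []
    for k, p in enumerate(profiles):
        kw = dict(kwargs)
        kw["seed"] = kwargs.get("seed", 0) + k
        tables.append(cbs_segment(p, **kw))
    return pd.concat(tables, ignore_index=True)
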