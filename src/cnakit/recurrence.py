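"""Minimal common regions of recurrent aberration and STAC-style significance.

An MCR is found per direction as the plateau of a frequency-track run: within
each maximal run of markers at or above ``min_freq``, the peak marker's
carrier set is extended left and right for as long as every carrier stays
aberrant, giving the minimal region shared by the largest set of overlapping
events.

Significance follows the permutation logic of interval-placement testing:
each sample's directed aberration intervals are re-placed uniformly at random
along the chromosome (lengths preserved, no wrap-around), and a region's
p-value is the fraction of permuted cohorts whose maximum marker frequency
anywhere on the chromosome reaches the observed peak — a max-statistic
correction over the chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomicInterval

__all__ = ["RecurrentRegion", "find_mcrs", "stac_null_max", "stac_test", "mcr_table"]


@dataclass
class RecurrentRegion:
    interval: GenomicInterval
    direction: str  # 'gain' or 'loss'
    peak_frequency: float
    member_samples: list = field(default_factory=list)
    stac_p: float = float("nan")

    @property
    def n_carriers(self) -> int:
        return len(self.member_samples)


def _runs(mask: np.ndarray):
    """Maximal runs of True as (lo, hi) half-open index pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    los = np.flatnonzero(d == 1)
    his = np.flatnonzero(d == -1)
    return list(zip(los, his))


def find_mcrs(
    track: pd.DataFrame,
    samples: list,
    class_codes: np.ndarray,
    min_freq: float = 0.10,
    include_sex: bool = False,
) -> list:
    """Plateau MCRs from a frequency track and its cohort class matrix."""
    if not (0 < min_freq <= 1):
        raise ValueError("min_freq must lie in (0, 1]")
    samples = np.asarray(samples, dtype=object)
    regions = []
    chrom_arr = track["chrom"].to_numpy(dtype=object)
    pos_arr = track["pos"].to_numpy()
    for direction, col, sign in (("gain", "gain_freq", 1), ("loss", "loss_freq", -1)):
        freq = track[col].to_numpy()
        aberrant = np.sign(class_codes) == sign  # samples x markers
        for chrom in pd.unique(chrom_arr):
            if not include_sex and chrom in ("X", "Y"):
                continue
            midx = np.flatnonzero(chrom_arr == chrom)
            f = freq[midx]
            spacing = int(np.median(np.diff(pos_arr[midx]))) if midx.size > 1 else 1
            for lo, hi in _runs(f >= min_freq):
                peak_rel = lo + int(np.argmax(f[lo:hi]))
                carriers = aberrant[:, midx[peak_rel]]
                a = b = peak_rel
                while a > lo and aberrant[carriers, midx[a - 1]].all():
                    a -= 1
                while b + 1 < hi and aberrant[carriers, midx[b + 1]].all():
                    b += 1
                start = int(pos_arr[midx[a]])
                end = int(pos_arr[midx[b]]) + spacing
                regions.append(
                    RecurrentRegion(
                        GenomicInterval(chrom, start, end),
                        direction,
                        float(f[peak_rel]),
                        member_samples=list(samples[carriers]),
                    )
                )
    return regions


def _sample_intervals(row: np.ndarray):
    return _runs(row.astype(bool))


def stac_null_max(
    aberration: np.ndarray, n_perm: int = 1000, seed: int = 0
) -> np.ndarray:
    """Null distribution of the chromosome-wide maximum marker frequency.

    ``aberration`` is a binary (samples × markers) matrix for one chromosome
    and direction.  Each permutation independently re-places every sample's
    aberration intervals (lengths preserved) uniformly among valid
    non-wrapping positions; per permutation the maximum column count is
    recorded.  Samples with no aberration contribute nothing.
    """
    ab = np.asarray(aberration)
    if ab.size == 0:
        raise ValueError("empty aberration matrix")
    n_samples, n_markers = ab.shape
    lengths = []  # per sample: list of interval lengths
    for s in range(n_samples):
        ivs = _sample_intervals(ab[s])
        if ivs:
            lengths.append(sorted(hi - lo for lo, hi in ivs))
    lengths.sort()  # canonical order: p-values invariant to sample order
    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm, dtype=np.int64)
    # samples with a single interval need no cap-at-1 and vectorize cheaply
    single = np.asarray([ls[0] for ls in lengths if len(ls) == 1], dtype=np.int64)
    multi = [ls for ls in lengths if len(ls) > 1]
    for b in range(n_perm):
        cnt = np.zeros(n_markers, dtype=np.int64)
        if single.size:
            d = np.zeros(n_markers + 1, dtype=np.int64)
            starts = (rng.random(single.size) * (n_markers - single + 1)).astype(
                np.int64
            )
            np.add.at(d, starts, 1)
            np.add.at(d, starts + single, -1)
            cnt += np.cumsum(d[:-1])
        for ls in multi:
            cover = np.zeros(n_markers + 1, dtype=np.int64)
            for L in ls:
                st = int(rng.integers(0, n_markers - L + 1))
                cover[st] += 1
                cover[st + L] -= 1
            cnt += np.minimum(np.cumsum(cover[:-1]), 1)
        null_max[b] = cnt.max() if cnt.size else 0
    return null_max


def stac_test(
    aberration: np.ndarray,
    peak_counts,
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Permutation p-values for observed region peak carrier counts.

    ``peak_counts`` are observed carrier counts of the regions under test on
    this chromosome; p = fraction of permutations whose chromosome-wide
    maximum frequency is >= the observed count.
    """
    import warnings

    if n_perm < 100:
        warnings.warn(f"STAC with n_perm={n_perm} < 100 is poorly resolved")
    null = stac_null_max(aberration, n_perm=n_perm, seed=seed)
    peaks = np.atleast_1d(np.asarray(peak_counts, dtype=np.int64))
    return np.array(
        [(1.0 + np.sum(null >= k)) / (n_perm + 1.0) for k in peaks], dtype=float
    )


def score_mcrs(
    regions: list,
    track: pd.DataFrame,
    samples: list,
    class_codes: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> list:
    """Attach STAC p-values to MCRs, chromosome by chromosome."""
    chrom_arr = track["chrom"].to_numpy(dtype=object)
    for direction, sign in (("gain", 1), ("loss", -1)):
        regs = [r for r in regions if r.direction == direction]
        for chrom in sorted({r.interval.chromosome for r in regs}):
            sub = [r for r in regs if r.interval.chromosome == chrom]
            midx = np.flatnonzero(chrom_arr == chrom)
            ab = (np.sign(class_codes[:, midx]) == sign).astype(np.int8)
            peaks = [r.n_carriers for r in sub]
            ps = stac_test(ab, peaks, n_perm=n_perm, seed=seed)
            for r, p in zip(sub, ps):
                r.stac_p = float(p)
    return regions


def mcr_table(regions: list) -> pd.DataFrame:
    """MCRs as a table with 1-based inclusive display coordinates."""
    return pd.DataFrame(
        [
            {
                "chrom": r.interval.chromosome,
                "start": r.interval.start + 1,
                "end": r.interval.end,
                "direction": r.direction,
                "frequency": r.peak_frequency,
                "stac_p": r.stac_p,
                "n_carriers": r.n_carriers,
            }
            for r in regions
        ],
        columns=[
            "chrom",
            "start",
            "end",
            "direction",
            "frequency",
            "stac_p",
            "n_carriers",
        ],
    )
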