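"""Sample-level quality control and profile centering.

MAPD (median absolute pairwise difference) is the median, over all pairs of
consecutive probes on the same chromosome, of |cn[i+1] - cn[i]|.  It tracks
per-probe noise while being insensitive to genuine copy-number steps (which
are rare among consecutive pairs), so noisy hybridizations can be removed at
a fixed cutoff (0.6 by default) without penalizing aberrant genomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ProbeProfile

__all__ = ["QCReport", "mapd", "qc_report", "center_profile", "smooth_profile"]

MAPD_CUTOFF = 0.6


@dataclass(frozen=True)
class QCReport:
    sample_id: str
    mapd: float
    pass_flag: bool


def mapd(profile: ProbeProfile) -> float:
    """Median absolute difference between consecutive probes, per chromosome.

    Differences never span a chromosome boundary.
    """
    diffs = []
    for _, idx in profile.chromosome_index().items():
        v = profile.values[idx]
        if v.size >= 2:
            diffs.append(np.abs(np.diff(v)))
    if not diffs:
        raise ValueError(
            f"sample {profile.sample_id}: no chromosome has >= 2 probes"
        )
    return float(np.median(np.concatenate(diffs)))


def qc_report(profile: ProbeProfile, cutoff: float = MAPD_CUTOFF) -> QCReport:
    m = mapd(profile)
    return QCReport(profile.sample_id, m, m <= cutoff)


def center_profile(
    profile: ProbeProfile,
    normal_baseline=None,
    bandwidth: float = 0.1,
) -> ProbeProfile:
    """Anchor the modal copy-number of a profile at the diploid level 2.0.

    The per-probe value density is estimated with a Gaussian-smoothed
    histogram; the profile is shifted so the density mode sits at 2.0.  The
    mode, rather than the mean or median, is used because aneuploid genomes
    can have well under half of their probes at the true diploid level while
    the diploid state usually remains the single largest cluster.

    If ``normal_baseline`` (a list of profiles on the same grid) is given,
    each probe is first divided by the normal-cohort median at that probe and
    rescaled to copies, removing probe-specific affinity effects.
    """
    values = profile.values
    if normal_baseline is not None:
        if len(normal_baseline) == 0:
            raise ValueError("normal baseline cohort is empty")
        ref = np.median(np.vstack([p.values for p in normal_baseline]), axis=0)
        if ref.size != values.size:
            raise ValueError("baseline profiles not on the sample's probe grid")
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.where(ref > 0, values / ref * 2.0, values)
    shift = 2.0 - _density_mode(values, bandwidth)
    return profile.replace_values(np.maximum(values + shift, 0.0))


def _density_mode(values: np.ndarray, bandwidth: float) -> float:
    lo, hi = float(np.min(values)) - 3 * bandwidth, float(np.max(values)) + 3 * bandwidth
    step = bandwidth / 4
    nbins = max(int(np.ceil((hi - lo) / step)), 8)
    hist, edges = np.histogram(values, bins=nbins, range=(lo, lo + nbins * step))
    # Gaussian kernel, truncated at 4 sigma, applied to the histogram
    half = int(np.ceil(4 * bandwidth / step))
    x = np.arange(-half, half + 1) * step
    kernel = np.exp(-0.5 * (x / bandwidth) ** 2)
    density = np.convolve(hist.astype(float), kernel, mode="same")
    centers = (edges[:-1] + edges[1:]) / 2
    return float(centers[np.argmax(density)])


def smooth_profile(profile: ProbeProfile, window: int = 5) -> ProbeProfile:
    """Running-median smoothing per chromosome (odd window)."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    from scipy.ndimage import median_filter

    out = profile.values.copy()
    for _, idx in profile.chromosome_index().items():
        out[idx] = median_filter(profile.values[idx], size=window, mode="nearest")
    return profile.replace_values(out)
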