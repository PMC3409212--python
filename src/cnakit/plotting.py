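"""Plots for fitted cohort results: genome-wide frequency tracks, G-score
tracks, Kaplan-Meier curves and network degree distributions.

All functions take an axes (created if omitted) and return it, so they
compose with user figure layouts.
"""

from __future__ import annotations

import numpy as np

from .genome import chromosome_sort_key

__all__ = [
    "plot_frequency_track",
    "plot_gscore_track",
    "plot_km",
    "plot_degree_distribution",
]


def _genome_axis(ax, chroms, positions):
    """Concatenated genome coordinate plus chromosome boundary ticks."""
    chroms = np.asarray(chroms, dtype=object)
    positions = np.asarray(positions, dtype=np.int64)
    offset, xs, ticks, labels = 0, np.empty(positions.size), [], []
    for c in sorted(set(chroms), key=chromosome_sort_key):
        idx = np.flatnonzero(chroms == c)
        span = positions[idx].max() + 1
        xs[idx] = positions[idx] + offset
        ticks.append(offset + span / 2)
        labels.append(str(c))
        offset += span
        ax.axvline(offset, color="0.85", lw=0.5, zorder=0)
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels, fontsize=7)
    return xs


def plot_frequency_track(track, ax=None):
    """Gain fraction above the axis, loss fraction below, genome-wide."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(12, 3))
    xs = _genome_axis(ax, track["chrom"], track["pos"])
    order = np.argsort(xs)
    ax.fill_between(xs[order], track["gain_freq"].to_numpy()[order], 0, color="tab:blue", label="gain")
    ax.fill_between(xs[order], -track["loss_freq"].to_numpy()[order], 0, color="tab:red", label="loss")
    ax.set_ylim(-1, 1)
    ax.set_ylabel("fraction of cohort")
    ax.axhline(0, color="k", lw=0.5)
    ax.legend(loc="upper right", fontsize=8)
    return ax


def plot_gscore_track(marker_chroms, marker_positions, gscore_track, ax=None):
    """Genome-wide G-score with the q-value cut visible as marker color."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(12, 2.5))
    xs = _genome_axis(ax, marker_chroms, marker_positions)
    order = np.argsort(xs)
    g = gscore_track["gscore"].to_numpy()[order]
    q = gscore_track["qvalue"].to_numpy()[order]
    ax.plot(xs[order], g, lw=0.7, color="0.4")
    sig = q < 0.25
    ax.plot(xs[order][sig], g[sig], ".", ms=3, color="tab:green")
    ax.set_ylabel("G-score")
    return ax


def plot_km(curves, ax=None):
    """Step plot of the two-group Kaplan-Meier curves from km_curves."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    for name, g in curves.groupby("group"):
        g = g.sort_values("time")
        ax.step(g["time"], g["survival"], where="post", label=name)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax


def plot_degree_distribution(distribution, ax=None):
    """Log-log degree histogram with the fitted slope."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    if distribution.bin_centers.size:
        ax.loglog(distribution.bin_centers, distribution.bin_counts, "o", ms=4)
        if np.isfinite(distribution.loglog_slope):
            x = distribution.bin_centers
            c = distribution.bin_counts[0] / x[0] ** distribution.loglog_slope
            ax.loglog(
                x,
                c * x**distribution.loglog_slope,
                "--",
                color="0.5",
                label=f"slope {distribution.loglog_slope:.2f}",
            )
            ax.legend()
    ax.set_xlabel("degree")
    ax.set_ylabel("gene count")
    return ax
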