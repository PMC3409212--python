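"""Copy-number bin classification, per-tumor event counts and frequency tracks.

Segments are placed into five bins on the absolute-copies scale:
amplified (> 3.8), gained (2.3, 3.8], unchanged [1.7, 2.3], deleted
[0.5, 1.7) and homozygously deleted (< 0.5).  Boundary values resolve
conservatively toward no-call: 1.7 and 2.3 are unchanged, while 3.8 is
gained and 0.5 deleted.

Classes are carried as small integer codes so cohort-scale marker matrices
stay cheap: -2 homozygous deletion, -1 deletion, 0 unchanged, +1 gain,
+2 amplification.  ``sign`` of the code gives the event direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import SEX_CHROMOSOMES, chromosome_sort_key

__all__ = [
    "BinThresholds",
    "classify_segment",
    "classify_segments",
    "CLASS_NAMES",
    "count_events",
    "event_count_table",
    "marker_class_matrix",
    "frequency_track",
]

log = logging.getLogger(__name__)

CLASS_NAMES = {
    -2: "homodeleted",
    -1: "deleted",
    0: "unchanged",
    1: "gained",
    2: "amplified",
}


@dataclass(frozen=True)
class BinThresholds:
    """Copy-number bin boundaries in absolute copies."""

    homodel_max: float = 0.5
    loss_max: float = 1.7
    neutral_max: float = 2.3
    gain_max: float = 3.8

    def __post_init__(self):
        t = (self.homodel_max, self.loss_max, self.neutral_max, self.gain_max)
        if not all(a < b for a, b in zip(t, t[1:])) or t[0] <= 0:
            raise ValueError(f"thresholds must be positive and increasing: {t}")

    def codes(self, mean_cn) -> np.ndarray:
        cn = np.asarray(mean_cn, dtype=float)
        if np.any(cn < 0):
            raise ValueError("negative copy number cannot be classified")
        return np.select(
            [
                cn > self.gain_max,
                cn > self.neutral_max,
                cn >= self.loss_max,
                cn >= self.homodel_max,
            ],
            [2, 1, 0, -1],
            default=-2,
        ).astype(np.int8)


DEFAULT_BINS = BinThresholds()


def classify_segment(mean_cn: float, thresholds: BinThresholds = DEFAULT_BINS) -> str:
    """Five-bin class name for one segment mean."""
    return CLASS_NAMES[int(thresholds.codes(mean_cn))]


def classify_segments(
    segments: pd.DataFrame, thresholds: BinThresholds = DEFAULT_BINS
) -> pd.DataFrame:
    """Add ``class_code`` and ``cna_class`` columns to a segment table."""
    out = segments.copy()
    codes = thresholds.codes(out["mean_cn"].to_numpy())
    out["class_code"] = codes
    out["cna_class"] = [CLASS_NAMES[int(c)] for c in codes]
    return out


def count_events(
    sample_segments: pd.DataFrame,
    thresholds: BinThresholds = DEFAULT_BINS,
    include_sex: bool = False,
) -> int:
    """Number of CNA events in one sample's classified segments.

    An event is a maximal run of adjacent same-direction non-neutral
    segments on one chromosome: adjacent gained and amplified segments merge
    into a single gain event, and deleted/homozygously-deleted likewise.
    Sex chromosomes are excluded unless requested.
    """
    seg = sample_segments
    if "class_code" not in seg.columns:
        seg = classify_segments(seg, thresholds)
    if not include_sex:
        seg = seg[~seg["chrom"].isin(SEX_CHROMOSOMES)]
    n = 0
    for _, g in seg.groupby("chrom", sort=False):
        g = g.sort_values("start")
        sign = np.sign(g["class_code"].to_numpy())
        prev = 0
        for s in sign:
            if s != 0 and s != prev:
                n += 1
            prev = s
    return n


def event_count_table(
    segments: pd.DataFrame,
    thresholds: BinThresholds = DEFAULT_BINS,
    include_sex: bool = False,
) -> pd.Series:
    """Per-sample event counts for a cohort segment table.

    Vectorized equivalent of applying :func:`count_events` per sample: an
    event begins wherever a non-neutral segment starts a new same-direction
    run within one sample-chromosome block.
    """
    seg = segments
    if "class_code" not in seg.columns:
        seg = classify_segments(seg, thresholds)
    if not include_sex:
        seg = seg[~seg["chrom"].isin(SEX_CHROMOSOMES)]
    key = seg["chrom"].map(chromosome_sort_key)
    seg = seg.assign(_k=key).sort_values(
        ["sample", "_k", "start"], kind="stable"
    )
    sample = seg["sample"].to_numpy(dtype=object)
    chrom = seg["chrom"].to_numpy(dtype=object)
    sign = np.sign(seg["class_code"].to_numpy())
    new_block = np.ones(len(seg), dtype=bool)
    if len(seg) > 1:
        new_block[1:] = (sample[1:] != sample[:-1]) | (chrom[1:] != chrom[:-1])
    prev = np.concatenate([[0], sign[:-1]])
    starts_run = (sign != 0) & (new_block | (sign != prev))
    counts = pd.Series(starts_run, index=sample).groupby(level=0).sum()
    all_samples = pd.Index(sorted(set(segments["sample"])), name="sample")
    return counts.reindex(all_samples, fill_value=0).astype(int)


def marker_class_matrix(
    segments: pd.DataFrame,
    marker_chroms: np.ndarray,
    marker_positions: np.ndarray,
    thresholds: BinThresholds = DEFAULT_BINS,
):
    """Per-sample class code at every marker position.

    Returns ``(samples, codes)`` with ``codes`` of shape (n_samples,
    n_markers), int8.  A marker not covered by any segment of a sample is
    treated as unchanged (logged once per sample).
    """
    seg = segments
    if "class_code" not in seg.columns:
        seg = classify_segments(seg, thresholds)
    marker_chroms = np.asarray(marker_chroms, dtype=object)
    marker_positions = np.asarray(marker_positions, dtype=np.int64)
    samples = sorted(seg["sample"].unique())
    codes = np.zeros((len(samples), marker_positions.size), dtype=np.int8)

    chrom_marker_idx = {
        c: np.flatnonzero(marker_chroms == c) for c in pd.unique(marker_chroms)
    }
    for si, (sample, g) in enumerate(seg.groupby("sample", sort=True)):
        uncovered = 0
        for chrom, gc in g.groupby("chrom", sort=False):
            midx = chrom_marker_idx.get(chrom)
            if midx is None or midx.size == 0:
                continue
            gc = gc.sort_values("start")
            starts = gc["start"].to_numpy()
            ends = gc["end"].to_numpy()
            cl = gc["class_code"].to_numpy()
            pos = marker_positions[midx]
            k = np.searchsorted(starts, pos, side="right") - 1
            inside = (k >= 0) & (pos < ends[np.clip(k, 0, None)])
            codes[si, midx[inside]] = cl[k[inside]]
            uncovered += int((~inside).sum())
        if uncovered:
            log.debug(
                "sample %s: %d markers uncovered by segments, treated as unchanged",
                sample,
                uncovered,
            )
    return samples, codes


def marker_value_matrix(
    segments: pd.DataFrame,
    marker_chroms: np.ndarray,
    marker_positions: np.ndarray,
    fill: float = 2.0,
):
    """Per-sample segment mean copy number at every marker.

    Companion to :func:`marker_class_matrix` on the continuous scale; markers
    uncovered by a sample's segmentation take ``fill`` (diploid by default).
    """
    marker_chroms = np.asarray(marker_chroms, dtype=object)
    marker_positions = np.asarray(marker_positions, dtype=np.int64)
    samples = sorted(segments["sample"].unique())
    values = np.full((len(samples), marker_positions.size), fill, dtype=float)
    chrom_marker_idx = {
        c: np.flatnonzero(marker_chroms == c) for c in pd.unique(marker_chroms)
    }
    for si, (_, g) in enumerate(segments.groupby("sample", sort=True)):
        for chrom, gc in g.groupby("chrom", sort=False):
            midx = chrom_marker_idx.get(chrom)
            if midx is None or midx.size == 0:
                continue
            gc = gc.sort_values("start")
            starts = gc["start"].to_numpy()
            ends = gc["end"].to_numpy()
            cn = gc["mean_cn"].to_numpy()
            pos = marker_positions[midx]
            k = np.searchsorted(starts, pos, side="right") - 1
            inside = (k >= 0) & (pos < ends[np.clip(k, 0, None)])
            values[si, midx[inside]] = cn[k[inside]]
    return samples, values


def frequency_track(
    marker_chroms: np.ndarray,
    marker_positions: np.ndarray,
    class_codes: np.ndarray,
) -> pd.DataFrame:
    """Cohort gain/loss fraction at every marker.

    ``class_codes`` is the (samples × markers) matrix from
    :func:`marker_class_matrix`; gains count codes > 0 (gained or amplified)
    and losses codes < 0.
    """
    if class_codes.ndim != 2 or class_codes.shape[0] < 1:
        raise ValueError("class_codes must be a (samples x markers) matrix")
    n = class_codes.shape[0]
    gain = (class_codes > 0).sum(axis=0) / n
    loss = (class_codes < 0).sum(axis=0) / n
    return pd.DataFrame(
        {
            "marker": np.arange(marker_positions.size),
            "chrom": np.asarray(marker_chroms, dtype=object),
            "pos": np.asarray(marker_positions, dtype=np.int64),
            "gain_freq": gain,
            "loss_freq": loss,
        }
    )


def track_value_at(track: pd.DataFrame, chromosome: str, position: int, column: str):
    """Track value at the marker nearest to a genomic position."""
    sub = track[track["chrom"] == chromosome]
    if sub.empty:
        raise KeyError(f"no markers on chromosome {chromosome}")
    i = (sub["pos"] - position).abs().idxmin()
    return float(sub.loc[i, column])
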