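"""Readers and writers for the tab-delimited formats the pipeline touches.

All files use 1-based coordinates (SEG inclusive end, probe positions
1-based, BED being the exception at 0-based half-open); everything internal
is 0-based half-open.  Copy number is carried internally in absolute copies
(diploid = 2.0); SEG files holding log2 ratios are converted at read time via
``CN = 2 * 2**log2ratio``.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import (
    GenomicInterval,
    SEX_CHROMOSOMES,
    chromosome_sort_key,
    normalize_chromosome,
)

__all__ = [
    "ProbeProfile",
    "GeneModel",
    "read_probe_matrix",
    "write_probe_matrix",
    "read_seg",
    "write_seg",
    "read_gene_model",
    "write_gene_model",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_gmt",
    "write_gmt",
    "SEG_COLUMNS",
]

SEG_COLUMNS = ["sample", "chrom", "start", "end", "n_probes", "value"]

#: required clinical columns; survival columns validated jointly
CLINICAL_COLUMNS = ["sample_id", "msi", "stage"]


@dataclass
class ProbeProfile:
    """One sample's ordered per-probe absolute copy-number values.

    Arrays are parallel and sorted by chromosome (karyotype order) then
    position; ``starts`` are 0-based probe start coordinates.
    """

    sample_id: str
    chroms: np.ndarray
    starts: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if not (self.chroms.size == self.starts.size == self.values.size):
            raise ValueError("probe arrays must have equal length")
        if np.any(self.values < 0):
            raise ValueError(f"negative copy number in sample {self.sample_id}")
        ranks = np.fromiter(
            (chromosome_sort_key(c) for c in self.chroms),
            dtype=np.int64,
            count=self.chroms.size,
        )
        combined = ranks * (1 << 40) + self.starts
        if combined.size and np.any(np.diff(combined) < 0):
            order = np.argsort(combined, kind="stable")
            self.chroms = self.chroms[order]
            self.starts = self.starts[order]
            self.values = self.values[order]
        for c, idx in self.chromosome_index().items():
            s = self.starts[idx]
            if s.size != np.unique(s).size:
                dup = s[np.where(np.diff(s) == 0)[0][0]]
                raise ValueError(
                    f"duplicate probe position chr{c}:{dup + 1} "
                    f"in sample {self.sample_id}"
                )

    @classmethod
    def _from_sorted(cls, sample_id, chroms, starts, values) -> "ProbeProfile":
        """Construct from arrays already validated and sorted (internal)."""
        out = object.__new__(cls)
        out.sample_id = sample_id
        out.chroms = chroms
        out.starts = starts
        out.values = values
        return out

    def __len__(self) -> int:
        return self.values.size

    def chromosome_index(self) -> dict:
        """Mapping chromosome -> slice of probe indices (contiguous after sort)."""
        out = {}
        if self.chroms.size == 0:
            return out
        boundaries = np.flatnonzero(self.chroms[1:] != self.chroms[:-1]) + 1
        edges = np.concatenate([[0], boundaries, [self.chroms.size]])
        for a, b in zip(edges[:-1], edges[1:]):
            out[self.chroms[a]] = slice(int(a), int(b))
        return out

    def replace_values(self, values: np.ndarray) -> "ProbeProfile":
        values = np.asarray(values, dtype=np.float64)
        if values.size != self.starts.size:
            raise ValueError("replacement values must match the probe grid")
        if np.any(values < 0):
            raise ValueError(f"negative copy number in sample {self.sample_id}")
        # grid already validated and sorted: bypass re-validation
        out = object.__new__(ProbeProfile)
        out.sample_id = self.sample_id
        out.chroms = self.chroms
        out.starts = self.starts
        out.values = values
        return out

    def autosomal_mask(self) -> np.ndarray:
        return np.array([c not in SEX_CHROMOSOMES for c in self.chroms])


@dataclass(frozen=True)
class GeneModel:
    """A gene with an ENTREZ-style identifier, a symbol and its locus."""

    gene_id: str
    symbol: str
    interval: GenomicInterval


# ---------------------------------------------------------------------------
# probe matrices


def read_probe_matrix(path) -> list:
    """Read a probe × sample copy-number matrix into per-sample profiles.

    Expected header: ``probe  chrom  pos  <sample1> <sample2> ...`` with
    1-based probe positions.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["probe", "chrom", "pos"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"probe matrix missing columns: {missing}")
    sample_cols = [c for c in df.columns if c not in required]
    if not sample_cols:
        raise ValueError("probe matrix has no sample columns")
    chroms = np.array([normalize_chromosome(c) for c in df["chrom"]], dtype=object)
    starts = df["pos"].to_numpy(dtype=np.int64) - 1  # 1-based file -> 0-based
    profiles = []
    for s in sample_cols:
        vals = pd.to_numeric(df[s], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(vals))
        if bad.size:
            probe = df["probe"].iloc[bad[0]]
            raise ValueError(
                f"non-numeric copy number for probe {probe!r} in sample {s!r}"
            )
        profiles.append(ProbeProfile(s, chroms.copy(), starts.copy(), vals))
    return profiles


def write_probe_matrix(path, profiles) -> None:
    ref = profiles[0]
    for p in profiles[1:]:
        if not (
            np.array_equal(p.chroms, ref.chroms) and np.array_equal(p.starts, ref.starts)
        ):
            raise ValueError("profiles must share one probe grid to write a matrix")
    df = pd.DataFrame(
        {
            "probe": [f"p{i}" for i in range(len(ref))],
            "chrom": ref.chroms,
            "pos": ref.starts + 1,
        }
    )
    for p in profiles:
        df[p.sample_id] = p.values
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# SEG


def read_seg(path, value_scale: str = "copies") -> pd.DataFrame:
    """Read a SEG file (1-based inclusive) into an internal segment table.

    Returns a DataFrame with columns ``sample, chrom, start, end, n_probes,
    mean_cn`` in 0-based half-open coordinates and absolute copies.

    Parameters
    ----------
    value_scale : 'copies' or 'log2', how the file's value column is scaled.
    """
    if value_scale not in ("copies", "log2"):
        raise ValueError("value_scale must be 'copies' or 'log2'")
    df = pd.read_csv(path, sep="\t", dtype={1: str})
    if df.shape[1] < 6:
        raise ValueError(f"SEG file needs 6 columns, found {df.shape[1]}")
    df = df.iloc[:, :6].copy()
    df.columns = SEG_COLUMNS
    df["chrom"] = [normalize_chromosome(c) for c in df["chrom"]]
    start = df["start"].to_numpy(dtype=np.int64) - 1  # 1-based inclusive -> 0-based
    end = df["end"].to_numpy(dtype=np.int64)  # inclusive end == half-open end
    if np.any(start >= end):
        i = int(np.flatnonzero(start >= end)[0])
        raise ValueError(f"segment with start > end at SEG row {i + 2}")
    value = df["value"].to_numpy(dtype=float)
    mean_cn = 2.0 * np.power(2.0, value) if value_scale == "log2" else value
    out = pd.DataFrame(
        {
            "sample": df["sample"].astype(str),
            "chrom": df["chrom"],
            "start": start,
            "end": end,
            "n_probes": df["n_probes"].to_numpy(dtype=np.int64),
            "mean_cn": mean_cn,
        }
    )
    _check_no_overlap(out)
    return sort_segments(out)


def sort_segments(segments: pd.DataFrame) -> pd.DataFrame:
    key = segments["chrom"].map(chromosome_sort_key)
    return (
        segments.assign(_k=key)
        .sort_values(["sample", "_k", "start"], kind="stable")
        .drop(columns="_k")
        .reset_index(drop=True)
    )


def _check_no_overlap(segments: pd.DataFrame) -> None:
    for (sample, chrom), g in segments.groupby(["sample", "chrom"], sort=False):
        g = g.sort_values("start")
        s, e = g["start"].to_numpy(), g["end"].to_numpy()
        if np.any(s[1:] < e[:-1]):
            raise ValueError(
                f"overlapping segments for sample {sample} on chr{chrom}"
            )


def write_seg(path, segments: pd.DataFrame) -> None:
    """Write internal segments as SEG (1-based inclusive, copies)."""
    out = segments.copy()
    out = out.rename(columns={"mean_cn": "value"})
    out["start"] = out["start"].astype(np.int64) + 1
    out["end"] = out["end"].astype(np.int64)
    cols = SEG_COLUMNS + [c for c in ("cna_class",) if c in out.columns]
    out[cols].to_csv(path, sep="\t", index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# BED gene models


def read_gene_model(path) -> list:
    """Read BED4(+1) gene models: chrom, start, end, gene_id[, symbol]."""
    genes, seen = [], set()
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"BED line {lineno}: expected >= 4 fields")
            chrom, start, end, gene_id = parts[:4]
            symbol = parts[4] if len(parts) > 4 else gene_id
            try:
                iv = GenomicInterval(chrom, int(start), int(end))
            except ValueError as e:
                raise ValueError(f"BED line {lineno}: {e}") from e
            if gene_id in seen:
                raise ValueError(f"BED line {lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            genes.append(GeneModel(gene_id, symbol, iv))
    return genes


def write_gene_model(path, genes) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.interval.chromosome}\t{g.interval.start}\t{g.interval.end}"
                f"\t{g.gene_id}\t{g.symbol}\n"
            )


# ---------------------------------------------------------------------------
# expression / clinical matrices


def read_expression(path) -> pd.DataFrame:
    """Genes × samples expression matrix, first column gene_id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene identifier in expression matrix: {dup!r}")
    return df.astype(float)


def write_expression(path, expression: pd.DataFrame) -> None:
    expression.to_csv(path, sep="\t", index_label="gene_id", float_format="%.4f")


def read_clinical(path) -> pd.DataFrame:
    """Per-sample clinical table indexed by sample_id.

    Survival columns come in (time, event) pairs, e.g. ``os_time``/``os_event``
    in months; an event with a missing time is rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id in clinical table: {dup!r}")
    df = df.set_index("sample_id")
    for endpoint in ("os", "rfs"):
        tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
        if tcol in df.columns and ecol in df.columns:
            t = pd.to_numeric(df[tcol], errors="coerce")
            e = pd.to_numeric(df[ecol], errors="coerce")
            bad = t.isna() & (e == 1)
            if bad.any():
                raise ValueError(
                    f"sample {bad.idxmax()!r}: {endpoint.upper()} event recorded "
                    "without a survival time"
                )
            if (t.dropna() < 0).any():
                raise ValueError(f"negative {endpoint.upper()} time")
            df[tcol], df[ecol] = t, e
    return df


def write_clinical(path, clinical: pd.DataFrame) -> None:
    clinical.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# GMT gene sets


@dataclass
class GeneSetCollection:
    """Named gene sets with the membership-size bookkeeping enrichment needs."""

    sets: dict = field(default_factory=dict)  # name -> list of gene ids
    descriptions: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def filter_by_size(self, min_size: int = 10, max_size: int = 500, universe=None):
        """Sets whose (universe-intersected) size lies in [min_size, max_size]."""
        kept = GeneSetCollection()
        uni = set(universe) if universe is not None else None
        for name, members in self.sets.items():
            eff = [m for m in members if uni is None or m in uni]
            if min_size <= len(eff) <= max_size:
                kept.sets[name] = eff
                kept.descriptions[name] = self.descriptions.get(name, "")
        return kept


def read_gmt(path) -> GeneSetCollection:
    coll = GeneSetCollection()
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"GMT line {lineno}: need name, description and >= 1 member"
                )
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if name in coll.sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            coll.sets[name] = members
            coll.descriptions[name] = desc
    return coll


def write_gmt(path, collection: GeneSetCollection) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def _open(path):
    if hasattr(path, "read"):
        return _io.StringIO(path.read()) if not hasattr(path, "readline") else path
    return open(path)
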