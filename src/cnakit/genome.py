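"""Genomic coordinate primitives and the reference genome layout.

Internal coordinates are 0-based half-open everywhere.  File formats that use
1-based (inclusive) coordinates are converted exactly once, at the I/O
boundary (:mod:`cnakit.io`).

The package ships a miniature genome whose chromosome and centromere
proportions follow the human build-36 karyotype scaled down (default 1/20,
~154 Mb total), so that a several-hundred-sample cohort can be simulated and
segmented in seconds while arm-level and focal events keep their relative
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GenomicInterval", "Genome", "CHROMOSOMES", "SEX_CHROMOSOMES"]

#: canonical chromosome order used for sorting throughout
CHROMOSOMES = [str(i) for i in range(1, 23)] + ["X", "Y"]
SEX_CHROMOSOMES = frozenset({"X", "Y"})

_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}

# human build-36 chromosome lengths and centromere positions, megabases
_HG_LENGTH_MB = {
    "1": 247.2, "2": 242.8, "3": 199.5, "4": 191.3, "5": 180.9,
    "6": 170.9, "7": 158.8, "8": 146.3, "9": 140.4, "10": 135.4,
    "11": 134.5, "12": 132.3, "13": 114.1, "14": 106.4, "15": 100.3,
    "16": 88.8, "17": 78.8, "18": 76.1, "19": 63.8, "20": 62.4,
    "21": 46.9, "22": 49.7, "X": 154.9,
}
_HG_CENTROMERE_MB = {
    "1": 124.3, "2": 93.3, "3": 91.7, "4": 50.7, "5": 47.7,
    "6": 60.5, "7": 59.1, "8": 45.2, "9": 51.4, "10": 40.3,
    "11": 52.9, "12": 35.4, "13": 17.9, "14": 17.6, "15": 19.0,
    "16": 36.6, "17": 24.0, "18": 17.2, "19": 26.5, "20": 27.5,
    "21": 13.2, "22": 14.7, "X": 60.6,
}


def normalize_chromosome(label: str) -> str:
    """Accept '17', 'chr17', 'chrX' etc.; return the bare label."""
    c = str(label).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c not in _CHROM_RANK:
        raise ValueError(f"unknown chromosome label: {label!r}")
    return c


def chromosome_sort_key(label: str) -> int:
    rank = _CHROM_RANK.get(label)
    return rank if rank is not None else _CHROM_RANK[normalize_chromosome(label)]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one chromosome."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self):
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chromosome}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def is_sex(self) -> bool:
        return self.chromosome in SEX_CHROMOSOMES

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chromosome: str, position: int) -> bool:
        return (
            normalize_chromosome(chromosome) == self.chromosome
            and self.start <= position < self.end
        )

    def __str__(self) -> str:  # 1-based inclusive, the convention people read
        return f"chr{self.chromosome}:{self.start + 1:,}-{self.end:,}"


class Genome:
    """Chromosome lengths, centromere positions and arm lookup.

    Parameters
    ----------
    lengths : dict mapping chromosome label -> length in bp
    centromeres : dict mapping chromosome label -> centromere position in bp
    """

    def __init__(self, lengths: dict, centromeres: dict):
        self.lengths = {normalize_chromosome(c): int(v) for c, v in lengths.items()}
        self.centromeres = {
            normalize_chromosome(c): int(v) for c, v in centromeres.items()
        }
        missing = set(self.lengths) - set(self.centromeres)
        if missing:
            raise ValueError(f"centromere position missing for: {sorted(missing)}")
        self.chromosomes = sorted(self.lengths, key=chromosome_sort_key)

    @classmethod
    def miniature(cls, scale: float = 0.05) -> "Genome":
        """Human-karyotype-proportioned genome scaled by ``scale`` (default 1/20)."""
        mb = 1_000_000
        lengths = {c: int(round(v * scale * mb)) for c, v in _HG_LENGTH_MB.items()}
        cents = {c: int(round(v * scale * mb)) for c, v in _HG_CENTROMERE_MB.items()}
        return cls(lengths, cents)

    @property
    def autosomes(self) -> list:
        return [c for c in self.chromosomes if c not in SEX_CHROMOSOMES]

    def chromosome_interval(self, chromosome: str) -> GenomicInterval:
        c = normalize_chromosome(chromosome)
        return GenomicInterval(c, 0, self.lengths[c])

    def arm(self, name: str) -> GenomicInterval:
        """Resolve an arm name like '20q', '3p', or a whole chromosome '18'."""
        name = str(name).strip()
        if name.lower().startswith("chr"):
            name = name[3:]
        if name and name[-1] in "pq":
            c = normalize_chromosome(name[:-1])
            cent = self.centromeres[c]
            if name[-1] == "p":
                return GenomicInterval(c, 0, cent)
            return GenomicInterval(c, cent, self.lengths[c])
        return self.chromosome_interval(name)

    def arm_of(self, chromosome: str, position: int) -> str:
        c = normalize_chromosome(chromosome)
        return "p" if position < self.centromeres[c] else "q"

    def arm_boundaries(self, chromosome: str) -> list:
        """[(arm_label, interval)] for one chromosome."""
        c = normalize_chromosome(chromosome)
        cent = self.centromeres[c]
        return [
            (f"{c}p", GenomicInterval(c, 0, cent)),
            (f"{c}q", GenomicInterval(c, cent, self.lengths[c])),
        ]

    def probe_positions(self, spacing: int = 50_000, include_sex: bool = True):
        """Uniform probe grid: (chrom array, start array), sorted."""
        chroms, starts = [], []
        for c in self.chromosomes:
            if not include_sex and c in SEX_CHROMOSOMES:
                continue
            pos = np.arange(spacing // 2, self.lengths[c], spacing, dtype=np.int64)
            chroms.append(np.full(pos.size, c, dtype=object))
            starts.append(pos)
        return np.concatenate(chroms), np.concatenate(starts)

    def total_length(self, include_sex: bool = True) -> int:
        return sum(
            v
            for c, v in self.lengths.items()
            if include_sex or c not in SEX_CHROMOSOMES
        )
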