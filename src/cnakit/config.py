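"""Pipeline configuration: every stage threshold with its standard default."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


@dataclass
class PipelineConfig:
    """All tunable thresholds of the analysis, with their default values.

    Defaults are the standard operating points of the analysis: five-bin
    copy-number thresholds (0.5 / 1.7 / 2.3 / 3.8 copies), CBS split p-value
    1e-6, MCR frequency floor 10% with STAC p < 0.01, focal-peak q < 0.25,
    group comparison at > 15 percentage points and Fisher p < 0.01, three
    clusters under complete linkage, correlation-edge threshold |r| >= 0.3,
    gene-set size bounds 10..500 with a 100-permutation FDR, log-rank
    p < 0.01, and the MAPD sample-QC cutoff 0.6.
    """

    mapd_cutoff: float = 0.6
    cbs_alpha: float = 1e-6
    cbs_n_perm: int = 10_000
    cbs_min_probes: int = 3
    cbs_merge_tol: float = 0.3
    cbs_rank: bool = False
    bins: tuple = (0.5, 1.7, 2.3, 3.8)
    mcr_min_freq: float = 0.10
    stac_p: float = 0.01
    stac_n_perm: int = 1000
    gistic_q: float = 0.25
    gistic_n_perm: int = 1000
    compare_diff: float = 15.0
    compare_p: float = 0.01
    cluster_k: int = 3
    cluster_metric: str = "euclidean"
    r_threshold: float = 0.3
    network_n_perm: int = 20
    perm_fdr_n: int = 100
    set_size: tuple = (10, 500)
    survival_p: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.cbs_alpha < 1):
            raise ValueError("cbs_alpha must lie in (0, 1)")
        if not (0 < self.mcr_min_freq <= 1):
            raise ValueError("mcr_min_freq must lie in (0, 1]")
        for name in ("stac_p", "gistic_q", "compare_p", "survival_p"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.mapd_cutoff < 0:
            raise ValueError("mapd_cutoff must be >= 0")
        b = tuple(self.bins)
        if len(b) != 4 or not all(x < y for x, y in zip(b, b[1:])):
            raise ValueError("bins must be four increasing thresholds")
        self.bins = b
        self.set_size = tuple(self.set_size)

    def thresholds(self):
        from .calling import BinThresholds

        return BinThresholds(*self.bins)

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "PipelineConfig":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            try:
                data = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
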