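"""Synthetic tumor-cohort generator with recorded ground truth.

The generator emulates the statistical structure of a stage-II/III
colorectal-cancer copy-number cohort: a microsatellite-stable (MSS) arm with
many aberrations per tumor and recurrent arm-level gains/losses, a
microsatellite-instable (MSI) arm with few aberrations but characteristic
focal deletions, cis dosage coupling of mRNA to gene copy number, and
survival coupled to designated events.

Key modelling choices
---------------------
* Per-tumor total event counts follow a negative binomial matched to the
  requested (mean, sd); planted events count toward that total, and the
  background event count makes up the remainder.
* Background events get random arm positions, lengths log-uniform between a
  floor and the whole arm, direction +/-1 copy with equal probability.  They
  are placed without overlapping (or abutting within a small probe gap) any
  other event of the sample, so the realized per-tumor event count is exact
  and recoverable as merged same-direction segment runs downstream.
* Overlapping *planted* events (e.g. a focal deletion inside a gained arm)
  add in copy number, floored at zero.
* Carrier draws are independent Bernoulli per event; a Gaussian copula
  version with requested pairwise correlations is available for studying
  event co-occurrence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calling import DEFAULT_BINS
from .genome import Genome, GenomicInterval
from .io import GeneModel, ProbeProfile

__all__ = [
    "PlantedEvent",
    "CohortSpec",
    "GroundTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_correlated_events",
]

_KIND_DIRECTION = {
    "gain": 1,
    "amplification": 1,
    "loss": -1,
    "homozygous_deletion": -1,
}


@dataclass(frozen=True)
class PlantedEvent:
    """A recurrent aberration planted at a fixed cohort frequency."""

    name: str
    region: str  # arm name ('20q'), chromosome ('18'), or 'chrom:start-end' 0-based
    kind: str  # gain | amplification | loss | homozygous_deletion
    target_cn: float
    frequency: float
    group: str | None = None  # restrict carriers to one clinical group
    os_hazard_ratio: float = 1.0
    rfs_hazard_ratio: float = 1.0

    def __post_init__(self):
        if self.kind not in _KIND_DIRECTION:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not (0.0 <= self.frequency <= 1.0):
            raise ValueError("frequency must lie in [0, 1]")
        b = DEFAULT_BINS
        ok = {
            "gain": b.neutral_max < self.target_cn <= b.gain_max,
            "amplification": self.target_cn > b.gain_max,
            "loss": b.homodel_max <= self.target_cn < b.loss_max,
            "homozygous_deletion": self.target_cn < b.homodel_max,
        }[self.kind]
        if not ok:
            raise ValueError(
                f"target_cn {self.target_cn} inconsistent with kind {self.kind!r} "
                "under the default copy-number bins"
            )

    def resolve(self, genome: Genome) -> GenomicInterval:
        if ":" in self.region:
            chrom, span = self.region.split(":")
            a, b = span.split("-")
            return GenomicInterval(chrom, int(a), int(b))
        return genome.arm(self.region)

    @property
    def direction(self) -> int:
        return _KIND_DIRECTION[self.kind]

    @property
    def delta(self) -> float:
        return self.target_cn - 2.0


@dataclass
class CohortSpec:
    """Complete description of a synthetic cohort."""

    n_mss: int = 269
    n_msi: int = 33
    mss_burden: tuple = (33.2, 17.6)  # mean, sd of total events per MSS tumor
    msi_burden: tuple = (10.2, 6.5)
    planted_events: list = field(default_factory=list)
    probe_spacing: int = 50_000
    noise_sd: float = 0.15
    genome_scale: float = 0.05
    bg_min_length: int = 400_000  # floor for background event length
    bg_probe_gap: int = 3  # neutral probes required between events
    gene_spacing: int = 500_000
    gene_length: int = 100_000
    expr_intercept: float = 0.0
    expr_slope: float = 0.5
    expr_noise_sd: float = 0.3
    baseline_hazard: float = 0.013  # per month
    follow_up: float = 84.0  # months
    stage3_fraction_mss: float = 239 / 269
    stage3_fraction_msi: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_mss < 0 or self.n_msi < 0 or self.n_mss + self.n_msi == 0:
            raise ValueError("cohort sizes must be non-negative and not both zero")
        for name in ("mss_burden", "msi_burden"):
            mean, sd = getattr(self, name)
            if mean < 0 or sd <= 0:
                raise ValueError(f"{name}: mean must be >= 0 and sd > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    # -- canonical study conditions -------------------------------------
    @staticmethod
    def arm_events() -> list:
        """The recurrent MSS arm-level events at their cohort frequencies."""
        return [
            PlantedEvent("gain_20q", "20q", "gain", 3.0, 0.725, "MSS",
                         os_hazard_ratio=0.5, rfs_hazard_ratio=0.7),
            PlantedEvent("gain_13q", "13q", "gain", 3.0, 0.510, "MSS"),
            PlantedEvent("gain_chr7", "7", "gain", 3.0, 0.418, "MSS"),
            PlantedEvent("gain_8q", "8q", "gain", 3.0, 0.331, "MSS"),
            PlantedEvent("loss_chr18", "18", "loss", 1.0, 0.586, "MSS"),
            PlantedEvent("loss_4q", "4q", "loss", 1.0, 0.26, "MSS"),
            PlantedEvent("loss_21q", "21q", "loss", 1.0, 0.216, "MSS"),
        ]

    @staticmethod
    def focal_events(genome_scale: float = 0.05) -> list:
        """MSI-enriched and stage-associated focal deletions.

        Loci are the scaled equivalents of 16q23.1, 20q11.1 and 3p14.2; each
        event appears once per group with its group's frequency.
        """
        def scaled(chrom, start_mb, width=600_000):
            a = int(start_mb * 1e6 * genome_scale / 0.05 * 1.0)
            return f"{chrom}:{a}-{a + width}"

        loc_16q = scaled("16", 3.86)
        loc_20q = scaled("20", 1.42)
        loc_3p = scaled("3", 3.00)
        return [
            PlantedEvent("del_16q23_msi", loc_16q, "loss", 1.0, 0.242, "MSI"),
            PlantedEvent("del_16q23_mss", loc_16q, "loss", 1.0, 0.071, "MSS"),
            PlantedEvent("del_20q11_msi", loc_20q, "loss", 1.0, 0.244, "MSI"),
            PlantedEvent("del_20q11_mss", loc_20q, "loss", 1.0, 0.089, "MSS"),
            PlantedEvent("del_3p14_iii", loc_3p, "loss", 1.0, 0.243, "III"),
            PlantedEvent("del_3p14_ii", loc_3p, "loss", 1.0, 0.033, "II"),
        ]

    @classmethod
    def default_mss(cls, n: int = 269, seed: int = 0) -> "CohortSpec":
        return cls(n_mss=n, n_msi=0, planted_events=cls.arm_events(), seed=seed)

    @classmethod
    def default_msi(cls, n: int = 33, seed: int = 0) -> "CohortSpec":
        ev = [e for e in cls.focal_events() if e.group == "MSI"]
        return cls(n_mss=0, n_msi=n, planted_events=ev, seed=seed)

    @classmethod
    def default_combined(
        cls, n_mss: int = 269, n_msi: int = 33, seed: int = 0
    ) -> "CohortSpec":
        return cls(
            n_mss=n_mss,
            n_msi=n_msi,
            planted_events=cls.arm_events() + cls.focal_events(),
            seed=seed,
        )


@dataclass
class GroundTruth:
    """What the generator actually did, for downstream validation."""

    planted_carriers: pd.DataFrame  # samples x planted-event names, bool
    realized_frequencies: dict  # event name -> carrier fraction within its group
    event_counts: pd.Series  # realized (placed) events per sample
    target_counts: pd.Series  # negative-binomial target per sample
    sample_events: dict  # sample -> list of (GenomicInterval, delta)


@dataclass
class SimulatedCohort:
    profiles: list
    clinical: pd.DataFrame
    expression: pd.DataFrame
    truth: GroundTruth
    genome: Genome
    gene_models: list
    spec: CohortSpec


def _negbin_counts(rng, n, mean, sd):
    var = sd * sd
    if var <= mean:  # under-dispersed request: fall back to Poisson
        return rng.poisson(mean, size=n)
    r = mean * mean / (var - mean)
    p = mean / var
    return rng.negative_binomial(r, p, size=n)


def _default_gene_models(genome: Genome, spacing: int, length: int) -> list:
    genes = []
    k = 0
    for chrom in genome.chromosomes:
        pos = spacing // 2
        while pos + length < genome.lengths[chrom]:
            k += 1
            genes.append(
                GeneModel(f"G{k:04d}", f"SYM{k:04d}",
                          GenomicInterval(chrom, pos, pos + length))
            )
            pos += spacing
    return genes


def _draw_carriers_independent(rng, spec, groups):
    """Bernoulli carrier matrix (n_samples x n_events)."""
    n = len(groups["msi"])
    carriers = np.zeros((n, len(spec.planted_events)), dtype=bool)
    for j, ev in enumerate(spec.planted_events):
        eligible = _eligible_mask(ev, groups)
        carriers[:, j] = eligible & (rng.random(n) < ev.frequency)
    return carriers


def _eligible_mask(ev, groups):
    n = len(groups["msi"])
    if ev.group is None:
        return np.ones(n, dtype=bool)
    if ev.group in ("MSI", "MSS"):
        return groups["msi"] == ev.group
    if ev.group in ("II", "III"):
        return groups["stage"] == ev.group
    raise ValueError(f"unknown group restriction {ev.group!r}")


def _draw_carriers_copula(rng, spec, groups, rho):
    """Gaussian-copula carriers with requested pairwise correlations."""
    rho = np.asarray(rho, dtype=float)
    m = len(spec.planted_events)
    if rho.shape != (m, m) or not np.allclose(rho, rho.T):
        raise ValueError("rho_matrix must be symmetric, one row per planted event")
    w = np.linalg.eigvalsh(rho)
    if w.min() < -1e-8:
        raise ValueError("rho_matrix is not positive semi-definite")
    n = len(groups["msi"])
    cov = rho + np.eye(m) * max(0.0, -w.min() + 1e-12)
    z = rng.multivariate_normal(np.zeros(m), cov, size=n, method="eigh")
    carriers = np.zeros((n, m), dtype=bool)
    for j, ev in enumerate(spec.planted_events):
        thresh = stats.norm.ppf(ev.frequency)
        carriers[:, j] = _eligible_mask(ev, groups) & (z[:, j] < thresh)
    return carriers


def _place_background(rng, genome, spec, existing, count):
    """Place ``count`` non-overlapping background events; returns list of
    (interval, delta).  ``existing`` is a per-chromosome list of (start, end)
    blocked spans (grown by the probe gap)."""
    arms = []
    for chrom in genome.autosomes:
        for _, iv in genome.arm_boundaries(chrom):
            if iv.length > spec.bg_min_length:
                arms.append(iv)
    weights = np.array([a.length for a in arms], dtype=float)
    cumw = np.cumsum(weights / weights.sum())
    log_lo = math.log(spec.bg_min_length)
    gap = spec.bg_probe_gap * spec.probe_spacing
    placed = []
    for _ in range(count):
        for _attempt in range(200):
            u = rng.random(4)
            arm = arms[int(np.searchsorted(cumw, u[0]))]
            length = int(math.exp(log_lo + u[1] * (math.log(arm.length) - log_lo)))
            start = arm.start + int(u[2] * (arm.length - length + 1))
            end = start + length
            blocked = existing.setdefault(arm.chromosome, [])
            if any(start - gap < e and b < end + gap for b, e in blocked):
                continue
            blocked.append((start, end))
            delta = 1.0 if u[3] < 0.5 else -1.0
            placed.append((GenomicInterval(arm.chromosome, start, end), delta))
            break
    return placed


def simulate_cohort(spec: CohortSpec, seed: int | None = None) -> SimulatedCohort:
    """Generate profiles, clinical annotation, expression and ground truth."""
    return _simulate(spec, seed, carriers_fn=_draw_carriers_independent)


def simulate_correlated_events(
    spec: CohortSpec, rho_matrix, seed: int | None = None
) -> SimulatedCohort:
    """As :func:`simulate_cohort` with Gaussian-copula-correlated carriers."""
    return _simulate(
        spec,
        seed,
        carriers_fn=lambda rng, sp, gr: _draw_carriers_copula(rng, sp, gr, rho_matrix),
    )


def _simulate(spec, seed, carriers_fn):
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    genome = Genome.miniature(spec.genome_scale)
    chroms, starts = genome.probe_positions(spec.probe_spacing)
    keep = np.array([c != "Y" for c in chroms])
    chroms, starts = chroms[keep], starts[keep]
    n = spec.n_mss + spec.n_msi
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    msi = np.array(["MSS"] * spec.n_mss + ["MSI"] * spec.n_msi, dtype=object)
    stage_p = np.where(msi == "MSS", spec.stage3_fraction_mss, spec.stage3_fraction_msi)
    stage = np.where(rng.random(n) < stage_p, "III", "II").astype(object)
    groups = {"msi": msi, "stage": stage}

    carriers = carriers_fn(rng, spec, groups)
    event_ivs = [ev.resolve(genome) for ev in spec.planted_events]
    for ev, iv in zip(spec.planted_events, event_ivs):
        if iv.is_sex:
            raise ValueError(f"planted event {ev.name} on a sex chromosome")

    # feasibility: planted expectation must not exceed the burden mean
    for grp, (mean, _) in (("MSS", spec.mss_burden), ("MSI", spec.msi_burden)):
        expect = sum(
            ev.frequency
            for ev in spec.planted_events
            if ev.group in (None, grp)
            or ev.group in ("II", "III")
        )
        n_grp = spec.n_mss if grp == "MSS" else spec.n_msi
        if n_grp and expect > mean:
            raise ValueError(
                f"{grp} burden mean {mean} below planted-event expectation {expect:.2f}"
            )

    target = np.empty(n, dtype=np.int64)
    mss_mask = msi == "MSS"
    target[mss_mask] = _negbin_counts(rng, int(mss_mask.sum()), *spec.mss_burden)
    target[~mss_mask] = _negbin_counts(rng, int((~mss_mask).sum()), *spec.msi_burden)

    gap = spec.bg_probe_gap * spec.probe_spacing
    profiles = []
    sample_events = {}
    realized_counts = np.zeros(n, dtype=np.int64)
    chrom_index = {}
    for c in pd.unique(chroms):
        chrom_index[c] = np.flatnonzero(chroms == c)
    gene_models = _default_gene_models(genome, spec.gene_spacing, spec.gene_length)

    base = np.full(starts.size, 2.0)
    # background events never touch a planted locus, in any sample: recurrent
    # loci stay clean so a planted cohort frequency is recovered exactly as
    # the realized carrier fraction, not carrier fraction plus background hits
    planted_blocked = {}
    for iv in event_ivs:
        planted_blocked.setdefault(iv.chromosome, []).append((iv.start, iv.end))
    for i, sid in enumerate(sample_ids):
        events = []
        blocked = {c: list(spans) for c, spans in planted_blocked.items()}
        for j, ev in enumerate(spec.planted_events):
            if carriers[i, j]:
                iv = event_ivs[j]
                events.append((iv, ev.delta))
        n_bg = max(int(target[i]) - len(events), 0)
        events.extend(_place_background(rng, genome, spec, blocked, n_bg))
        values = base.copy()
        for iv, delta in events:
            idx = chrom_index.get(iv.chromosome)
            if idx is None:
                continue
            pos = starts[idx]
            sel = idx[(pos >= iv.start) & (pos < iv.end)]
            values[sel] += delta
        values = np.maximum(values, 0.0)
        if spec.noise_sd > 0:
            values = np.maximum(values + rng.normal(0, spec.noise_sd, values.size), 0.0)
        if not profiles:  # validate the shared grid once
            profiles.append(ProbeProfile(sid, chroms, starts, values))
            chroms, starts = profiles[0].chroms, profiles[0].starts
        else:
            profiles.append(ProbeProfile._from_sorted(sid, chroms, starts, values))
        sample_events[sid] = events
        realized_counts[i] = len(events)

    # expression: cis dosage model on the noiseless event stack
    expr = _expression_matrix(
        spec, rng, gene_models, sample_ids, sample_events
    )

    clinical = _clinical_table(
        spec, rng, sample_ids, msi, stage, carriers
    )

    realized_freq = {}
    for j, ev in enumerate(spec.planted_events):
        elig = _eligible_mask(ev, groups)
        realized_freq[ev.name] = (
            float(carriers[elig, j].mean()) if elig.any() else float("nan")
        )

    truth = GroundTruth(
        planted_carriers=pd.DataFrame(
            carriers, index=sample_ids, columns=[ev.name for ev in spec.planted_events]
        ),
        realized_frequencies=realized_freq,
        event_counts=pd.Series(realized_counts, index=sample_ids, name="events"),
        target_counts=pd.Series(target, index=sample_ids, name="target"),
        sample_events=sample_events,
    )
    return SimulatedCohort(
        profiles, clinical, expr, truth, genome, gene_models, spec
    )


def demo_gene_sets(gene_models, n_sets: int = 15, seed: int = 0):
    """Synthetic gene-set collection over the cohort's gene models.

    Random sets of plausible pathway sizes, for exercising the enrichment
    stage when no curated GMT is supplied.
    """
    from .io import GeneSetCollection

    rng = np.random.default_rng(seed)
    ids = np.array([g.gene_id for g in gene_models], dtype=object)
    coll = GeneSetCollection()
    for k in range(n_sets):
        size = int(rng.integers(10, min(80, ids.size)))
        members = list(rng.choice(ids, size=size, replace=False))
        coll.sets[f"SET_{k:02d}"] = members
        coll.descriptions[f"SET_{k:02d}"] = "synthetic gene set"
    return coll


def _expression_matrix(spec, rng, gene_models, sample_ids, sample_events):
    n_genes, n = len(gene_models), len(sample_ids)
    cn = np.full((n_genes, n), 2.0)
    gene_mid = {}
    for gi, g in enumerate(gene_models):
        gene_mid.setdefault(g.interval.chromosome, []).append(
            (gi, g.interval.midpoint)
        )
    for si, sid in enumerate(sample_ids):
        for iv, delta in sample_events[sid]:
            for gi, mid in gene_mid.get(iv.chromosome, ()):
                if iv.start <= mid < iv.end:
                    cn[gi, si] += delta
    cn = np.maximum(cn, 0.0)
    expr = (
        spec.expr_intercept
        + spec.expr_slope * cn
        + rng.normal(0, spec.expr_noise_sd, size=cn.shape)
    )
    return pd.DataFrame(expr, index=[g.gene_id for g in gene_models], columns=sample_ids)


def _clinical_table(spec, rng, sample_ids, msi, stage, carriers):
    n = len(sample_ids)
    os_hr = np.ones(n)
    rfs_hr = np.ones(n)
    # hazard multiplies over carried survival-linked events
    for j, ev in enumerate(spec.planted_events):
        os_hr *= np.where(carriers[:, j], ev.os_hazard_ratio, 1.0)
        rfs_hr *= np.where(carriers[:, j], ev.rfs_hazard_ratio, 1.0)
    h0 = spec.baseline_hazard

    def endpoint(hr):
        t_event = rng.exponential(1.0 / (h0 * hr))
        censor = rng.uniform(0, spec.follow_up, size=n)
        time = np.minimum(t_event, censor)
        event = (t_event <= censor).astype(int)
        return np.round(time, 2), event

    os_time, os_event = endpoint(os_hr)
    rfs_time, rfs_event = endpoint(rfs_hr * 1.0)

    # 20q-gain carriers are depleted of the BRAF-mutant-like expression label
    has_20q = np.zeros(n, dtype=bool)
    for j, ev in enumerate(spec.planted_events):
        if ev.name == "gain_20q":
            has_20q = carriers[:, j]
    p_brafm_like = np.where(has_20q, 0.05, 0.55)
    brafm_like = rng.random(n) < p_brafm_like
    braf_mut = rng.random(n) < np.where(brafm_like, 0.25, 0.02)
    kras_mut = rng.random(n) < 0.4

    return pd.DataFrame(
        {
            "msi": msi,
            "stage": stage,
            "braf_mut": braf_mut.astype(int),
            "kras_mut": kras_mut.astype(int),
            "brafm_like": np.where(brafm_like, "BRAFm-like", "non-BRAFm-like"),
            "os_time": os_time,
            "os_event": os_event,
            "rfs_time": rfs_time,
            "rfs_event": rfs_event,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
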