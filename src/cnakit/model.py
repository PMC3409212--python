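"""Cohort-level model facade: build from data, fit, inspect results.

:class:`CohortAnalysis` bundles a cohort's probe profiles with its clinical
annotation, expression matrix and gene models; :meth:`CohortAnalysis.fit`
runs the staged analysis (QC → centering → segmentation → classification →
recurrence / focal peaks / group comparison / clustering / dosage /
network / survival) and returns a :class:`CohortResults` carrying every
stage's table, with :meth:`CohortResults.summary` giving the one-screen
overview.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calling, compare, dosage, gistic, network, qc, recurrence, survival
from .config import PipelineConfig
from .genome import SEX_CHROMOSOMES
from .segmentation import cbs_segment

log = logging.getLogger(__name__)

__all__ = ["CohortAnalysis", "CohortResults"]

#: stage execution order with hard dependencies
_STAGES = [
    "qc",
    "center",
    "segment",
    "classify",
    "track",
    "mcr",
    "gistic",
    "compare",
    "cluster",
    "genecn",
    "concordance",
    "enrich",
    "network",
    "survival",
]
_DEPS = {
    "center": {"qc"},
    "segment": {"center"},
    "classify": {"segment"},
    "track": {"classify"},
    "mcr": {"track"},
    "gistic": {"classify"},
    "compare": {"track"},
    "cluster": {"genecn"},
    "genecn": {"classify"},
    "concordance": {"genecn"},
    "enrich": {"gistic"},
    "network": {"genecn"},
    "survival": {"mcr", "gistic"},
}


@dataclass
class CohortResults:
    """Everything :meth:`CohortAnalysis.fit` computed."""

    config: PipelineConfig
    qc_table: pd.DataFrame | None = None
    segments: pd.DataFrame | None = None
    event_counts: pd.Series | None = None
    track: pd.DataFrame | None = None
    marker_samples: list | None = None
    marker_codes: np.ndarray | None = None
    marker_chroms: np.ndarray | None = None
    marker_positions: np.ndarray | None = None
    mcrs: list | None = None
    mcr_table: pd.DataFrame | None = None
    peaks: list | None = None
    peak_table: pd.DataFrame | None = None
    comparisons: dict = field(default_factory=dict)
    burden: dict = field(default_factory=dict)
    clusters: pd.Series | None = None
    enrichment_by_label: dict = field(default_factory=dict)
    gene_cn: pd.DataFrame | None = None
    concordance: pd.DataFrame | None = None
    pathway_enrichment: pd.DataFrame | None = None
    correlation: pd.DataFrame | None = None
    degree: network.DegreeDistribution | None = None
    network_ks: tuple | None = None
    survival_table: pd.DataFrame | None = None

    def plot_frequency_track(self, ax=None):
        from .plotting import plot_frequency_track

        if self.track is None:
            raise ValueError("no frequency track: run the 'track' stage first")
        return plot_frequency_track(self.track, ax=ax)

    def plot_degree_distribution(self, ax=None):
        from .plotting import plot_degree_distribution

        if self.degree is None:
            raise ValueError("no degree distribution: run the 'network' stage first")
        return plot_degree_distribution(self.degree, ax=ax)

    def summary(self) -> str:
        lines = ["Cohort copy-number analysis", "=" * 29]
        if self.qc_table is not None:
            n = len(self.qc_table)
            failed = int((~self.qc_table["pass"]).sum())
            lines.append(f"samples: {n} ({failed} failed MAPD QC)")
        if self.segments is not None:
            lines.append(f"segments: {len(self.segments)}")
        if self.event_counts is not None:
            lines.append(
                "events/tumor: mean %.1f sd %.1f"
                % (self.event_counts.mean(), self.event_counts.std(ddof=1))
            )
        for name, (t, p, (ma, sa), (mb, sb)) in self.burden.items():
            lines.append(
                f"burden {name}: {ma:.1f}±{sa:.1f} vs {mb:.1f}±{sb:.1f} "
                f"(Welch t={t:.2f}, p={p:.2g})"
            )
        if self.mcr_table is not None:
            sig = (self.mcr_table["stac_p"] < self.config.stac_p).sum()
            lines.append(f"MCRs: {len(self.mcr_table)} ({sig} at STAC p<{self.config.stac_p})")
        if self.peak_table is not None:
            lines.append(f"focal peaks (q<{self.config.gistic_q}): {len(self.peak_table)}")
        for name, comp in self.comparisons.items():
            lines.append(f"comparison {name}: {int(comp['significant'].sum())} significant markers")
        if self.clusters is not None:
            sizes = self.clusters.value_counts().sort_index()
            lines.append("clusters: " + ", ".join(f"{k}:{v}" for k, v in sizes.items()))
        if self.concordance is not None and len(self.concordance):
            ok = self.concordance["testable"].sum()
            lines.append(f"cis concordance: {ok} testable genes")
        if self.degree is not None:
            lines.append(
                f"network: max degree {int(self.degree.degrees.max()) if len(self.degree.degrees) else 0}, "
                f"log-log slope {self.degree.loglog_slope:.2f}"
            )
        if self.survival_table is not None and len(self.survival_table):
            sig = int(self.survival_table["significant"].sum())
            lines.append(f"survival associations at p<{self.config.survival_p}: {sig}")
        return "\n".join(lines)


class CohortAnalysis:
    """A cohort of copy-number profiles plus its annotation, ready to fit.

    Parameters
    ----------
    profiles : list of ProbeProfile
    clinical : optional DataFrame indexed by sample id (msi, stage, survival)
    expression : optional genes × samples DataFrame
    gene_models : optional list of GeneModel
    genome : Genome giving chromosome lengths and arm boundaries
    gene_sets : optional GeneSetCollection for pathway enrichment
    config : PipelineConfig; defaults used when omitted
    """

    def __init__(
        self,
        profiles,
        clinical=None,
        expression=None,
        gene_models=None,
        genome=None,
        gene_sets=None,
        config=None,
    ):
        if not profiles:
            raise ValueError("need at least one profile")
        self.profiles = list(profiles)
        self.clinical = clinical
        self.expression = expression
        self.gene_models = gene_models or []
        self.genome = genome
        self.gene_sets = gene_sets
        self.config = config or PipelineConfig()

    @classmethod
    def from_simulation(cls, sim, config=None) -> "CohortAnalysis":
        return cls(
            sim.profiles,
            clinical=sim.clinical,
            expression=sim.expression,
            gene_models=sim.gene_models,
            genome=sim.genome,
            config=config,
        )

    # ------------------------------------------------------------------
    def fit(self, stages=None, seed: int | None = None) -> CohortResults:
        """Run the requested stages (all by default) and return the results."""
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        wanted = self._resolve_stages(stages)
        res = CohortResults(config=cfg)
        thresholds = cfg.thresholds()

        profiles = self.profiles
        if "qc" in wanted:
            reports = [qc.qc_report(p, cfg.mapd_cutoff) for p in profiles]
            res.qc_table = pd.DataFrame(
                {
                    "sample": [r.sample_id for r in reports],
                    "mapd": [r.mapd for r in reports],
                    "pass": [r.pass_flag for r in reports],
                }
            )
            profiles = [p for p, r in zip(profiles, reports) if r.pass_flag]
            if not profiles:
                raise RuntimeError(
                    "stage qc: every sample failed the MAPD cutoff "
                    f"{cfg.mapd_cutoff}; nothing to analyze"
                )
        if "center" in wanted:
            profiles = [qc.center_profile(p) for p in profiles]
        if "segment" in wanted:
            tables = []
            for k, p in enumerate(profiles):
                tables.append(
                    cbs_segment(
                        p,
                        alpha=cfg.cbs_alpha,
                        n_perm=cfg.cbs_n_perm,
                        min_probes=cfg.cbs_min_probes,
                        merge_tol=cfg.cbs_merge_tol,
                        rank=cfg.cbs_rank,
                        genome=self.genome,
                        seed=seed + k,
                    )
                )
            res.segments = pd.concat(tables, ignore_index=True)
        if "classify" in wanted:
            res.segments = calling.classify_segments(res.segments, thresholds)
            res.event_counts = calling.event_count_table(res.segments, thresholds)
            ref = profiles[0]
            res.marker_chroms = ref.chroms
            res.marker_positions = ref.starts
            res.marker_samples, res.marker_codes = calling.marker_class_matrix(
                res.segments, ref.chroms, ref.starts, thresholds
            )
            if self.clinical is not None and "msi" in self.clinical.columns:
                res.burden.update(self._burden_tests(res.event_counts))
        if "track" in wanted:
            res.track = calling.frequency_track(
                res.marker_chroms, res.marker_positions, res.marker_codes
            )
        if "mcr" in wanted:
            res.mcrs = recurrence.find_mcrs(
                res.track, res.marker_samples, res.marker_codes, cfg.mcr_min_freq
            )
            recurrence.score_mcrs(
                res.mcrs,
                res.track,
                res.marker_samples,
                res.marker_codes,
                n_perm=cfg.stac_n_perm,
                seed=seed,
            )
            res.mcr_table = recurrence.mcr_table(res.mcrs)
        if "gistic" in wanted:
            res.peaks, res.peak_table = self._gistic(res, seed)
        if "compare" in wanted:
            res.comparisons.update(self._comparisons(res))
        if "genecn" in wanted:
            if self.gene_models:
                res.gene_cn = dosage.gene_level_cn(res.segments, self.gene_models)
        if "cluster" in wanted and res.gene_cn is not None:
            chrom_of = {g.gene_id: g.interval.chromosome for g in self.gene_models}
            auto = [g for g in res.gene_cn.index if chrom_of[g] not in SEX_CHROMOSOMES]
            res.clusters = compare.cluster_cohort(
                res.gene_cn.loc[auto].dropna(),
                k=cfg.cluster_k,
                gene_chromosomes=chrom_of,
                metric=cfg.cluster_metric,
            )
            if self.clinical is not None:
                for col in ("brafm_like", "braf_mut", "kras_mut", "msi", "stage"):
                    if col in self.clinical.columns:
                        labels = self.clinical[col].reindex(res.clusters.index)
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            res.enrichment_by_label[col] = compare.label_enrichment(
                                res.clusters, labels
                            )
        if "concordance" in wanted and res.gene_cn is not None and self.expression is not None:
            res.concordance = self._concordance(res, thresholds)
        if "enrich" in wanted and self.gene_sets is not None and res.peaks:
            hit_genes = sorted(
                {g for p in res.peaks if p.direction == "amp" for g in p.genes}
            )
            universe = [g.gene_id for g in self.gene_models]
            if hit_genes:
                res.pathway_enrichment = dosage.pathway_enrichment(
                    hit_genes,
                    self.gene_sets,
                    universe,
                    n_perm=cfg.perm_fdr_n,
                    size_bounds=cfg.set_size,
                    seed=seed,
                )
        if "network" in wanted and res.gene_cn is not None:
            chrom_of = {g.gene_id: g.interval.chromosome for g in self.gene_models}
            res.correlation = network.pairwise_correlations(res.gene_cn)
            graph = network.edge_graph(
                res.correlation, chrom_of, cfg.r_threshold, unlinked_only=True
            )
            res.degree = network.degree_distribution(graph)
            _, ks, ks_p = network.randomization_null(
                res.gene_cn,
                chrom_of,
                n_perm=cfg.network_n_perm,
                r_threshold=cfg.r_threshold,
                seed=seed,
            )
            res.network_ks = (ks, ks_p)
        if "survival" in wanted and self.clinical is not None and "os_time" in self.clinical.columns:
            res.survival_table = self._survival(res)
        return res

    # ------------------------------------------------------------------
    def _resolve_stages(self, stages):
        if stages is None:
            return set(_STAGES)
        wanted = set(stages)
        unknown = wanted - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        # close over dependencies
        changed = True
        while changed:
            changed = False
            for s in list(wanted):
                for d in _DEPS.get(s, ()):
                    if d not in wanted:
                        wanted.add(d)
                        changed = True
        return wanted

    def _burden_tests(self, counts):
        out = {}
        cl = self.clinical
        msi_ids = cl.index[cl["msi"] == "MSI"].intersection(counts.index)
        mss_ids = cl.index[cl["msi"] == "MSS"].intersection(counts.index)
        if len(msi_ids) >= 2 and len(mss_ids) >= 2:
            out["MSS_vs_MSI"] = compare.burden_ttest(counts[mss_ids], counts[msi_ids])
        return out

    def _comparisons(self, res):
        out = {}
        if self.clinical is None:
            return out
        samples = np.asarray(res.marker_samples, dtype=object)
        cl = self.clinical.reindex(samples)
        pairs = [("msi", "MSI", "MSS"), ("stage", "III", "II")]
        for col, a, b in pairs:
            if col not in cl.columns:
                continue
            mask_a = (cl[col] == a).to_numpy()
            mask_b = (cl[col] == b).to_numpy()
            if mask_a.sum() == 0 or mask_b.sum() == 0:
                continue
            for direction in ("gain", "loss"):
                comp = compare.compare_frequencies(
                    res.marker_codes[mask_a],
                    res.marker_codes[mask_b],
                    res.marker_chroms,
                    res.marker_positions,
                    direction=direction,
                    diff_threshold=self.config.compare_diff,
                    p_threshold=self.config.compare_p,
                )
                out[f"{a}_vs_{b}_{direction}"] = comp
        return out

    def _gistic(self, res, seed):
        cfg = self.config
        _, marker_cn = calling.marker_value_matrix(
            res.segments, res.marker_chroms, res.marker_positions
        )
        amp, dele = gistic.focal_component(
            res.marker_chroms, res.marker_positions, marker_cn, self.genome
        )
        peaks = []
        for direction, amps in (("amp", amp), ("del", dele)):
            _, pooled = gistic.gscore_and_q(
                res.marker_chroms, amps, n_perm=cfg.gistic_n_perm, seed=seed
            )
            peaks.extend(
                gistic.call_peaks(
                    res.marker_chroms,
                    res.marker_positions,
                    amps,
                    pooled,
                    direction,
                    q_cutoff=cfg.gistic_q,
                    genes=self.gene_models,
                )
            )
        return peaks, gistic.peak_table(peaks)

    def _concordance(self, res, thresholds):
        common_genes = res.gene_cn.index.intersection(self.expression.index)
        common_samples = res.gene_cn.columns.intersection(self.expression.columns)
        rows = []
        for g in common_genes:
            r = dosage.cis_concordance(
                g,
                res.gene_cn.loc[g, common_samples],
                self.expression.loc[g, common_samples],
                thresholds,
            )
            rows.append(r)
        return dosage.concordance_table(rows)

    def _survival(self, res):
        carriers = {}
        sign_of = {"gain": 1, "loss": -1, "amp": 1, "del": -1}
        samples = np.asarray(res.marker_samples, dtype=object)
        regions = []
        if res.mcrs:
            regions.extend(
                (f"MCR_{r.direction}_{r.interval}", r.direction, r.interval, r.member_samples)
                for r in res.mcrs
            )
        if res.peaks:
            for p in res.peaks:
                mid = p.interval.midpoint
                on = (res.marker_chroms == p.interval.chromosome) & (
                    np.abs(res.marker_positions - mid)
                    == np.min(
                        np.abs(
                            res.marker_positions[
                                res.marker_chroms == p.interval.chromosome
                            ]
                            - mid
                        )
                    )
                )
                m = int(np.flatnonzero(on)[0])
                carrier = np.sign(res.marker_codes[:, m]) == sign_of[p.direction]
                regions.append(
                    (f"peak_{p.direction}_{p.interval}", p.direction, p.interval, list(samples[carrier]))
                )
        for name, _, _, members in regions:
            carriers[name] = members
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return survival.scan_regions(
                carriers, self.clinical, p_threshold=self.config.survival_p
            )
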