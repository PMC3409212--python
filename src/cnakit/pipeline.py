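"""End-to-end orchestration: run every stage and write the result tables.

Tables are plain tab-delimited files with '#'-prefixed metadata header lines;
a ``manifest.json`` records the configuration, seeds and per-table row
counts so a run can be verified and reproduced exactly.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .io import write_seg
from .model import CohortAnalysis

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "write_table"]


def write_table(path, df: pd.DataFrame, meta: dict | None = None, index=False):
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def run_pipeline(
    analysis: CohortAnalysis,
    out_dir,
    seed: int | None = None,
    stages=None,
) -> dict:
    """Fit the cohort model and write every result table under ``out_dir``.

    Returns the manifest dictionary.  Any stage failure aborts with the
    stage name attached.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = analysis.config
    seed = cfg.seed if seed is None else seed
    t0 = time.time()
    try:
        res = analysis.fit(stages=stages, seed=seed)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    meta = {"cnakit": __version__, "seed": seed}
    manifest = {"version": __version__, "seed": seed, "config": json.loads(cfg.to_json()), "tables": {}}

    def emit(name, df, index=False):
        if df is None or (hasattr(df, "__len__") and len(df) == 0):
            return
        write_table(out / f"{name}.tsv", df, meta, index=index)
        manifest["tables"][name] = len(df)

    if res.qc_table is not None:
        emit("qc", res.qc_table)
    if res.segments is not None:
        write_seg(out / "segments.seg", res.segments)
        manifest["tables"]["segments"] = len(res.segments)
    if res.event_counts is not None:
        emit("event_counts", res.event_counts.rename("n_events").to_frame(), index=True)
    emit("frequency_track", res.track)
    emit("mcrs", res.mcr_table)
    emit("gistic_peaks", res.peak_table)
    for name, comp in res.comparisons.items():
        emit(f"compare_{name}", comp)
    if res.clusters is not None:
        emit("clusters", res.clusters.to_frame(), index=True)
    for label, table in res.enrichment_by_label.items():
        emit(f"cluster_enrichment_{label}", table)
    if res.gene_cn is not None:
        emit("gene_cn", res.gene_cn, index=True)
    emit("concordance", res.concordance)
    emit("pathway_enrichment", res.pathway_enrichment)
    if res.degree is not None:
        emit("degree", res.degree.degrees.to_frame(), index=True)
    emit("survival", res.survival_table)

    runtime = round(time.time() - t0, 2)
    if res.burden:
        manifest["burden"] = {
            k: {"t": v[0], "p": v[1], "group_a": v[2], "group_b": v[3]}
            for k, v in res.burden.items()
        }
    if res.network_ks is not None:
        manifest["network_ks"] = {"stat": res.network_ks[0], "p": res.network_ks[1]}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("pipeline finished in %.1fs: %s", runtime, out)
    return manifest
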