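"""Kaplan-Meier / log-rank association of recurrent regions with outcome.

Every region (MCR or focal peak) defines a carrier group — samples whose
copy-number class at the region matches the region's direction — and each
region × endpoint (OS, RFS) × stage stratum (II, III, combined) combination
is tested with the standard two-group log-rank statistic.  Unadjusted
p-values at the 0.01 cutoff are reported, with a Benjamini-Hochberg column
alongside because a genome-wide scan is heavily multiple.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from statsmodels.stats.multitest import multipletests

__all__ = ["km_logrank", "scan_regions", "km_curves"]


@dataclass
class LogrankResult:
    p: float
    statistic: float
    direction: str  # 'carrier_better' or 'carrier_worse'
    carrier_n: int
    noncarrier_n: int


def km_logrank(carrier, times, events) -> LogrankResult:
    """Two-group log-rank test with carrier direction.

    ``direction`` is read from the sign of observed-minus-expected events in
    the carrier group: fewer events than expected means carriers fare better.
    """
    carrier = np.asarray(carrier, dtype=bool)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if carrier.all() or not carrier.any():
        raise ValueError("both carrier and non-carrier groups must be non-empty")
    if events.sum() == 0:
        raise ValueError("no events observed; the log-rank test is undefined")
    res = logrank_test(
        times[carrier], times[~carrier], events[carrier], events[~carrier]
    )
    o_minus_e = _observed_minus_expected(carrier, times, events)
    direction = "carrier_better" if o_minus_e < 0 else "carrier_worse"
    return LogrankResult(
        float(res.p_value),
        float(res.test_statistic),
        direction,
        int(carrier.sum()),
        int((~carrier).sum()),
    )


def _observed_minus_expected(carrier, times, events):
    """Sum over event times of (observed - expected) carrier events."""
    order = np.argsort(times)
    t, e, c = times[order], events[order], carrier[order]
    n = t.size
    o_minus_e = 0.0
    at_risk_total = n
    at_risk_carrier = int(c.sum())
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = int(e[i:j].sum())
        if d > 0 and at_risk_total > 0:
            d_carrier = int((e[i:j] & c[i:j].astype(int)).sum())
            o_minus_e += d_carrier - d * at_risk_carrier / at_risk_total
        at_risk_total -= j - i
        at_risk_carrier -= int(c[i:j].sum())
        i = j
    return o_minus_e


def km_curves(carrier, times, events) -> pd.DataFrame:
    """Kaplan-Meier survival coordinates for the two groups."""
    carrier = np.asarray(carrier, dtype=bool)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    frames = []
    for name, mask in (("carrier", carrier), ("noncarrier", ~carrier)):
        if not mask.any():
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=name)
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        sf["group"] = name
        frames.append(sf)
    return pd.concat(frames, ignore_index=True)


def scan_regions(
    region_carriers: dict,
    clinical: pd.DataFrame,
    endpoints: tuple = ("os", "rfs"),
    strata: tuple = ("II", "III", "combined"),
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Log-rank scan of every region × endpoint × stage stratum.

    ``region_carriers`` maps region name -> list of carrier sample ids.
    ``clinical`` is indexed by sample id with ``stage`` and per-endpoint
    ``*_time`` / ``*_event`` columns.  Degenerate combinations (one-sided
    grouping or no events) are skipped with a warning.
    """
    rows = []
    for region, carriers in region_carriers.items():
        carrier_set = set(carriers)
        for endpoint in endpoints:
            tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
            if tcol not in clinical.columns:
                continue
            for stratum in strata:
                sub = (
                    clinical
                    if stratum == "combined"
                    else clinical[clinical["stage"] == stratum]
                )
                sub = sub.dropna(subset=[tcol, ecol])
                if sub.empty:
                    continue
                carrier = sub.index.isin(carrier_set)
                try:
                    res = km_logrank(
                        carrier, sub[tcol].to_numpy(), sub[ecol].to_numpy()
                    )
                except ValueError as exc:
                    warnings.warn(
                        f"{region}/{endpoint}/{stratum} skipped: {exc}"
                    )
                    continue
                rows.append(
                    {
                        "region": region,
                        "endpoint": endpoint.upper(),
                        "stratum": stratum,
                        "logrank_p": res.p,
                        "direction": res.direction,
                        "carrier_n": res.carrier_n,
                        "noncarrier_n": res.noncarrier_n,
                    }
                )
    out = pd.DataFrame(
        rows,
        columns=[
            "region",
            "endpoint",
            "stratum",
            "logrank_p",
            "direction",
            "carrier_n",
            "noncarrier_n",
        ],
    )
    if not out.empty:
        out["logrank_p_bh"] = multipletests(out["logrank_p"], method="fdr_bh")[1]
        out["significant"] = out["logrank_p"] < p_threshold
    return out
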