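import numpy as np
import pandas as pd
import pytest

from cnakit.genome import Genome
from cnakit.io import ProbeProfile
from cnakit.simulate import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def genome():
    return Genome.miniature()


@pytest.fixture(scope="session")
def small_sim():
    """A small mixed cohort shared by read-only tests."""
    return simulate_cohort(CohortSpec.default_combined(n_mss=40, n_msi=10), seed=11)


def make_profile(values, chrom="1", sample_id="S1", spacing=50_000):
    """One-chromosome profile on a uniform grid."""
    values = np.asarray(values, dtype=float)
    starts = np.arange(values.size, dtype=np.int64) * spacing + spacing // 2
    chroms = np.full(values.size, chrom, dtype=object)
    return ProbeProfile(sample_id, chroms, starts, values)


def make_segments(rows):
    """Segment table from (sample, chrom, start, end, n_probes, mean_cn) tuples."""
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "n_probes", "mean_cn"]
    )
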