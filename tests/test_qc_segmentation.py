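"""MAPD quality control, centering, and change-point detection."""

import numpy as np
import pytest

from cnakit.io import ProbeProfile
from cnakit.qc import center_profile, mapd, qc_report
from cnakit.segmentation import cbs_segment, max_arc_statistic

from conftest import make_profile


class TestMapd:
    def test_constant_profile_is_zero(self):
        assert mapd(make_profile([2.0] * 10)) == 0.0

    def test_hand_enumerated_alternating_profile(self):
        # diffs: 0.4, 0.4, 0.4, 0.4 -> median 0.4
        assert mapd(make_profile([2.0, 2.4, 2.0, 2.4, 2.0])) == pytest.approx(0.4)

    def test_differences_do_not_span_chromosomes(self):
        chroms = np.array(["1", "1", "2", "2"], dtype=object)
        starts = np.array([0, 50_000, 0, 50_000])
        values = np.array([2.0, 2.0, 10.0, 10.0])
        p = ProbeProfile("S1", chroms, starts, values)
        assert mapd(p) == 0.0  # the 2->10 jump is across a boundary

    def test_noisy_sample_fails_cutoff(self):
        # alternating +-0.35 gives every |diff| = 0.7 > 0.6
        vals = 2.0 + 0.35 * np.array([1, -1] * 50)
        rep = qc_report(make_profile(vals), cutoff=0.6)
        assert rep.mapd == pytest.approx(0.7)
        assert not rep.pass_flag

    def test_too_few_probes_rejected(self):
        with pytest.raises(ValueError, match=">= 2 probes"):
            mapd(make_profile([2.0]))


class TestCentering:
    def test_uniform_offset_removed(self):
        rng = np.random.default_rng(0)
        vals = 2.3 + rng.normal(0, 0.05, 500)
        centered = center_profile(make_profile(vals))
        assert abs(np.median(centered.values) - 2.0) < 0.05

    def test_mode_anchors_majority_cluster(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate(
            [2.5 + rng.normal(0, 0.05, 300), 3.5 + rng.normal(0, 0.05, 200)]
        )
        centered = center_profile(make_profile(vals))
        # the 60% cluster is moved to 2.0; the 40% cluster lands near 3.0
        assert abs(np.median(centered.values[:300]) - 2.0) < 0.1
        assert abs(np.median(centered.values[300:]) - 3.0) < 0.1

    def test_neutral_baseline_leaves_profile_unchanged(self):
        rng = np.random.default_rng(2)
        vals = 2.0 + rng.normal(0, 0.05, 200)
        prof = make_profile(vals)
        normals = [make_profile(np.full(200, 2.0), sample_id=f"N{i}") for i in range(5)]
        out = center_profile(prof, normal_baseline=normals)
        ref = center_profile(prof)
        assert np.allclose(out.values, ref.values, atol=1e-9)

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            center_profile(make_profile([2.0] * 10), normal_baseline=[])


def naive_max_split(x):
    """Independent exhaustive oracle over all arcs, plain double loop."""
    x = np.asarray(x, dtype=float)
    n = x.size
    d = np.abs(np.diff(x))
    kth = (d.size - 1) // 4
    q25 = float(np.partition(d, kth)[kth]) / 0.45049
    med = float(np.median(d)) / 0.95387
    sigma = max(q25, 0.5 * med)
    if sigma == 0:
        sigma = max(1e-3 * x.std(), 1e-12)
    best, bi, bj = -1.0, 0, n
    for i in range(n):
        for j in range(i + 1, n + 1):
            k = j - i
            if k == n:
                continue
            inside = x[i:j].mean()
            outside = (x.sum() - x[i:j].sum()) / (n - k)
            t = abs(inside - outside) / (sigma * np.sqrt(1 / k + 1 / (n - k)))
            if t > best:
                best, bi, bj = t, i, j
    return best, bi, bj


class TestCbs:
    def test_pure_noise_yields_single_segment(self):
        rng = np.random.default_rng(3)
        p = make_profile(2.0 + rng.normal(0, 0.15, 200))
        seg = cbs_segment(p, alpha=1e-6)
        assert len(seg) == 1

    def test_step_breakpoint_localized_and_matches_oracle(self):
        rng = np.random.default_rng(4)
        vals = np.concatenate([np.full(50, 2.0), np.full(50, 3.0)])
        vals += rng.normal(0, 0.1, 100)
        t_imp, i_imp, j_imp = max_arc_statistic(vals)
        t_orc, i_orc, j_orc = naive_max_split(vals)
        assert t_imp == pytest.approx(t_orc, rel=1e-9)
        assert {c for c in (i_imp, j_imp) if 0 < c < 100} == {
            c for c in (i_orc, j_orc) if 0 < c < 100
        }
        seg = cbs_segment(make_profile(vals), alpha=1e-6)
        assert len(seg) == 2
        # breakpoint within +-2 probes of the planted step at probe 50
        cut = seg.iloc[0]["end"]
        assert abs(cut / 50_000 - 50) <= 2

    def test_focal_amplicon_recovered_as_three_segments(self):
        rng = np.random.default_rng(5)
        vals = np.full(100, 2.0)
        vals[45:55] = 5.0
        vals += rng.normal(0, 0.1, 100)
        seg = cbs_segment(make_profile(vals), alpha=1e-6)
        assert len(seg) == 3
        assert abs(seg.iloc[1]["mean_cn"] - 5.0) < 0.2

    def test_oracle_agreement_on_random_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            n = int(rng.integers(20, 120))
            x = 2.0 + rng.normal(0, 0.2, n)
            x[: int(rng.integers(3, n // 2))] += rng.choice([-1.0, 1.0])
            t_imp, i_imp, j_imp = max_arc_statistic(x)
            t_orc, i_orc, j_orc = naive_max_split(x)
            assert t_imp == pytest.approx(t_orc, rel=1e-9)
            # an arc and its complement induce the same partition (tied t)
            cuts_imp = {c for c in (i_imp, j_imp) if 0 < c < n}
            cuts_orc = {c for c in (i_orc, j_orc) if 0 < c < n}
            assert cuts_imp == cuts_orc

    def test_segment_means_reconstruct_probe_mean(self):
        rng = np.random.default_rng(7)
        vals = np.concatenate([np.full(60, 2.0), np.full(40, 3.2)])
        vals += rng.normal(0, 0.1, 100)
        p = make_profile(vals)
        seg = cbs_segment(p, alpha=1e-6)
        weighted = np.average(seg["mean_cn"], weights=seg["n_probes"])
        assert weighted == pytest.approx(vals.mean(), abs=1e-9)

    def test_more_stringent_alpha_never_adds_segments(self):
        rng = np.random.default_rng(8)
        vals = np.full(150, 2.0)
        vals[30:60] += 1.0
        vals[100:110] -= 1.0
        vals += rng.normal(0, 0.2, 150)
        counts = [
            len(cbs_segment(make_profile(vals), alpha=a, seed=0))
            for a in (1e-2, 1e-4, 1e-6, 1e-9)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            cbs_segment(make_profile([2.0] * 10), alpha=0.0)

    def test_short_chromosome_returns_single_segment(self):
        seg = cbs_segment(make_profile([2.0, 3.0]), alpha=1e-6, min_probes=3)
        assert len(seg) == 1
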