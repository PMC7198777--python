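"""Read trimming, depth ingestion, marker-ratio profiles, origin calls."""

import numpy as np
import pytest

from repliskew import (DepthProfile, ReadRecord, ReplicationModel, TrimParams,
                       depth_from_bedgraph, detect_origin, mfa_ratio,
                       ori_ter_ratio, simulate_depth_profiles, trim_reads)
from repliskew.genome import circular_distance

from conftest import noiseless_depth_pair


def _read(length, phred):
    return ReadRecord("A" * length, tuple([phred] * length))


class TestTrimReads:
    def test_end_clips_leave_99_of_116_discarded(self):
        # 116 - 15 - 2 = 99 < 100: discarded despite perfect quality
        retained, qc = trim_reads([_read(116, 40)])
        assert retained == []
        assert qc["retained_fraction"] == 0.0

    def test_200nt_perfect_read_keeps_183(self):
        retained, _ = trim_reads([_read(200, 40)])
        assert len(retained) == 1
        assert len(retained[0]) == 200 - 15 - 2

    def test_low_quality_tail_trimmed(self):
        quals = [40] * 150 + [2] * 40
        read = ReadRecord("A" * 190, tuple(quals))
        retained, _ = trim_reads([read])
        assert len(retained) == 1
        # 15 clipped from 5' leaves 135 high-quality bases before the bad tail
        assert len(retained[0]) == 135

    def test_empty_input(self):
        retained, qc = trim_reads([])
        assert retained == [] and qc["n_in"] == 0

    def test_matches_exhaustive_per_read_oracle(self):
        """Retained segments equal an independent O(n^2) best-segment search."""
        rng = np.random.default_rng(31)
        params = TrimParams(min_phred=30, trim_5prime=15, trim_3prime=2,
                            min_length=50)
        limit = 10.0 ** (-params.min_phred / 10.0)
        reads = []
        for _ in range(60):
            n = int(rng.integers(80, 220))
            quals = rng.integers(2, 41, size=n)
            reads.append(ReadRecord("A" * n, tuple(int(q) for q in quals)))
        retained, _ = trim_reads(reads, params)
        expected = []
        for read in reads:
            quals = np.asarray(read.qualities[15:len(read) - 2], dtype=float)
            if len(quals) < params.min_length:
                continue
            delta = limit - 10.0 ** (-quals / 10.0)
            pre = np.concatenate([[0.0], np.cumsum(delta)])
            best = (0.0, 0, 0)  # (sum, length, start) maximized lexicographically
            for i in range(len(quals)):
                for j in range(i + 1, len(quals) + 1):
                    s = pre[j] - pre[i]
                    cand = (s, j - i, i)
                    if (s > best[0]
                            or (s == best[0] and j - i > best[1])):
                        best = cand
            if best[1] >= params.min_length:
                expected.append(read.bases[15 + best[2]:15 + best[2] + best[1]])
        assert [r.bases for r in retained] == expected


class TestDepthFromBedgraph:
    def test_single_interval_single_window(self, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chr\t0\t1000\t500\n")
        profile = depth_from_bedgraph(p, 10_000, window=1000)
        assert profile.counts[0] == 500
        assert profile.counts[1:].sum() == 0
        assert profile.total_reads == 500

    def test_pro_rata_split_matches_per_base_expansion(self, tmp_path):
        p = tmp_path / "b.bedgraph"
        # interval straddling windows 0/1 plus another fully inside window 1
        p.write_text("chr\t500\t1500\t300\nchr\t1500\t1800\t90\n")
        profile = depth_from_bedgraph(p, 10_000, window=1000)
        base = np.zeros(10_000)
        base[500:1500] += 300 / 1000
        base[1500:1800] += 90 / 300
        expected = base.reshape(10, 1000).sum(axis=1)
        np.testing.assert_allclose(profile.counts, expected, atol=1e-9)

    def test_empty_file_flagged(self, tmp_path):
        p = tmp_path / "c.bedgraph"
        p.write_text("# nothing\n")
        profile = depth_from_bedgraph(p, 10_000, window=1000)
        assert profile.counts.sum() == 0
        assert profile.qc_flags.get("empty_input")

    def test_out_of_range_interval_names_line(self, tmp_path):
        p = tmp_path / "d.bedgraph"
        p.write_text("chr\t0\t1000\t5\nchr\t9000\t11000\t5\n")
        with pytest.raises(ValueError, match=":2"):
            depth_from_bedgraph(p, 10_000, window=1000)


class TestMFARatio:
    def test_identical_samples_give_unit_ratio(self):
        counts = np.random.default_rng(1).poisson(500, 3000).astype(float)
        exp = DepthProfile(1000, counts, counts.sum(), 3_000_000, "exponential")
        stat = DepthProfile(1000, counts.copy(), counts.sum(), 3_000_000, "stationary")
        profile = mfa_ratio(exp, stat)
        np.testing.assert_allclose(profile.fine_values, 1.0, atol=1e-12)
        np.testing.assert_allclose(profile.coarse_values, 1.0, atol=1e-12)

    def test_normalization_invariance_under_count_scaling(self):
        rng = np.random.default_rng(2)
        c1 = rng.poisson(500, 3000).astype(float)
        c2 = rng.poisson(500, 3000).astype(float)
        exp = DepthProfile(1000, c1, c1.sum(), 3_000_000, "exponential")
        stat = DepthProfile(1000, c2, c2.sum(), 3_000_000, "stationary")
        base = mfa_ratio(exp, stat)
        exp2 = DepthProfile(1000, 7 * c1, 7 * c1.sum(), 3_000_000, "exponential")
        scaled = mfa_ratio(exp2, stat)
        np.testing.assert_allclose(scaled.fine_values, base.fine_values, rtol=1e-12)
        np.testing.assert_allclose(scaled.coarse_values, base.coarse_values, rtol=1e-12)

    def test_zero_stationary_windows_masked(self):
        c1 = np.full(3000, 500.0)
        c2 = np.full(3000, 500.0)
        c2[10] = 0
        exp = DepthProfile(1000, c1, c1.sum(), 3_000_000, "exponential")
        stat = DepthProfile(1000, c2, c2.sum(), 3_000_000, "stationary")
        profile = mfa_ratio(exp, stat)
        assert profile.fine_mask[10]
        assert np.isnan(profile.fine_values[10])
        assert not profile.coarse_mask.any()  # coarse window still has counts

    def test_simulated_ratio_recovers_one_plus_r(self, single_origin_profiles):
        exp, stat = single_origin_profiles
        profile = mfa_ratio(exp, stat)
        ratio = ori_ter_ratio(profile, 0)
        # coarse windows hold ~100*500 counts; allow 3 SE plus window-average bias
        se = np.sqrt(2 * 2 / (100 * 500))
        assert ratio == pytest.approx(1.5, abs=3 * se + 0.04)

    def test_mismatched_grids_rejected(self):
        a = DepthProfile(1000, np.ones(3000), 3000, 3_000_000)
        b = DepthProfile(1000, np.ones(2000), 2000, 2_000_000)
        with pytest.raises(ValueError):
            mfa_ratio(a, b)


class TestDetectOrigin:
    def test_noiseless_v_profile(self):
        model = ReplicationModel("single_origin", 3_000_000, ori_position=1_550_000,
                                 replicating_fraction=0.4)
        exp, stat = noiseless_depth_pair(model, 1000)
        profile = mfa_ratio(exp, stat)
        call = detect_origin(profile, seed=0)
        assert call.mode == "single_origin_V"
        assert circular_distance(call.origin_position, 1_550_000, 3_000_000) <= 10_000

    def test_rotation_equivariance(self):
        calls = []
        for ori in (0, 1_200_000):
            model = ReplicationModel("single_origin", 3_000_000, ori_position=ori,
                                     replicating_fraction=0.3, seed=5)
            exp, stat = noiseless_depth_pair(model, 1000)
            calls.append(detect_origin(mfa_ratio(exp, stat), seed=0))
        shift = circular_distance(calls[1].origin_position - 1_200_000,
                                  calls[0].origin_position, 3_000_000)
        assert shift <= 10_000
        assert calls[1].peak_trough_ratio == pytest.approx(
            calls[0].peak_trough_ratio, rel=1e-6)

    def test_flat_profile_classified_flat(self):
        model = ReplicationModel("multi_origin_async", 3_000_000, seed=3)
        exp, stat = simulate_depth_profiles(model, 1000, 500.0)
        call = detect_origin(mfa_ratio(exp, stat), seed=3)
        assert call.mode == "flat_multi_origin"
        assert call.p_flat > 0.05

    @pytest.mark.parametrize("r", [0.1, 0.3, 0.5])
    def test_replicating_fraction_recovered_by_peak_trough_ratio(self, r):
        """Median (peak_trough_ratio - 1) estimates r within 20% relative."""
        ptrs = []
        for seed in range(10):
            model = ReplicationModel("single_origin", 3_000_000, ori_position=0,
                                     replicating_fraction=r, seed=seed)
            exp, stat = simulate_depth_profiles(model, 1000, 500.0)
            call = detect_origin(mfa_ratio(exp, stat), seed=seed, n_bootstrap=20)
            ptrs.append(call.peak_trough_ratio)
        median = float(np.median(ptrs))
        assert abs((median - 1 - r) / r) <= 0.20

    def test_too_few_coarse_windows_rejected(self):
        model = ReplicationModel("single_origin", 1_000_000,
                                 replicating_fraction=0.3)
        exp, stat = noiseless_depth_pair(model, 1000)
        with pytest.raises(ValueError):
            detect_origin(mfa_ratio(exp, stat))  # only 10 coarse windows

    def test_heavily_masked_profile_indeterminate(self):
        c1 = np.full(3000, 500.0)
        c2 = np.full(3000, 500.0)
        c2[:900] = 0  # 30% of stationary windows empty
        exp = DepthProfile(1000, c1, c1.sum(), 3_000_000)
        stat = DepthProfile(1000, c2, c2.sum(), 3_000_000, "stationary")
        call = detect_origin(mfa_ratio(exp, stat), seed=0)
        assert call.mode == "indeterminate"
        assert call.origin_position is None


class TestOriTerRatio:
    def test_unit_profile_gives_one(self):
        counts = np.full(3000, 400.0)
        exp = DepthProfile(1000, counts, counts.sum(), 3_000_000)
        stat = DepthProfile(1000, counts.copy(), counts.sum(), 3_000_000, "stationary")
        assert ori_ter_ratio(mfa_ratio(exp, stat), 0) == 1.0

    def test_noiseless_oracle_equivalence_single_origin(self):
        """Machine-precision match to (1+r)/1 when ori sits at a window center."""
        model = ReplicationModel("single_origin", 3_000_000, ori_position=50_000,
                                 replicating_fraction=0.37)
        exp, stat = noiseless_depth_pair(model, 100_000)
        profile = mfa_ratio(exp, stat, coarse_window=100_000)
        assert ori_ter_ratio(profile, 50_000) == pytest.approx(1.37, abs=1e-12)

    def test_noiseless_oracle_equivalence_multifork(self):
        model = ReplicationModel("multifork", 3_000_000, ori_position=50_000,
                                 fork_intensity=1.5)
        exp, stat = noiseless_depth_pair(model, 100_000)
        profile = mfa_ratio(exp, stat, coarse_window=100_000)
        assert ori_ter_ratio(profile, 50_000) == pytest.approx(2 ** 1.5, rel=1e-12)

    def test_masked_antipode_uses_nearest_neighbor(self):
        c1 = np.full(3000, 500.0)
        c2 = np.full(3000, 500.0)
        c2[1500:1600] = 0  # kill the antipodal coarse window entirely
        exp = DepthProfile(1000, c1, c1.sum(), 3_000_000)
        stat = DepthProfile(1000, c2, c2.sum(), 3_000_000, "stationary")
        profile = mfa_ratio(exp, stat)
        assert ori_ter_ratio(profile, 0) == 1.0
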