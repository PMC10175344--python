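"""Copy-number calling: log intensities, reference fit, binning, CBS, calls."""

import numpy as np
import pandas as pd
import pytest

from methclass import (
    CNVParams,
    total_log_intensity,
    fit_reference,
    bin_genome,
    bin_ratios,
    segment_cbs,
    call_states,
    call_cnv,
    generate_manifest,
)
from methclass.cnv import _max_circular_t
from methclass.containers import GenomicBin, GAIN, LOSS, NEUTRAL
from conftest import make_manifest, make_matrix, simple_config


def naive_best_circular_split(x, min_seg_bins=2):
    """Independent brute-force maximizer of the circular two-segment |t|.

    Arcs starting at index 0 are skipped: on a circle ``x[0:k]`` versus
    the rest is the same partition as ``x[k:n]`` versus the rest, so
    scanning ``i >= 1`` visits every two-arc partition exactly once.
    """
    x = np.asarray(x, float)
    n = len(x)
    best = (-1.0, None, None)
    for i in range(1, n + 1):
        for j in range(i + min_seg_bins, n + 1):
            n1 = j - i
            n2 = n - n1
            if n2 < min_seg_bins:
                continue
            seg = x[i:j]
            rest = np.concatenate([x[:i], x[j:]])
            pooled = (np.sum((seg - seg.mean()) ** 2) + np.sum((rest - rest.mean()) ** 2))
            s2 = pooled / (n - 2)
            if s2 == 0:
                t = np.inf if seg.mean() != rest.mean() else 0.0
            else:
                t = abs(seg.mean() - rest.mean()) / np.sqrt(s2 * (1 / n1 + 1 / n2))
            if t > best[0]:
                best = (t, i, j)
    return best


class TestTotalLogIntensity:
    def test_closed_forms(self):
        m = make_matrix(["p1", "p2"], {"s": ([0, 1000], [0, 23])})
        out = total_log_intensity(m)["s"]
        assert out.iloc[0] == 0.0
        assert out.iloc[1] == 10.0  # log2(1024)

    def test_doubling_adds_one_in_large_intensity_limit(self):
        vals = np.array([1e4, 5e4, 2e5])
        m1 = make_matrix(["a", "b", "c"], {"s": (vals, vals)})
        m2 = make_matrix(["a", "b", "c"], {"s": (2 * vals, 2 * vals)})
        d = total_log_intensity(m2)["s"] - total_log_intensity(m1)["s"]
        assert np.allclose(d, 1.0, atol=0.001)


class TestFitReference:
    def test_query_identical_to_reference_gives_zero(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(12, 1, (500, 3))
        ratios = fit_reference(ref[:, 0], ref)
        assert np.allclose(ratios, 0.0, atol=1e-10)

    def test_constant_shift_absorbed_by_intercept(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(12, 1, (500, 2))
        ratios = fit_reference(ref[:, 0] + 3.7, ref)
        assert np.allclose(ratios, 0.0, atol=1e-10)

    def test_arm_shift_recovered(self):
        rng = np.random.default_rng(2)
        n = 5000
        base = rng.normal(12, 1, n)
        refs = np.column_stack([base + rng.normal(0, 0.05, n) for _ in range(4)])
        query = base + rng.normal(0, 0.05, n)
        arm = np.zeros(n)
        arm[: n // 10] = 0.4  # one "arm" = 10% of probes
        ratios = fit_reference(query + arm, refs)
        global_shift = np.median(ratios[n // 10:])
        recovered = np.median(ratios[: n // 10]) - global_shift
        assert recovered == pytest.approx(0.4, abs=0.05)

    def test_non_negative_fit_recovers_shift_too(self):
        rng = np.random.default_rng(5)
        n = 2000
        base = rng.normal(12, 1, n)
        refs = np.column_stack([base + rng.normal(0, 0.05, n) for _ in range(3)])
        arm = np.zeros(n)
        arm[: n // 10] = 0.4
        ratios = fit_reference(base + arm, refs, non_negative=True)
        recovered = np.median(ratios[: n // 10]) - np.median(ratios[n // 10:])
        assert recovered == pytest.approx(0.4, abs=0.05)

    def test_rank_deficient_references_warn(self):
        ref = np.ones((100, 2))
        ref[:, 1] = 2.0  # collinear with the intercept
        with pytest.warns(UserWarning, match="rank-deficient"):
            fit_reference(np.ones(100), ref)

    def test_needs_two_references(self):
        with pytest.raises(ValueError, match="2 reference"):
            fit_reference(np.ones(10), np.ones((10, 1)))


class TestBinGenome:
    def test_uniform_density_no_merging(self):
        # 1 probe per kb, 50 kb windows, min 15 -> each bin one window of 50
        positions = np.arange(1, 50_001, 1000)
        probes = [f"p{i}" for i in range(len(positions))]
        manifest = make_manifest(probes, positions=positions)
        bins = bin_genome(manifest, CNVParams(target_bin_size=50_000))
        assert len(bins) == 1
        assert (bins[0].start, bins[0].end, bins[0].n_probes) == (0, 50_000, 50)

    def test_deficient_window_merges_right_then_left(self):
        # window 1 has 3 probes, window 2 has 20 -> single bin of 23
        positions = np.concatenate([
            np.linspace(1, 40_000, 3).astype(int),
            np.linspace(50_001, 99_000, 20).astype(int),
        ])
        probes = [f"p{i}" for i in range(23)]
        manifest = make_manifest(probes, positions=positions)
        bins = bin_genome(manifest, CNVParams(target_bin_size=50_000, min_probes_per_bin=15))
        assert len(bins) == 1
        assert bins[0].n_probes == 23

    def test_trailing_deficient_bin_merges_left(self):
        positions = np.concatenate([
            np.linspace(1, 49_000, 20).astype(int),
            np.array([60_000, 70_000]),
        ])
        manifest = make_manifest([f"p{i}" for i in range(22)], positions=positions)
        bins = bin_genome(manifest, CNVParams(target_bin_size=50_000, min_probes_per_bin=15))
        assert len(bins) == 1
        assert bins[0].end == 100_000 and bins[0].n_probes == 22

    def test_sparse_chromosome_excluded(self):
        manifest = make_manifest(
            ["a", "b", "c"], chroms=["chr1", "chr1", "chr2"], positions=[1, 2, 3]
        )
        with pytest.raises(ValueError, match="no chromosome"):
            bin_genome(manifest, CNVParams(min_probes_per_bin=15))

    def test_random_manifests_bins_valid(self):
        params = CNVParams(target_bin_size=1_000_000, min_probes_per_bin=10)
        for seed in range(100):
            config = simple_config(
                n_probes_per_array=300, n_chromosomes=3, chrom_length=5_000_000,
                seed=seed, classes=(), n_reference_samples=1,
            )
            manifest = generate_manifest(config)
            bins = bin_genome(manifest, params)
            seen = set()
            by_chrom: dict = {}
            for b in bins:
                assert b.n_probes >= params.min_probes_per_bin
                assert b.start < b.end
                by_chrom.setdefault(b.chrom, []).append(b)
                seen.update(b.probe_ids)
            for chrom_bins in by_chrom.values():
                for a, b in zip(chrom_bins[:-1], chrom_bins[1:]):
                    assert a.end <= b.start  # disjoint and sorted
            covered = manifest[manifest["chrom"].isin(by_chrom)]
            assert seen == set(covered["probe_id"])


class TestBinRatios:
    def test_median_and_robustness(self):
        bins = [
            GenomicBin("chr1", 0, 100, ("a", "b", "c")),
            GenomicBin("chr1", 100, 200, ("d", "e", "f")),
        ]
        ratios = pd.Series(
            [0.1, 0.2, 0.3, 0.0, 0.0, 5.0], index=list("abcdef")
        )
        out = bin_ratios(ratios, bins)
        assert np.array_equal(out, [0.2, 0.0])


class TestSegmentCBS:
    def test_constant_vector_single_segment(self):
        for n in (1, 2, 5, 40):
            segs = segment_cbs(np.full(n, 0.7), CNVParams(), np.random.default_rng(0))
            assert segs == [(0, n, pytest.approx(0.7))]

    def test_noise_free_step_found_exactly(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        segs = segment_cbs(x, CNVParams(), np.random.default_rng(1))
        assert segs == [(0, 20, 0.0), (20, 40, 1.0)]

    def test_three_level_profile(self):
        x = np.r_[np.zeros(15), np.full(10, 1.0), np.zeros(15)]
        segs = segment_cbs(x, CNVParams(), np.random.default_rng(2))
        assert [(s[0], s[1]) for s in segs] == [(0, 15), (15, 25), (25, 40)]

    def test_first_split_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            n = int(rng.integers(4, 50))
            x = rng.normal(size=n) + np.repeat(
                rng.normal(scale=0.5, size=2), [n // 2, n - n // 2]
            )
            t_o, i_o, j_o = naive_best_circular_split(x)
            t_i, i_i, j_i = _max_circular_t(x, 2)
            assert (i_i, j_i) == (i_o, j_o)
            assert t_i == pytest.approx(t_o, rel=1e-9)

    def test_pure_noise_mostly_single_segment(self):
        params = CNVParams(seg_alpha=0.01, seg_permutations=100)
        single = sum(
            len(segment_cbs(np.random.default_rng(100 + s).normal(size=50),
                            params, np.random.default_rng(s))) == 1
            for s in range(20)
        )
        assert single >= 18

    def test_seeded_reproducibility(self):
        x = np.random.default_rng(5).normal(size=60) + np.r_[np.zeros(30), np.full(30, 0.3)]
        s1 = segment_cbs(x, CNVParams(), np.random.default_rng(7))
        s2 = segment_cbs(x, CNVParams(), np.random.default_rng(7))
        assert s1 == s2


class TestCallStates:
    @pytest.mark.parametrize(
        "mean,expected", [(0.3, GAIN), (-0.3, LOSS), (0.05, NEUTRAL), (0.15, GAIN), (-0.15, LOSS)]
    )
    def test_thresholding(self, mean, expected):
        calls = call_states([(0, 4, mean)], CNVParams(call_threshold=0.15), 4)
        assert (calls == expected).all()


class TestCallCnvEndToEnd:
    @pytest.mark.parametrize("floor,atol", [(1e3, 2e-3), (1e5, 1e-6)])
    def test_scale_invariance_of_bin_ratios(self, floor, atol):
        """A global intensity rescaling leaves bin ratios unchanged up to the
        pseudo-count nonlinearity, which shrinks as ~1/intensity."""
        config = simple_config(n_probes_per_array=1000, n_chromosomes=2,
                               classes=(), n_reference_samples=4, seed=13)
        manifest = generate_manifest(config)
        rng = np.random.default_rng(4)
        n = len(manifest)
        vals = {f"r{i}": (rng.uniform(floor, 10 * floor, n), rng.uniform(floor, 10 * floor, n))
                for i in range(4)}
        m1 = make_matrix(manifest["probe_id"], vals)
        m2 = make_matrix(manifest["probe_id"], {k: (3 * v[0], 3 * v[1]) for k, v in vals.items()})
        bins = bin_genome(manifest, CNVParams(target_bin_size=2_000_000, min_probes_per_bin=10))
        params = CNVParams(target_bin_size=2_000_000, min_probes_per_bin=10)
        li1, li2 = total_log_intensity(m1), total_log_intensity(m2)
        p1 = call_cnv("r0", li1["r0"], li1[["r1", "r2", "r3"]], bins, params,
                      np.random.default_rng(0))
        p2 = call_cnv("r0", li2["r0"], li2[["r1", "r2", "r3"]], bins, params,
                      np.random.default_rng(0))
        assert np.allclose(p1.log2_ratio, p2.log2_ratio, atol=atol)

    def test_segments_partition_bins_per_chromosome(self, small_cohort):
        _, manifest, matrix, sheet, _ = small_cohort
        params = CNVParams(target_bin_size=2_000_000, min_probes_per_bin=10)
        bins = bin_genome(manifest, params)
        li = total_log_intensity(matrix)
        refs = sheet.loc[sheet["is_reference"], "sample_id"].tolist()
        query = sheet.loc[~sheet["is_reference"], "sample_id"].iloc[0]
        profile = call_cnv(query, li[query], li[refs], bins, params,
                           np.random.default_rng(11))
        covered = []
        for chrom, sub in profile.segments.groupby("chrom"):
            sub = sub.sort_values("start_bin")
            for a, b in zip(sub["end_bin"].iloc[:-1], sub["start_bin"].iloc[1:]):
                assert a == b
            covered.extend(range(sub["start_bin"].iloc[0], sub["end_bin"].iloc[-1]))
        assert sorted(covered) == list(range(len(bins)))
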