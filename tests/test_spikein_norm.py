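import math

import numpy as np
import pytest

from chipquant import spikein_norm as sn
from chipquant.core_intervals import ChromSizes, GenomicInterval
from chipquant.coverage import CoverageTrack
from chipquant.io_formats import AlignedRead
from chipquant.synthetic_data import SimConfig, simulate_dual_genome_reads
from conftest import random_interval
from oracles import count_overlapping_reads_bp


def _read(chrom, start, end, mapq=30, genome="target"):
    return AlignedRead(genome, GenomicInterval(chrom, start, end), mapq)


def _track(values, state="raw", bin=10):
    values = np.asarray(values, dtype=float)
    sizes = ChromSizes({"chrI": len(values) * bin})
    return CoverageTrack({"chrI": values}, bin=bin, sizes=sizes, state=state)


class TestPartitionAndFilter:
    def test_mapq_threshold_inclusive(self):
        kept, counts = sn.partition_and_filter([_read("chrI", 0, 50, mapq=10)], mapq_min=10)
        assert counts == {"target": 1}

    def test_mapq_below_threshold_dropped(self):
        kept, counts = sn.partition_and_filter([_read("chrI", 0, 50, mapq=9)], mapq_min=10)
        assert counts == {}

    def test_one_bp_blacklist_overlap_drops(self):
        blacklist = [GenomicInterval("chrI", 49, 100)]
        kept, counts = sn.partition_and_filter(
            [_read("chrI", 0, 50), _read("chrI", 100, 150)], blacklist=blacklist
        )
        # read [0,50) overlaps base 49; read [100,150) is adjacent only
        assert counts == {"target": 1}
        assert kept["target"][0].interval.start == 100

    def test_blacklist_agrees_with_base_pair_oracle(self, rng):
        reads = [
            _read(iv.chrom, iv.start, iv.end)
            for iv in (random_interval(rng, max_width=80) for _ in range(300))
        ]
        blacklist = [random_interval(rng, max_width=200) for _ in range(20)]
        kept, _ = sn.partition_and_filter(reads, blacklist=blacklist)
        n_kept = len(kept.get("target", []))
        n_overlapping = count_overlapping_reads_bp(
            [(r.interval.chrom, r.interval.start, r.interval.end) for r in reads],
            [(b.chrom, b.start, b.end) for b in blacklist],
        )
        assert n_kept == len(reads) - n_overlapping

    def test_split_by_genome_with_map(self):
        reads = [
            _read("ce_chrI", 0, 50, genome="x"),
            _read("cb_chrI", 0, 50, genome="x"),
        ]
        kept, counts = sn.partition_and_filter(
            reads, genome_map={"ce_": "target", "cb_": "spike"}
        )
        assert counts == {"target": 1, "spike": 1}

    def test_unmapped_chromosome_hard_error(self):
        with pytest.raises(KeyError):
            sn.partition_and_filter([_read("chrX", 0, 50)], genome_map={"ce_": "target"})


class TestSpikeinRatio:
    def test_ten_percent(self):
        est = sn.spikein_ratio({"spike": 1_000, "target": 10_000})
        assert est.ratio == pytest.approx(0.1)

    def test_five_percent(self):
        est = sn.spikein_ratio({"spike": 500, "target": 10_000})
        assert est.ratio == pytest.approx(0.05)

    def test_zero_target_reads_hard_error(self):
        with pytest.raises(ValueError):
            sn.spikein_ratio({"spike": 100, "target": 0})

    def test_recovery_within_binomial_se(self):
        # planted r = 0.08, n = 200,000; binomial SE on the spike fraction
        cfg = SimConfig(seed=7, spike_ratio=0.08, n_input_reads=200_000, n_chip_reads=100)
        sim = simulate_dual_genome_reads(cfg)
        by_genome, _ = sn.partition_and_filter(sim.input_reads, mapq_min=0)
        est = sn.spikein_ratio(by_genome)
        p = 0.08 / 1.08
        se_p = math.sqrt(p * (1 - p) / 200_000)
        # transform SE of the fraction to SE of the ratio r = p/(1-p)
        se_r = se_p / (1 - p) ** 2
        assert abs(est.ratio - 0.08) < 3 * se_r


class TestScalingFactor:
    def test_arithmetic(self):
        est = sn.spikein_ratio({"spike": 1_000, "target": 10_000})
        assert sn.scaling_factor(est, 2_000_000).value == pytest.approx(0.05)

    def test_one_million_unit_case(self):
        est = sn.spikein_ratio({"spike": 1_000, "target": 10_000})
        assert sn.scaling_factor(est, 1_000_000).value == pytest.approx(0.1)

    def test_inverse_proportionality(self):
        est = sn.spikein_ratio({"spike": 1_000, "target": 10_000})
        s1 = sn.scaling_factor(est, 500_000).value
        s2 = sn.scaling_factor(est, 1_000_000).value
        assert s1 == pytest.approx(2 * s2)

    def test_zero_reads_in_peaks_hard_error(self):
        est = sn.spikein_ratio({"spike": 1_000, "target": 10_000})
        with pytest.raises(ValueError):
            sn.scaling_factor(est, 0)


class TestCountReadsInPeaks:
    def test_fully_inside(self):
        peaks = [GenomicInterval("chrI", 100, 400)]
        reads = [_read("chrI", 150, 200) for _ in range(3)]
        assert sn.count_reads_in_peaks(reads, peaks) == 3

    def test_read_spanning_two_peaks_counted_once(self):
        peaks = [GenomicInterval("chrI", 100, 200), GenomicInterval("chrI", 200, 300)]
        reads = [_read("chrI", 150, 250)]
        assert sn.count_reads_in_peaks(reads, peaks) == 1

    def test_matches_brute_force_oracle(self, rng):
        reads = [
            _read(iv.chrom, iv.start, iv.end)
            for iv in (random_interval(rng, max_width=100) for _ in range(400))
        ]
        peaks = [random_interval(rng, max_width=400) for _ in range(30)]
        expected = count_overlapping_reads_bp(
            [(r.interval.chrom, r.interval.start, r.interval.end) for r in reads],
            [(p.chrom, p.start, p.end) for p in peaks],
        )
        assert sn.count_reads_in_peaks(reads, peaks) == expected


class TestScaleTrack:
    def test_scales_bins(self):
        est = sn.spikein_ratio({"spike": 500_000, "target": 1_000_000})
        s = sn.scaling_factor(est, 1_000_000)  # s = 0.5
        out = sn.scale_track(_track([1, 2, 3]), s)
        assert out.data["chrI"].tolist() == [0.5, 1.0, 1.5]
        assert out.state == "scaled"

    def test_identity_scale(self):
        est = sn.spikein_ratio({"spike": 1_000_000, "target": 1_000_000})
        s = sn.scaling_factor(est, 1_000_000)  # s = 1
        track = _track([1, 2, 3])
        out = sn.scale_track(track, s)
        assert out.data["chrI"].tolist() == [1, 2, 3]

    def test_mass_linearity_and_zeros_preserved(self):
        est = sn.spikein_ratio({"spike": 1, "target": 4})
        s = sn.scaling_factor(est, 1_000_000)
        track = _track([0, 4, 0, 8])
        out = sn.scale_track(track, s)
        assert out.total_mass() == pytest.approx(s.value * track.total_mass())
        assert out.data["chrI"][0] == 0.0 and out.data["chrI"][2] == 0.0

    def test_wrong_state_hard_error(self):
        est = sn.spikein_ratio({"spike": 1, "target": 1})
        s = sn.scaling_factor(est, 1_000_000)
        with pytest.raises(ValueError, match="raw"):
            sn.scale_track(_track([1], state="scaled"), s)


class TestSubtractMode:
    def test_discrete_mode(self):
        out = sn.subtract_mode(_track([1, 1, 1, 5, 1], state="scaled"))
        assert out.data["chrI"].tolist() == [0, 0, 0, 4, 0]
        assert out.meta["mode"] == 1.0

    def test_flat_background_removed_entirely(self):
        out = sn.subtract_mode(_track([3.5] * 8, state="scaled"))
        assert not np.any(out.data["chrI"])

    def test_all_zero_returned_unchanged_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            out = sn.subtract_mode(_track([0, 0, 0], state="scaled"))
        assert not np.any(out.data["chrI"])
        assert any("all-zero" in r.message for r in caplog.records)

    def test_never_negative(self, rng):
        values = rng.random(500) * 3
        out = sn.subtract_mode(_track(values, state="scaled"))
        assert np.all(out.data["chrI"] >= 0)

    def test_recovers_planted_background(self, rng):
        # planted uniform background b + noise, sparse strong peaks
        b, noise_sd = 2.0, 0.05
        n = 5_000
        values = b + rng.normal(0, noise_sd, n)
        peak_bins = rng.choice(n, size=100, replace=False)
        values[peak_bins] += 10.0
        values = np.maximum(values, 0)
        track = _track(values, state="scaled")
        out = sn.subtract_mode(track)
        mode = out.meta["mode"]
        # the tallest-bin midpoint wanders a few histogram bins around b under
        # Gaussian noise; a noise-sd tolerance is the statistically meaningful
        # bound (and is 200x tighter than the planted peak amplitude)
        assert abs(mode - b) <= noise_sd
        non_peak = np.setdiff1d(np.arange(n), peak_bins)
        ceiling = 4 * noise_sd
        assert np.mean(out.data["chrI"][non_peak] <= ceiling) >= 0.95

    def test_requires_scaled_state(self):
        with pytest.raises(ValueError):
            sn.subtract_mode(_track([1, 2, 3], state="raw"))


class TestZscoreTrack:
    def test_population_sd(self):
        out = sn.zscore_track(_track([0, 0, 10, 10]))
        assert out.data["chrI"].tolist() == [-1, -1, 1, 1]

    def test_mean_zero_sd_one(self, rng):
        out = sn.zscore_track(_track(rng.random(1000)))
        vals = out.all_values()
        assert abs(vals.mean()) < 1e-9
        assert abs(vals.std() - 1) < 1e-9

    def test_affine_invariance(self, rng):
        values = rng.random(200)
        z1 = sn.zscore_track(_track(values)).all_values()
        z2 = sn.zscore_track(_track(3.7 * values + 11.0)).all_values()
        np.testing.assert_allclose(z1, z2, atol=1e-9)

    def test_zero_variance_hard_error(self):
        with pytest.raises(ValueError):
            sn.zscore_track(_track([2, 2, 2]))


class TestInputNormalize:
    def test_identical_tracks_all_zero(self, rng):
        values = rng.random(50) + 0.5
        out = sn.input_normalize(_track(values), _track(values.copy()))
        np.testing.assert_allclose(out.data["chrI"], 0.0, atol=1e-12)

    def test_doubled_bin_is_plus_one_without_pseudocount(self):
        # equal-mass tracks where chip is exactly 2x input in the first bin
        chip = _track([4.0, 0.5, 0.5, 0.5, 0.5])
        inp = _track([2.0, 1.0, 1.0, 1.0, 1.0])
        out = sn.input_normalize(chip, inp, pseudocount=0.0)
        assert out.data["chrI"][0] == pytest.approx(1.0)

    def test_binning_mismatch_hard_error(self):
        with pytest.raises(ValueError):
            sn.input_normalize(_track([1, 2]), _track([1, 2], bin=20))

    def test_planted_enrichment_ranks_above_background(self, rng):
        hits = 0
        trials = 50
        for t in range(trials):
            r = np.random.default_rng(t)
            inp = 5 + r.random(200)
            chip = inp.copy() + r.random(200) * 0.2
            enriched = r.choice(200, size=5, replace=False)
            chip[enriched] *= 4
            out = sn.input_normalize(_track(chip), _track(inp))
            ranks = np.argsort(out.data["chrI"])[::-1][:5]
            hits += set(ranks.tolist()) == set(enriched.tolist())
        assert hits / trials >= 0.99


class TestCoverageFromReads:
    def test_simple_depth(self):
        sizes = ChromSizes({"chrI": 100})
        reads = [_read("chrI", 0, 50), _read("chrI", 25, 75)]
        track = sn.coverage_from_reads(reads, sizes, bin=25)
        assert track.data["chrI"].tolist() == [1.0, 2.0, 1.0, 0.0]

    def test_ignores_foreign_chromosomes(self):
        sizes = ChromSizes({"chrI": 100})
        track = sn.coverage_from_reads([_read("chrX", 0, 50)], sizes, bin=10)
        assert not np.any(track.data["chrI"])


class TestEndToEndLinearity:
    def test_depth_invariance_of_scaled_tracks(self):
        """Two ChIP samples with identical true signal but 2x depth agree after
        spike-in scaling and mode subtraction (the point of the method)."""
        from chipquant.synthetic_data import simulate_chip_sample

        cfg = SimConfig(seed=5, n_input_reads=100_000, n_chip_reads=100)
        sim = simulate_dual_genome_reads(cfg)
        by_genome, _ = sn.partition_and_filter(sim.input_reads, mapq_min=10)
        est = sn.spikein_ratio(by_genome)
        tracks = []
        for stream, n_reads in (("sampleA", 150_000), ("sampleB", 300_000)):
            reads = simulate_chip_sample(cfg, n_reads, stream=stream)
            chip_by_genome, _ = sn.partition_and_filter(reads, mapq_min=10)
            s = sn.scaling_factor(
                est, sn.count_reads_in_peaks(chip_by_genome["spike"], sim.spike_peaks)
            )
            raw = sn.coverage_from_reads(chip_by_genome["target"], cfg.target_sizes)
            tracks.append(sn.subtract_mode(sn.scale_track(raw, s)))
        a, b = tracks
        # compare the flat interiors of the planted peaks
        rel_diffs = []
        for peak in sim.target_peaks:
            mid = (peak.start + peak.end) // 2
            iv = GenomicInterval(peak.chrom, mid - 100, mid + 100)
            va, _ = a.values_in(iv)
            vb, _ = b.values_in(iv)
            rel_diffs.append(np.abs(va - vb) / np.maximum(va, vb))
        assert float(np.median(np.concatenate(rel_diffs))) < 0.10
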