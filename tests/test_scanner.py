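"""HQHV window scanning: filters, ordering, recovery and reporting."""

import itertools

import numpy as np
import pytest

from hqhvscan import (
    DataError,
    DepthTrack,
    GenomeInterval,
    NamedSequence,
    SampleData,
    ScanConfig,
    SimConfig,
    VariantCall,
    check_flanks,
    global_mean_depth,
    scan,
    simulate_dataset,
    window_stats,
    write_scan_outputs,
)
from hqhvscan.distances import p_distance


def _flat_samples(ref_len, n=2, depth=10, chrom="c1"):
    samples = []
    for i in range(n):
        track = DepthTrack(
            GenomeInterval(chrom, 0, ref_len), np.full(ref_len, depth), sample=f"S{i+1}"
        )
        samples.append(SampleData(f"S{i+1}", [], {chrom: track}))
    return samples


def _add_calls(sample, reference, positions, zygosity="hom_alt"):
    sub = {"A": "G", "C": "T", "G": "A", "T": "C"}
    for pos in positions:
        ref_base = reference.residues[pos]
        sample.calls.append(
            VariantCall(reference.name, pos, ref_base, sub[ref_base], zygosity, sample.name)
        )


@pytest.fixture
def flat_reference():
    rng = np.random.default_rng(5)
    return NamedSequence("c1", "".join(rng.choice(list("ACGT"), size=2000)))


class TestGlobalMeanDepth:
    def test_uniform(self):
        track = DepthTrack(GenomeInterval("c", 0, 4), np.array([4, 4, 4, 4]))
        assert global_mean_depth(track) == 4.0

    def test_mixed(self):
        track = DepthTrack(GenomeInterval("c", 0, 2), np.array([0, 8]))
        assert global_mean_depth(track) == 4.0

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            global_mean_depth({})


class TestWindowStats:
    def test_density_strict_boundary(self, flat_reference):
        config = ScanConfig(window_len=500)
        iv = GenomeInterval("c1", 0, 500)
        samples = _flat_samples(2000)
        _add_calls(samples[0], flat_reference, [10, 20, 30, 40, 50])
        stats, _ = window_stats(flat_reference, samples, iv, config)
        assert stats.union_variant_density == pytest.approx(0.01)
        assert stats.reject_reason == "density"  # 5/500 fails the strict >
        _add_calls(samples[0], flat_reference, [60])
        stats, _ = window_stats(flat_reference, samples, iv, config)
        assert stats.union_variant_density == pytest.approx(0.012)
        assert stats.reject_reason == "none"  # 6/500 passes

    def test_union_counts_distinct_positions(self, flat_reference):
        config = ScanConfig(window_len=500)
        iv = GenomeInterval("c1", 0, 500)
        samples = _flat_samples(2000)
        shared = [10, 20, 30, 40]
        _add_calls(samples[0], flat_reference, shared + [50, 60])
        _add_calls(samples[1], flat_reference, shared)  # same positions again
        stats, _ = window_stats(flat_reference, samples, iv, config)
        assert stats.union_variant_count == 6

    def test_doubled_depth_rejected_for_coverage(self, flat_reference):
        samples = _flat_samples(2000)
        samples[0].depth["c1"].depths[0:500] *= 2
        config = ScanConfig(window_len=500)
        stats, _ = window_stats(
            flat_reference, samples, GenomeInterval("c1", 0, 500), config
        )
        assert abs(stats.depth_ratio["S1"] - 1.0) > config.cov_tol
        assert stats.reject_reason == "coverage"

    def test_coverage_checked_before_nhet(self, flat_reference):
        samples = _flat_samples(2000)
        samples[0].depth["c1"].depths[0:500] = 0  # both low coverage AND all-N
        stats, _ = window_stats(
            flat_reference, samples, GenomeInterval("c1", 0, 500), ScanConfig()
        )
        assert stats.reject_reason == "coverage"

    def test_nhet_fraction_threshold(self, flat_reference):
        samples = _flat_samples(2000)
        _add_calls(samples[0], flat_reference, list(range(10, 22)), zygosity="het")
        _add_calls(samples[1], flat_reference, list(range(100, 112)))
        stats, _ = window_stats(
            flat_reference, samples, GenomeInterval("c1", 0, 500), ScanConfig()
        )
        # 12 het sites / 500 = 2.4% >= 1%
        assert stats.reject_reason == "nhet"

    def test_window_outside_reference_rejected(self, flat_reference):
        with pytest.raises(DataError, match="outside"):
            window_stats(
                flat_reference, _flat_samples(2000),
                GenomeInterval("c1", 1900, 2400), ScanConfig(window_len=500),
            )


class TestScan:
    def test_fewer_than_two_samples_rejected(self, flat_reference):
        with pytest.raises(DataError, match="2 samples"):
            scan(flat_reference, _flat_samples(2000, n=1))

    def test_zero_divergence_zero_candidates(self, flat_reference):
        result = scan(flat_reference, _flat_samples(2000), ScanConfig())
        assert result.retained == []
        assert result.report["counts"]["rejected_density"] == result.report["counts"]["evaluated"]

    def test_planted_recovery_and_truth(self, seed1_dataset, scan_samples):
        result = scan(seed1_dataset.reference, scan_samples, ScanConfig())
        retained_starts = sorted(c.interval.start for c in result.retained)
        truth_starts = sorted(b["start"] for b in seed1_dataset.truth["planted_blocks"])
        assert retained_starts == truth_starts  # sensitivity 1, no false positives

    def test_duplicated_block_rejected_for_coverage(self, seed1_dataset, scan_samples):
        result = scan(seed1_dataset.reference, scan_samples, ScanConfig())
        dup_start = seed1_dataset.truth["duplicated_blocks"][0]["start"]
        reason = next(
            st.reject_reason for st in result.window_stats if st.interval.start == dup_start
        )
        assert reason == "coverage"

    def test_report_partitions_windows(self, seed1_dataset, scan_samples):
        counts = scan(seed1_dataset.reference, scan_samples, ScanConfig()).report["counts"]
        partition = (
            counts["rejected_coverage"] + counts["rejected_nhet"]
            + counts["rejected_density"] + counts["rejected_distance"]
            + counts["retained"]
        )
        assert partition == counts["evaluated"]
        assert counts["passed_density"] == counts["rejected_distance"] + counts["retained"]

    def test_tiling_matches_per_window_oracle(self, flat_reference):
        """scan with step == window_len is reproduced by naive per-window
        recomputation straight from calls and depth."""
        rng = np.random.default_rng(9)
        samples = _flat_samples(2000, n=3)
        for s in samples:
            _add_calls(s, flat_reference, sorted(rng.choice(2000, size=15, replace=False)))
        config = ScanConfig(window_len=500, step=500, min_snp_density=0.004)
        result = scan(flat_reference, samples, config)

        from hqhvscan import build_consensus

        expected_retained = []
        for start in range(0, 2000 - 500 + 1, 500):
            iv = GenomeInterval("c1", start, start + 500)
            union = set()
            ok = True
            consensus = {}
            for s in samples:
                win_calls = [c for c in s.calls if start <= c.pos < start + 500]
                union.update(c.pos for c in win_calls)
                wmean = s.depth["c1"].depths[start:start + 500].mean()
                gmean = s.depth["c1"].depths.mean()
                if abs(wmean / gmean - 1.0) > config.cov_tol:
                    ok = False
                cons = build_consensus(flat_reference, iv, win_calls, s.depth["c1"], 1)
                if (cons.n_count + cons.het_count) / 500 >= config.max_nhet_frac:
                    ok = False
                consensus[s.name] = cons
            if not ok or len(union) / 500 <= config.min_snp_density:
                continue
            dists = [
                p_distance(
                    consensus[a].as_named_sequence(), consensus[b].as_named_sequence(),
                    mode="average_states",
                ).distance
                for a, b in itertools.combinations(sorted(consensus), 2)
            ]
            if min(dists) >= config.min_pair_distance:
                expected_retained.append(start)
        assert sorted(c.interval.start for c in result.retained) == expected_retained
        assert expected_retained  # the oracle saw signal at this density

    def test_monotonic_in_density_and_cov_tol(self, seed1_dataset, scan_samples):
        retained_by_density = [
            len(scan(seed1_dataset.reference, scan_samples,
                     ScanConfig(min_snp_density=d)).retained)
            for d in (0.004, 0.01, 0.016)
        ]
        assert retained_by_density == sorted(retained_by_density, reverse=True)
        retained_by_tol = [
            len(scan(seed1_dataset.reference, scan_samples,
                     ScanConfig(cov_tol=t)).retained)
            for t in (0.02, 0.1, 0.5)
        ]
        assert retained_by_tol == sorted(retained_by_tol)

    def test_variance_filter_opt_in(self, seed1_dataset, scan_samples):
        base = scan(seed1_dataset.reference, scan_samples, ScanConfig())
        strict = scan(
            seed1_dataset.reference, scan_samples,
            ScanConfig(min_pair_variance=1.0),  # impossible bar
        )
        assert len(base.retained) > 0
        assert len(strict.retained) == 0

    def test_outputs_written(self, tmp_path, seed1_dataset, scan_samples):
        result = scan(seed1_dataset.reference, scan_samples, ScanConfig())
        paths = write_scan_outputs(result, str(tmp_path / "run"))
        bed_lines = open(paths["bed"]).read().strip().splitlines()
        assert len(bed_lines) == len(result.retained)
        chrom, start, end, name, score, strand = bed_lines[0].split("\t")
        assert int(end) - int(start) == 500 and strand == "."
        import json

        report = json.load(open(paths["report"]))
        assert report["counts"] == result.report["counts"]


class TestCheckFlanks:
    def test_clean_flanks_suitable(self, flat_reference):
        samples = _flat_samples(2000)
        _add_calls(samples[0], flat_reference, list(range(600, 608)))
        result = scan(flat_reference, samples, ScanConfig(min_snp_density=0.002))
        cand = next(c for c in result.retained if c.interval.start == 500)
        assert check_flanks(cand, flat_reference, samples) == ("suitable", None)

    def test_variant_in_flank_unsuitable(self, flat_reference):
        samples = _flat_samples(2000)
        _add_calls(samples[0], flat_reference, list(range(600, 608)) + [490])
        result = scan(flat_reference, samples, ScanConfig(min_snp_density=0.002))
        cand = next(c for c in result.retained if c.interval.start == 500)
        assert check_flanks(cand, flat_reference, samples) == ("unsuitable", "left_flank")

    def test_edge_candidate_unsuitable(self, flat_reference):
        samples = _flat_samples(2000)
        _add_calls(samples[0], flat_reference, list(range(10, 18)))
        result = scan(flat_reference, samples, ScanConfig(min_snp_density=0.002))
        cand = next(c for c in result.retained if c.interval.start == 0)
        assert check_flanks(cand, flat_reference, samples) == ("unsuitable", "edge")
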