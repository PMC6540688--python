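"""Scan a synthetic genome for HQHV marker candidates.

Builds a 100 kb reference with three planted divergent 500 bp blocks
(1 variant per ~67 bp) over a sparse background (1 per 500 bp) and one
coverage-duplicated block, then runs the four-filter window scan.  The
report shows why each window was excluded; the retained windows are the
planted blocks and nothing else.
"""

from hqhvscan import SampleData, ScanConfig, SimConfig, scan, simulate_dataset

config = SimConfig(
    seed=1,
    ref_len=100_000,
    n_samples=3,
    background_density=0.002,
    planted_blocks=[(20_000, 500, 0.015), (50_000, 500, 0.015), (80_000, 500, 0.015)],
    duplicated_blocks=[(60_000, 500, 2)],
)
dataset = simulate_dataset(config)
samples = [SampleData(s.name, s.calls, s.depth) for s in dataset.samples]

result = scan(dataset.reference, samples, ScanConfig())

print("window rejection accounting:")
for key, value in result.report["counts"].items():
    print(f"  {key:18s} {value}")

print("\nretained candidate regions (1-based coordinates):")
for cand in result.retained:
    print(
        f"  {cand.interval.region_string():22s}"
        f" min pair p-distance {cand.min_pair_distance:.4f}"
        f"  across-pair variance {cand.pair_variance:.6f}"
    )
print(
    "\nEach retained window shows >1 SNP/100 bp of between-sample divergence "
    "with clean, single-copy coverage; the fold-2 duplicated block at "
    "60,001-60,500 was rejected by the coverage filter."
)
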