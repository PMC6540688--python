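"""Windowed detection of high-quality, highly variable (HQHV) regions.

The reference is tiled in fixed-length windows (500 bp by default — the
span one Sanger run can confirm) and four filters are applied in a fixed
order, so every window lands in exactly one rejection category:

1. *coverage* — each sample's window mean depth must lie within
   ``cov_tol`` (default ±10%) of that sample's global mean depth; windows in
   duplicated genomic regions show fold-inflated relative coverage and fail
   here;
2. *nhet* — the fraction of undetermined (N) plus heterozygous consensus
   positions must stay below ``max_nhet_frac`` (default 1%) in every sample,
   screening out poorly mapped or paralog-collapsed windows;
3. *density* — the number of distinct variant positions in the union across
   samples must exceed ``min_snp_density`` (default 1 SNP / 100 bp, strict);
4. *distance* — all pairwise p-distances between the samples' consensus
   sequences (average-states mode, since consensus may carry heterozygote
   codes) must reach ``min_pair_distance`` (default 0.001); the across-pair
   variance is reported for every candidate and can optionally be used as an
   additional filter.

Windows surviving 1-3 become candidate regions with per-pair distances;
those also passing 4 are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .consensus import SampleConsensus, build_consensus
from .distances import p_distance, variance_across_pairs
from .errors import DataError
from .seqio import DepthTrack, GenomeInterval, NamedSequence, VariantCall

REJECT_REASONS = ("none", "coverage", "nhet", "density", "distance")


@dataclass
class ScanConfig:
    """Every numeric criterion of the HQHV scan."""

    window_len: int = 500
    step: int = 500
    cov_tol: float = 0.1
    max_nhet_frac: float = 0.01
    min_snp_density: float = 0.01
    min_pair_distance: float = 0.001
    min_pair_variance: float | None = None  # opt-in variance filter
    min_depth: int = 1
    distance_mode: str = "average_states"

    def __post_init__(self):
        if self.window_len < 100:
            raise DataError("window_len must be >= 100 bp")
        if self.step <= 0:
            raise DataError("step must be positive")
        for name in ("cov_tol", "max_nhet_frac", "min_snp_density", "min_pair_distance"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be >= 0")
        if self.min_pair_variance is not None and self.min_pair_variance < 0:
            raise DataError("min_pair_variance must be >= 0")
        if self.min_depth < 0:
            raise DataError("min_depth must be >= 0")


@dataclass
class SampleData:
    """One sample's scan inputs: SNP calls plus per-chromosome depth."""

    name: str
    calls: list[VariantCall]
    depth: dict[str, DepthTrack]


@dataclass
class WindowStats:
    interval: GenomeInterval
    depth_ratio: dict[str, float]
    nhet_frac: dict[str, float]
    n_count: dict[str, int]
    het_count: dict[str, int]
    union_variant_count: int
    union_variant_density: float
    reject_reason: str  # first failing filter, or "none"


@dataclass
class CandidateRegion:
    interval: GenomeInterval
    consensus: dict[str, SampleConsensus]
    pair_distances: dict[tuple[str, str], float]
    pair_variance: float
    status: str  # "retained" | "rejected:distance"

    @property
    def min_pair_distance(self) -> float:
        return min(self.pair_distances.values())


@dataclass
class ScanResult:
    candidates: list[CandidateRegion]
    window_stats: list[WindowStats]
    report: dict

    @property
    def retained(self) -> list[CandidateRegion]:
        return [c for c in self.candidates if c.status == "retained"]


def global_mean_depth(depth: DepthTrack | dict[str, DepthTrack]) -> float:
    """Arithmetic mean depth over all positions of a sample's track set."""
    tracks = list(depth.values()) if isinstance(depth, dict) else [depth]
    total = sum(len(t.depths) for t in tracks)
    if total == 0:
        raise DataError("empty depth track")
    return float(sum(int(t.depths.sum()) for t in tracks) / total)


def _sample_prep(reference: NamedSequence, sample: SampleData):
    chrom = reference.name
    track = sample.depth.get(chrom)
    if track is None:
        raise DataError(f"sample {sample.name!r} has no depth track for {chrom!r}")
    calls = sorted(
        (c for c in sample.calls if c.chrom == chrom), key=lambda c: c.pos
    )
    positions = np.array([c.pos for c in calls], dtype=np.int64)
    return track, calls, positions


def window_stats(
    reference: NamedSequence,
    samples: list[SampleData],
    interval: GenomeInterval,
    config: ScanConfig,
    _global_means: dict[str, float] | None = None,
) -> tuple[WindowStats, dict[str, SampleConsensus]]:
    """Evaluate the four filters over one window.

    Returns the stats row (with ``reject_reason`` set to the first failing
    of coverage/nhet/density; the distance filter is applied by
    :func:`scan`, which owns the pairwise distances) and the per-sample
    consensus sequences.
    """
    if interval.chrom != reference.name or interval.end > len(reference):
        raise DataError(f"window {interval.region_string()} outside the reference")
    depth_ratio: dict[str, float] = {}
    nhet_frac: dict[str, float] = {}
    n_count: dict[str, int] = {}
    het_count: dict[str, int] = {}
    consensus: dict[str, SampleConsensus] = {}
    union_positions: set[int] = set()
    for sample in samples:
        track, calls, positions = _sample_prep(reference, sample)
        gmean = (_global_means or {}).get(sample.name) or global_mean_depth(sample.depth)
        off = interval.start - track.interval.start
        wdepth = track.depths[off:off + len(interval)]
        depth_ratio[sample.name] = float(wdepth.mean() / gmean) if gmean > 0 else float("inf")
        lo, hi = np.searchsorted(positions, [interval.start, interval.end])
        window_calls = calls[lo:hi]
        cons = build_consensus(reference, interval, window_calls, track, config.min_depth)
        consensus[sample.name] = cons
        n_count[sample.name] = cons.n_count
        het_count[sample.name] = cons.het_count
        nhet_frac[sample.name] = (cons.n_count + cons.het_count) / len(interval)
        union_positions.update(c.pos for c in window_calls)

    union_count = len(union_positions)
    density = union_count / len(interval)
    if any(abs(r - 1.0) > config.cov_tol for r in depth_ratio.values()):
        reason = "coverage"
    elif any(f >= config.max_nhet_frac for f in nhet_frac.values()):
        reason = "nhet"
    elif density <= config.min_snp_density:
        reason = "density"
    else:
        reason = "none"
    stats = WindowStats(
        interval, depth_ratio, nhet_frac, n_count, het_count,
        union_count, density, reason,
    )
    return stats, consensus


def scan(
    reference: NamedSequence | list[NamedSequence],
    samples: list[SampleData],
    config: ScanConfig | None = None,
) -> ScanResult:
    """Tile the reference and emit candidate HQHV regions plus a scan report.

    The report partitions every evaluated window into exactly one of
    ``rejected_coverage``, ``rejected_nhet``, ``rejected_density``,
    ``rejected_distance`` or ``retained``; ``passed_density`` counts windows
    that survived the first three filters.
    """
    config = config or ScanConfig()
    if len(samples) < 2:
        raise DataError("scan requires >= 2 samples")
    references = reference if isinstance(reference, list) else [reference]
    global_means = {s.name: global_mean_depth(s.depth) for s in samples}

    counts = {
        "evaluated": 0,
        "rejected_coverage": 0,
        "rejected_nhet": 0,
        "rejected_density": 0,
        "passed_density": 0,
        "rejected_distance": 0,
        "retained": 0,
    }
    candidates: list[CandidateRegion] = []
    all_stats: list[WindowStats] = []

    for ref in references:
        for start in range(0, len(ref) - config.window_len + 1, config.step):
            interval = GenomeInterval(ref.name, start, start + config.window_len)
            stats, consensus = window_stats(ref, samples, interval, config, global_means)
            counts["evaluated"] += 1
            if stats.reject_reason != "none":
                counts[f"rejected_{stats.reject_reason}"] += 1
                all_stats.append(stats)
                continue
            counts["passed_density"] += 1
            names = sorted(consensus)
            pair_distances: dict[tuple[str, str], float] = {}
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    a, b = consensus[names[i]], consensus[names[j]]
                    res = p_distance(
                        a.as_named_sequence(), b.as_named_sequence(),
                        mode=config.distance_mode,
                    )
                    pair_distances[(names[i], names[j])] = res.distance
            # with exactly two samples there is a single pair: variance is 0
            dist_values = list(pair_distances.values())
            variance = variance_across_pairs(dist_values) if len(dist_values) >= 2 else 0.0
            retained = min(pair_distances.values()) >= config.min_pair_distance
            if retained and config.min_pair_variance is not None:
                retained = variance >= config.min_pair_variance
            status = "retained" if retained else "rejected:distance"
            if retained:
                counts["retained"] += 1
            else:
                counts["rejected_distance"] += 1
                stats.reject_reason = "distance"
            candidates.append(CandidateRegion(interval, consensus, pair_distances, variance, status))
            all_stats.append(stats)

    report = {
        "config": {
            "window_len": config.window_len,
            "step": config.step,
            "cov_tol": config.cov_tol,
            "max_nhet_frac": config.max_nhet_frac,
            "min_snp_density": config.min_snp_density,
            "min_pair_distance": config.min_pair_distance,
            "min_pair_variance": config.min_pair_variance,
            "min_depth": config.min_depth,
            "distance_mode": config.distance_mode,
        },
        "samples": [s.name for s in samples],
        "counts": counts,
        "retained_regions": [
            {
                "region": c.interval.region_string(),
                "start": c.interval.start,
                "end": c.interval.end,
                "min_pair_distance": round(c.min_pair_distance, 6),
                "pair_variance": round(c.pair_variance, 6),
            }
            for c in candidates
            if c.status == "retained"
        ],
    }
    return ScanResult(candidates, all_stats, report)


def write_scan_outputs(result: ScanResult, out_prefix: str) -> dict[str, str]:
    """Write the scan artifacts: BED6 candidates, consensus FASTA, per-window
    stats TSV and the JSON report.  Returns the paths written.

    BED scores encode the minimum pair distance (1000 x distance, capped at
    1000); the stats table has one row per evaluated window with explicit
    per-sample columns.
    """
    import json as _json

    import pandas as pd

    from .seqio import write_bed, write_fasta

    paths = {
        "bed": f"{out_prefix}.candidates.bed",
        "fasta": f"{out_prefix}.candidates.fa",
        "stats": f"{out_prefix}.stats.tsv",
        "report": f"{out_prefix}.report.json",
    }
    retained = result.retained
    write_bed(
        [
            (c.interval, f"HQHV_{i + 1:02d}", int(round(1000 * c.min_pair_distance)))
            for i, c in enumerate(retained)
        ],
        paths["bed"],
    )
    records = [
        cons.as_named_sequence()
        for c in retained
        for _, cons in sorted(c.consensus.items())
    ]
    if records:
        write_fasta(records, paths["fasta"])
    else:
        open(paths["fasta"], "w").close()

    by_interval = {
        (c.interval.start, c.interval.end, c.interval.chrom): c for c in result.candidates
    }
    rows = []
    for st in result.window_stats:
        row: dict = {
            "chrom": st.interval.chrom,
            "start1": st.interval.start + 1,
            "end": st.interval.end,
            "union_variant_count": st.union_variant_count,
            "union_variant_density": round(st.union_variant_density, 6),
            "reject_reason": st.reject_reason,
        }
        for name in sorted(st.depth_ratio):
            row[f"depth_ratio_{name}"] = round(st.depth_ratio[name], 4)
            row[f"nhet_frac_{name}"] = round(st.nhet_frac[name], 6)
            row[f"n_count_{name}"] = st.n_count[name]
            row[f"het_count_{name}"] = st.het_count[name]
        cand = by_interval.get((st.interval.start, st.interval.end, st.interval.chrom))
        if cand is not None:
            for (a, b), d in sorted(cand.pair_distances.items()):
                row[f"pdist_{a}_{b}"] = round(d, 6)
            row["pair_variance"] = round(cand.pair_variance, 6)
            row["status"] = cand.status
        rows.append(row)
    pd.DataFrame(rows).to_csv(paths["stats"], sep="\t", index=False)
    with open(paths["report"], "w") as fh:
        _json.dump(result.report, fh, indent=1, sort_keys=True)
    return paths


def check_flanks(
    candidate: CandidateRegion,
    reference: NamedSequence,
    samples: list[SampleData],
    flank_len: int = 25,
    max_flank_variants: int = 0,
    min_depth: int = 1,
) -> tuple[str, str | None]:
    """Primer-site suitability of a candidate's flanks.

    A candidate is ``suitable`` when each ``flank_len`` bp flank carries at
    most ``max_flank_variants`` variant or N/heterozygous positions in every
    sample; candidates too close to a contig edge are unsuitable outright.
    Returns ``(verdict, reason)``.
    """
    iv = candidate.interval
    if iv.start - flank_len < 0 or iv.end + flank_len > len(reference):
        return "unsuitable", "edge"
    flanks = {
        "left_flank": GenomeInterval(iv.chrom, iv.start - flank_len, iv.start),
        "right_flank": GenomeInterval(iv.chrom, iv.end, iv.end + flank_len),
    }
    for side, flank in flanks.items():
        for sample in samples:
            track, calls, positions = _sample_prep(reference, sample)
            lo, hi = np.searchsorted(positions, [flank.start, flank.end])
            cons = build_consensus(reference, flank, calls[lo:hi], track, min_depth)
            bad_positions = {c.pos for c in calls[lo:hi]}
            bad_positions.update(
                flank.start + i for i, c in enumerate(cons.residues) if c not in "ACGT"
            )
            if len(bad_positions) > max_flank_variants:
                return "unsuitable", side
    return "suitable", None
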