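"""Seeded generator of synthetic multi-species NGS evidence with truth tables.

The generator emulates the inputs of window-based marker discovery: a random
reference, per-sample SNP call sets whose *distinct-position* density is
controlled per region, Poisson depth tracks with optional fold-inflated
duplicated blocks, low-coverage masked stretches, and heterozygous sites at a
controlled rate.  Every draw flows from one ``numpy`` Generator seeded by the
config, so the same seed reproduces byte-identical files.

Density control.  A planted block's number of distinct variant positions is
drawn from Binomial(len, density) conditioned to lie within half a standard
deviation of its mean, and background variants are placed stratified (one
such draw per 500 bp stratum).  The across-seed mean therefore stays at
``len * density`` while the realized density of every region tracks its
target tightly — a block planted at 1.5x a detection threshold reliably
exceeds the threshold and background windows reliably stay below it, which
is what makes planted-recovery experiments deterministic.

Each variant position is carried (homozygous-alt) by a non-empty proper
subset of the samples; within a planted block the subsets cycle through a
shuffled enumeration of all such subsets, so every sample pair is separated
by at least one site whenever the block holds at least as many variants as
there are subsets.
"""

from __future__ import annotations

import itertools
import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError
from .seqio import (
    DepthTrack,
    GenomeInterval,
    HET_CODES,
    NamedSequence,
    VariantCall,
    write_fasta,
)

REF_NAME = "ref1"
BACKGROUND_STRATUM = 500  # bp; stratification unit for background variants
MASK_STRETCH = 25  # bp; length of one simulated low-coverage stretch

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    seed: int
    ref_len: int = 100_000
    n_samples: int = 3
    background_density: float = 0.002
    planted_blocks: list[tuple[int, int, float]] = field(default_factory=list)
    depth_mean: float = 30.0
    duplicated_blocks: list[tuple[int, int, float]] = field(default_factory=list)
    het_rate: float = 0.0
    n_mask_rate: float = 0.0

    def __post_init__(self):
        if self.n_samples < 2:
            raise DataError("at least 2 samples are required")
        for rate in (self.background_density, self.het_rate, self.n_mask_rate):
            if not (0.0 <= rate <= 1.0):
                raise DataError(f"rate {rate} outside [0, 1]")
        blocks = sorted(self.planted_blocks)
        prev_end = 0
        for start, length, density in blocks:
            if start < prev_end:
                raise DataError("planted blocks overlap")
            if start + length > self.ref_len:
                raise DataError("planted block extends past the reference")
            if not (0.0 <= density <= 1.0):
                raise DataError(f"planted density {density} outside [0, 1]")
            prev_end = start + length
        for start, length, fold in self.duplicated_blocks:
            if fold < 2:
                raise DataError("duplication fold must be >= 2")
            if start < 0 or start + length > self.ref_len:
                raise DataError("duplicated block outside the reference")

    @property
    def sample_names(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_samples)]


@dataclass
class SimulatedSample:
    name: str
    calls: list[VariantCall]
    depth: dict[str, DepthTrack]


@dataclass
class SimulatedDataset:
    config: SimConfig
    reference: NamedSequence
    samples: list[SimulatedSample]
    truth: dict
    paths: dict | None = None


def _conditioned_binomial(rng: np.random.Generator, n: int, p: float,
                          half_width_sd: float = 0.5, max_tries: int = 10_000) -> int:
    """Binomial(n, p) draw conditioned within ``half_width_sd`` SD of its mean."""
    if n <= 0 or p <= 0.0:
        return 0
    mean = n * p
    sd = math.sqrt(n * p * (1.0 - p))
    lo, hi = mean - half_width_sd * sd, mean + half_width_sd * sd
    for _ in range(max_tries):
        k = int(rng.binomial(n, p))
        if lo <= k <= hi:
            return k
    return int(round(mean))


def _carrier_subsets(n_samples: int) -> list[tuple[int, ...]]:
    """All non-empty proper subsets of sample indices."""
    idx = range(n_samples)
    return [
        combo
        for size in range(1, n_samples)
        for combo in itertools.combinations(idx, size)
    ]


def simulate_dataset(config: SimConfig, out_dir: str | os.PathLike | None = None) -> SimulatedDataset:
    """Generate reference, per-sample calls and depth, plus a truth table.

    With ``out_dir`` set, writes ``ref.fa``, ``<sample>.vcf``,
    ``<sample>.depth.tsv`` and ``truth.json`` there (same seed, same bytes).
    """
    rng = np.random.default_rng(config.seed)
    ref_arr = _BASES[rng.integers(0, 4, size=config.ref_len)]
    ref_seq = ref_arr.tobytes().decode()
    reference = NamedSequence(REF_NAME, ref_seq)

    planted = sorted(config.planted_blocks)
    in_planted = np.zeros(config.ref_len, dtype=bool)
    for start, length, _ in planted:
        in_planted[start:start + length] = True

    subsets = _carrier_subsets(config.n_samples)
    variant_records: list[dict] = []  # {pos, ref, alt, carriers, zygosity}
    truth_blocks: list[dict] = []

    def add_variant(pos: int, carriers: tuple[int, ...], zygosity: str) -> None:
        ref_base = ref_seq[pos]
        alt_base = str(rng.choice([b for b in "ACGT" if b != ref_base]))
        variant_records.append(
            {"pos": int(pos), "ref": ref_base, "alt": alt_base,
             "carriers": list(carriers), "zygosity": zygosity}
        )

    # planted divergent blocks: tightly-controlled distinct-position density,
    # carrier subsets cycled so that every sample pair is separated
    for start, length, density in planted:
        count = _conditioned_binomial(rng, length, density)
        positions = np.sort(rng.choice(np.arange(start, start + length), size=count, replace=False))
        order = rng.permutation(len(subsets))
        for i, pos in enumerate(positions):
            add_variant(int(pos), subsets[order[i % len(subsets)]], "hom_alt")
        truth_blocks.append(
            {"start": start, "length": length, "target_density": density,
             "realized_count": int(count), "positions": [int(p) for p in positions]}
        )

    # background variants, stratified per 500 bp so local density tracks target
    for stratum_start in range(0, config.ref_len, BACKGROUND_STRATUM):
        stratum_end = min(stratum_start + BACKGROUND_STRATUM, config.ref_len)
        avail = np.arange(stratum_start, stratum_end)[~in_planted[stratum_start:stratum_end]]
        count = _conditioned_binomial(rng, len(avail), config.background_density)
        if count == 0:
            continue
        positions = np.sort(rng.choice(avail, size=count, replace=False))
        for pos in positions:
            add_variant(int(pos), subsets[rng.integers(0, len(subsets))], "hom_alt")

    taken = {rec["pos"] for rec in variant_records}

    # heterozygous sites: per sample, Bernoulli(het_rate) over free positions
    if config.het_rate > 0:
        for s in range(config.n_samples):
            n_het = _conditioned_binomial(rng, config.ref_len, config.het_rate)
            free = np.setdiff1d(np.arange(config.ref_len), np.fromiter(taken, dtype=int, count=len(taken)))
            positions = rng.choice(free, size=min(n_het, len(free)), replace=False)
            for pos in np.sort(positions):
                add_variant(int(pos), (s,), "het")
                taken.add(int(pos))

    variant_records.sort(key=lambda r: r["pos"])

    # depth: Poisson around the mean, fold-inflated in duplicated blocks,
    # zeroed in masked stretches
    depth_by_sample: list[np.ndarray] = []
    mask_stretches: list[list[tuple[int, int]]] = []
    for s in range(config.n_samples):
        depth = rng.poisson(config.depth_mean, size=config.ref_len).astype(np.int64)
        for start, length, fold in config.duplicated_blocks:
            depth[start:start + length] = (depth[start:start + length] * fold).astype(np.int64)
        stretches: list[tuple[int, int]] = []
        if config.n_mask_rate > 0:
            n_stretches = max(1, int(round(config.ref_len * config.n_mask_rate / MASK_STRETCH)))
            starts = rng.integers(0, max(1, config.ref_len - MASK_STRETCH), size=n_stretches)
            for st in np.sort(starts):
                depth[st:st + MASK_STRETCH] = 0
                stretches.append((int(st), MASK_STRETCH))
        depth_by_sample.append(depth)
        mask_stretches.append(stretches)

    samples: list[SimulatedSample] = []
    for s, name in enumerate(config.sample_names):
        calls = [
            VariantCall(REF_NAME, rec["pos"], rec["ref"], rec["alt"], rec["zygosity"], name)
            for rec in variant_records
            if s in rec["carriers"]
        ]
        track = DepthTrack(GenomeInterval(REF_NAME, 0, config.ref_len), depth_by_sample[s], sample=name)
        samples.append(SimulatedSample(name, calls, {REF_NAME: track}))

    truth = {
        "seed": config.seed,
        "ref_len": config.ref_len,
        "reference_name": REF_NAME,
        "samples": config.sample_names,
        "planted_blocks": truth_blocks,
        "duplicated_blocks": [
            {"start": start, "length": length, "fold": fold}
            for start, length, fold in config.duplicated_blocks
        ],
        "mask_stretches": {
            name: stretches for name, stretches in zip(config.sample_names, mask_stretches)
        },
        "variants": variant_records,
    }

    paths = None
    if out_dir is not None:
        paths = _write_dataset(Path(out_dir), reference, samples, truth)
    return SimulatedDataset(config, reference, samples, truth, paths)


def _write_dataset(out_dir: Path, reference: NamedSequence,
                   samples: list[SimulatedSample], truth: dict) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    ref_path = out_dir / "ref.fa"
    write_fasta([reference], ref_path)
    paths: dict = {"ref": str(ref_path), "samples": {}}
    for sample in samples:
        vcf_path = out_dir / f"{sample.name}.vcf"
        _write_vcf(sample, reference, vcf_path)
        depth_path = out_dir / f"{sample.name}.depth.tsv"
        _write_depth(sample, depth_path)
        paths["samples"][sample.name] = {"vcf": str(vcf_path), "depth": str(depth_path)}
    truth_path = out_dir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    paths["truth"] = str(truth_path)
    return paths


def _write_vcf(sample: SimulatedSample, reference: NamedSequence, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={REF_NAME},length={len(reference)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample.name}\n")
        for call in sorted(sample.calls, key=lambda c: c.pos):
            gt = "0/1" if call.zygosity == "het" else "1/1"
            fh.write(
                f"{call.chrom}\t{call.pos + 1}\t.\t{call.ref_base}\t{call.alt_base}"
                f"\t.\tPASS\t.\tGT\t{gt}\n"
            )


def _write_depth(sample: SimulatedSample, path: Path) -> None:
    with open(path, "w") as fh:
        for chrom, track in sample.depth.items():
            for pos, depth in enumerate(track.depths, start=1):
                fh.write(f"{chrom}\t{pos}\t{depth}\n")


def simulate_f1(
    native_allele: NamedSequence,
    foreign_allele: NamedSequence,
    het_miscall_rate: float = 0.0,
    seed: int = 0,
    sample: str = "F1_sim",
    locus: str = "locus",
) -> "DiploidObservation":
    """Direct-sequencing observation of a first-generation cross.

    Every site where the parents differ reads as the two-state IUPAC code;
    with probability ``het_miscall_rate`` such a site instead reads as one
    parent's base (allele dropout).  Rate 0 gives a perfect F1 trace.
    """
    from .genotyping import DiploidObservation

    if len(native_allele) != len(foreign_allele):
        raise DataError("parent alleles differ in length")
    if not (0.0 <= het_miscall_rate <= 1.0):
        raise DataError("het_miscall_rate outside [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for a, b in zip(native_allele.residues, foreign_allele.residues):
        if a == b:
            out.append(a)
        elif rng.random() < het_miscall_rate:
            out.append(a if rng.random() < 0.5 else b)
        else:
            out.append(HET_CODES[frozenset((a, b))])
    return DiploidObservation(sample=sample, locus=locus, residues="".join(out))
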