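"""Per-sample consensus construction from SNP calls and depth.

For every position of a reference interval the rule is, in order:

1. depth below ``min_depth``  -> ``N`` (undetermined),
2. homozygous-alt call        -> the alternate base,
3. heterozygous call          -> the two-state IUPAC code for {ref, alt},
4. otherwise                  -> the reference base.

Two- state ambiguity codes are the only ambiguity this module produces;
three/four-state codes never arise from biallelic SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .seqio import (
    HET_CODES,
    TWO_STATE_CODES,
    DepthTrack,
    GenomeInterval,
    NamedSequence,
    VariantCall,
)


@dataclass
class SampleConsensus:
    """One sample's inferred sequence over a reference interval."""

    sample: str
    interval: GenomeInterval
    residues: str
    n_count: int
    het_count: int

    def __post_init__(self):
        if len(self.residues) != len(self.interval):
            raise DataError("consensus length != interval length")

    @property
    def fasta_name(self) -> str:
        """Record name convention: ``sample|chrom:start1-end`` (1-based)."""
        return f"{self.sample}|{self.interval.region_string()}"

    def as_named_sequence(self) -> NamedSequence:
        return NamedSequence(self.fasta_name, self.residues)


def build_consensus(
    reference: NamedSequence,
    interval: GenomeInterval,
    calls: list[VariantCall],
    depth: DepthTrack,
    min_depth: int = 1,
) -> SampleConsensus:
    """Apply one sample's SNP calls and depth mask over ``interval``.

    ``reference`` is the full chromosome sequence; ``depth`` may cover the
    chromosome or just the interval.  Calls outside the interval and
    conflicting calls at one position are hard errors.
    """
    if interval.end > len(reference):
        raise DataError(
            f"interval {interval.region_string()} outside reference {reference.name!r}"
        )
    if depth.interval.chrom != interval.chrom:
        raise DataError("depth track chromosome does not match interval")
    if depth.interval.start > interval.start or depth.interval.end < interval.end:
        raise DataError(
            f"depth track {depth.interval.region_string()} does not cover "
            f"{interval.region_string()}"
        )

    sample = calls[0].sample if calls else (depth.sample or "sample")
    res = np.frombuffer(
        reference.residues[interval.start:interval.end].encode(), dtype="S1"
    ).copy()
    off = interval.start - depth.interval.start
    window_depth = depth.depths[off:off + len(interval)]
    low = window_depth < min_depth
    res[low] = b"N"

    seen: dict[int, VariantCall] = {}
    for call in calls:
        if call.chrom != interval.chrom or not (interval.start <= call.pos < interval.end):
            raise DataError(
                f"call at {call.chrom}:{call.pos + 1} outside {interval.region_string()}"
            )
        prev = seen.get(call.pos)
        if prev is not None:
            if (prev.alt_base, prev.zygosity) != (call.alt_base, call.zygosity):
                raise DataError(f"conflicting calls at {call.chrom}:{call.pos + 1}")
            continue  # identical duplicate
        seen[call.pos] = call
        i = call.pos - interval.start
        if low[i]:
            continue  # masked by depth; the call is not trusted there
        ref_base = reference.residues[call.pos]
        if ref_base != call.ref_base:
            raise DataError(
                f"call REF {call.ref_base} disagrees with reference {ref_base} "
                f"at {call.chrom}:{call.pos + 1}"
            )
        if call.zygosity == "hom_alt":
            res[i] = call.alt_base.encode()
        else:
            res[i] = HET_CODES[frozenset((call.ref_base, call.alt_base))].encode()

    residues = res.tobytes().decode()
    n_count = residues.count("N")
    het_count = sum(residues.count(c) for c in TWO_STATE_CODES)
    return SampleConsensus(sample, interval, residues, n_count, het_count)
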