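"""Sequence, depth, variant and distance-matrix I/O.

All coordinates are 0-based half-open internally; files that use 1-based
conventions (samtools depth, VCF, GenBank-style region strings) are converted
at this boundary.  Human-facing reports convert back to 1-based inclusive.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, ParseError

log = logging.getLogger(__name__)

#: Nucleotide alphabet accepted on input: canonical bases, N, and the
#: IUPAC ambiguity codes (two-, three- and four-state).
IUPAC_CODES = frozenset("ACGTNRYSWKMBDHV")

#: IUPAC code -> set of canonical bases it denotes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Unordered base pair -> two-state ambiguity (heterozygote) code.
HET_CODES: dict[frozenset[str], str] = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}

TWO_STATE_CODES = frozenset("RYSWKM")


@dataclass(frozen=True)
class NamedSequence:
    """A named nucleotide sequence over the IUPAC alphabet (optionally gapped)."""

    name: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise DataError(f"sequence {self.name!r} is empty")
        bad = set(self.residues) - IUPAC_CODES - {"-"}
        if bad:
            pos = next(i for i, c in enumerate(self.residues) if c in bad)
            raise DataError(
                f"sequence {self.name!r}: disallowed character {self.residues[pos]!r} "
                f"at position {pos + 1}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GenomeInterval:
    """Reference interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise DataError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def region_string(self) -> str:
        """1-based inclusive form used in reports (GenBank/Table style)."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"


@dataclass
class DepthTrack:
    """Per-position read depth over one interval of one chromosome."""

    interval: GenomeInterval
    depths: np.ndarray
    sample: str | None = None

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if len(self.depths) != len(self.interval):
            raise DataError(
                f"depth track length {len(self.depths)} != interval length {len(self.interval)}"
            )
        if (self.depths < 0).any():
            raise DataError("negative depth")


@dataclass(frozen=True)
class VariantCall:
    """One biallelic SNP call in one sample (pos is 0-based)."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    zygosity: str  # "hom_alt" | "het"
    sample: str

    def __post_init__(self):
        if self.ref_base == self.alt_base:
            raise DataError(f"ref == alt ({self.ref_base}) at {self.chrom}:{self.pos + 1}")
        if self.ref_base not in "ACGT" or self.alt_base not in "ACGT":
            raise DataError(f"non-canonical allele at {self.chrom}:{self.pos + 1}")
        if self.zygosity not in ("hom_alt", "het"):
            raise DataError(f"bad zygosity {self.zygosity!r}")


def read_fasta(path: str | os.PathLike, allow_gaps: bool = False) -> list[NamedSequence]:
    """Read a (multi-)FASTA file with strict alphabet and name checking.

    Residues are folded to uppercase.  Parse errors name the offending line.
    ``allow_gaps`` admits '-' for pre-aligned input.
    """
    records: list[NamedSequence] = []
    seen: set[str] = set()
    name: str | None = None
    chunks: list[str] = []
    header_line = 0
    allowed = IUPAC_CODES | ({"-"} if allow_gaps else set())

    def flush(line_no: int):
        nonlocal name, chunks
        if name is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"empty record {name!r}", str(path), header_line)
        records.append(NamedSequence(name, seq))
        name, chunks = None, []

    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(i)
                header = line[1:].strip()
                if not header:
                    raise ParseError("malformed header (no name)", str(path), i)
                if header in seen:
                    raise ParseError(f"duplicate record name {header!r}", str(path), i)
                seen.add(header)
                name = header
                header_line = i
            else:
                if name is None:
                    raise ParseError("sequence data before first header", str(path), i)
                up = line.upper()
                bad = set(up) - allowed
                if bad:
                    col = next(j for j, c in enumerate(up) if c in bad)
                    raise ParseError(
                        f"disallowed character {up[col]!r} in record {name!r}",
                        str(path), i,
                    )
                chunks.append(up)
        flush(-1)
    if not records:
        raise ParseError("no FASTA records found", str(path), 0)
    return records


def write_fasta(records: list[NamedSequence], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def read_depth_table(path: str | os.PathLike, sample: str | None = None) -> dict[str, DepthTrack]:
    """Read a samtools-depth style TSV (chrom, 1-based pos, depth).

    Rows must be sorted by chrom then position; missing positions are filled
    with depth 0.  Each chromosome's track spans [0, max position seen).
    """
    per_chrom: dict[str, tuple[list[int], list[int]]] = {}
    order: list[str] = []
    last: tuple[str, int] | None = None
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("expected 3 tab-separated columns", str(path), i)
            chrom, pos_s, depth_s = parts[0], parts[1], parts[2]
            try:
                pos, depth = int(pos_s), int(depth_s)
            except ValueError:
                raise ParseError(f"non-integer pos/depth {pos_s!r}/{depth_s!r}", str(path), i)
            if pos < 1:
                raise ParseError(f"position {pos} is not 1-based positive", str(path), i)
            if depth < 0:
                raise ParseError(f"negative depth {depth}", str(path), i)
            if last is not None and chrom == last[0] and pos <= last[1]:
                raise ParseError(f"unsorted or duplicate position {chrom}:{pos}", str(path), i)
            if chrom not in per_chrom:
                if chrom in order:
                    raise ParseError(f"chromosome {chrom} rows are not contiguous", str(path), i)
                per_chrom[chrom] = ([], [])
                order.append(chrom)
            per_chrom[chrom][0].append(pos - 1)
            per_chrom[chrom][1].append(depth)
            last = (chrom, pos)
    tracks: dict[str, DepthTrack] = {}
    for chrom in order:
        positions, depths = per_chrom[chrom]
        arr = np.zeros(positions[-1] + 1, dtype=np.int64)
        arr[np.asarray(positions)] = depths
        tracks[chrom] = DepthTrack(GenomeInterval(chrom, 0, len(arr)), arr, sample=sample)
    return tracks


def read_vcf_snps(path: str | os.PathLike) -> list[VariantCall]:
    """Read biallelic SNP calls with genotypes from a VCF v4.x file.

    Indels, multiallelic records and no-calls are skipped (counted in the
    log); 0/0 genotypes emit nothing.  Positions are converted to 0-based.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    calls: list[VariantCall] = []
    skipped_non_snp = 0
    skipped_no_gt = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            skipped_non_snp += 1
            continue
        ref, alt = var.REF.upper(), var.ALT[0].upper()
        if len(ref) != 1 or len(alt) != 1:
            skipped_non_snp += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown/missing, 3=hom-alt
        for sample, gt in zip(samples, var.gt_types):
            if gt == 0:
                continue
            if gt == 2:
                skipped_no_gt += 1
                log.warning("missing genotype at %s:%d for %s", var.CHROM, var.POS, sample)
                continue
            zyg = "het" if gt == 1 else "hom_alt"
            calls.append(VariantCall(var.CHROM, var.start, ref, alt, zyg, sample))
    if skipped_non_snp:
        log.info("%s: skipped %d non-SNP/multiallelic records", path, skipped_non_snp)
    if skipped_no_gt:
        log.info("%s: skipped %d genotype-less sample records", path, skipped_no_gt)
    return calls


def write_nexus_distances(labels: list[str], matrix: np.ndarray, path: str | os.PathLike) -> None:
    """Write a NEXUS TAXA + DISTANCES file readable by SplitsTree-class tools."""
    matrix = np.asarray(matrix, dtype=float)
    n = len(labels)
    if matrix.shape != (n, n):
        raise DataError(f"matrix shape {matrix.shape} does not match {n} labels")
    if np.abs(matrix - matrix.T).max(initial=0.0) > 1e-12:
        raise DataError("distance matrix is not symmetric")
    if np.abs(np.diag(matrix)).max(initial=0.0) > 1e-12:
        raise DataError("distance matrix diagonal is not zero")

    def quote(label: str) -> str:
        return f"'{label}'" if any(c.isspace() for c in label) else label

    with open(path, "w") as fh:
        fh.write("#NEXUS\n\n")
        fh.write("BEGIN TAXA;\n")
        fh.write(f"  DIMENSIONS ntax={n};\n  TAXLABELS\n")
        for lab in labels:
            fh.write(f"    {quote(lab)}\n")
        fh.write("  ;\nEND;\n\n")
        fh.write("BEGIN DISTANCES;\n")
        fh.write(f"  DIMENSIONS ntax={n};\n")
        fh.write("  FORMAT TRIANGLE=BOTH DIAGONAL LABELS;\n  MATRIX\n")
        for lab, row in zip(labels, matrix):
            vals = " ".join(f"{v:.10g}" for v in row)
            fh.write(f"    {quote(lab)} {vals}\n")
        fh.write("  ;\nEND;\n")


def write_bed(intervals: list[tuple[GenomeInterval, str, int]], path: str | os.PathLike) -> None:
    """Write BED6 rows from (interval, name, score) triples (strand '.')."""
    with open(path, "w") as fh:
        for iv, name, score in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{min(max(score, 0), 1000)}\t.\n")
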