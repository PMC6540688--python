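"""Diploid genotype decomposition and native/foreign/F1 classification.

A direct Sanger read of a diploid individual shows, at each heterozygous
position, the two-state IUPAC code for the two chromosomes.  Given a panel
of known haplotype alleles for the locus, the observation is decomposed by
exhaustive search: an unordered allele pair (x, y) is *consistent* when at
every determined position the observed state set equals {x_i, y_i}.  ``N``
positions are uninformative and constrain nothing.

Sample-level classification combines the mitochondrial haplotype origin
(maternal lineage) with the origins of the nuclear allele pairs:

=====================================  ==========================
observation                            classification
=====================================  ==========================
all loci native/native, mito native    native
  or unknown
all loci foreign/foreign, mito         foreign
  foreign or unknown
every locus heterozygous               F1_hybrid_candidate
  native/foreign (any mito)
anything else                          later_generation_or_unresolved
=====================================  ==========================

With only two or three markers a perfect multilocus heterozygote is labeled
a *candidate* first-generation hybrid, never a proven F1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .errors import DataError
from .seqio import IUPAC_SETS, NamedSequence

ORIGINS = ("native", "foreign", "unknown")

NATIVE = "native"
FOREIGN = "foreign"
UNKNOWN = "unknown"


@dataclass
class AllelePanel:
    """Known haplotype alleles for one locus, tagged with a population origin."""

    locus: str
    alleles: list[NamedSequence]
    origins: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.alleles:
            raise DataError(f"panel {self.locus!r} has no alleles")
        lengths = {len(a) for a in self.alleles}
        if len(lengths) != 1:
            raise DataError(f"panel {self.locus!r} alleles differ in length: {sorted(lengths)}")
        names = [a.name for a in self.alleles]
        if len(set(names)) != len(names):
            raise DataError(f"panel {self.locus!r} has duplicate allele names")
        for a in self.alleles:
            ambiguous = set(a.residues) - set("ACGT")
            if ambiguous:
                raise DataError(
                    f"panel allele {a.name!r} contains ambiguity codes {sorted(ambiguous)}"
                )
        for name, origin in self.origins.items():
            if origin not in ORIGINS:
                raise DataError(f"allele {name!r}: unknown origin tag {origin!r}")

    @property
    def length(self) -> int:
        return len(self.alleles[0])

    def origin_of(self, allele_name: str) -> str:
        return self.origins.get(allele_name, UNKNOWN)


@dataclass(frozen=True)
class DiploidObservation:
    """One sample's direct (unphased) sequence at one locus."""

    sample: str
    locus: str
    residues: str


@dataclass
class LocusCall:
    """Decomposition result for one locus of one sample."""

    locus: str
    pairs: set[tuple[str, str]]
    origins: tuple[str, str] | None  # origins of the (single) consistent pair

    @property
    def resolved(self) -> bool:
        return len(self.pairs) == 1


@dataclass
class HybridCall:
    sample: str
    mito_origin: str
    locus_calls: list[LocusCall]
    classification: str


def consistent_pairs(obs: DiploidObservation, panel: AllelePanel) -> set[tuple[str, str]]:
    """All unordered panel-allele pairs that explain the observation exactly.

    A pair (x, y) is consistent iff at every non-N observed position the
    observed IUPAC state set equals {x_i, y_i}.  An empty result flags a
    novel allele not representable by the panel.
    """
    if len(obs.residues) != panel.length:
        raise DataError(
            f"observation length {len(obs.residues)} != panel length {panel.length}"
        )
    informative = [
        (i, IUPAC_SETS[c])
        for i, c in enumerate(obs.residues)
        if c != "N" and c != "-"
    ]
    pairs: set[tuple[str, str]] = set()
    for x, y in itertools.combinations_with_replacement(sorted(panel.alleles, key=lambda a: a.name), 2):
        if all({x.residues[i], y.residues[i]} == states for i, states in informative):
            pairs.add((x.name, y.name))
    return pairs


def assign_mito_origin(observed: NamedSequence, references: list[NamedSequence],
                       origins: dict[str, str]) -> str:
    """Origin of the maternal lineage by exact haplotype match.

    Returns the origin tag of the first reference identical to the observed
    haplotype, or "unknown" when nothing matches.
    """
    for ref in references:
        if ref.residues == observed.residues:
            return origins.get(ref.name, UNKNOWN)
    return UNKNOWN


def classify_sample(
    mito_origin: str,
    locus_calls: list[tuple[tuple[str, str], tuple[str, str]]],
    sample: str = "sample",
) -> HybridCall:
    """Classify a sample from its mito origin and per-locus allele-pair origins.

    ``locus_calls`` is a list of ((allele_x, allele_y), (origin_x, origin_y))
    tuples, one per diagnostic nuclear locus.
    """
    if mito_origin not in ORIGINS:
        raise DataError(f"unknown mito origin {mito_origin!r}")
    if not locus_calls:
        raise DataError("at least one locus call is required")
    origin_sets = [frozenset(origins) for _, origins in locus_calls]
    all_native = all(s == {NATIVE} for s in origin_sets)
    all_foreign = all(s == {FOREIGN} for s in origin_sets)
    all_het = all(s == {NATIVE, FOREIGN} for s in origin_sets)
    if all_native and mito_origin in (NATIVE, UNKNOWN):
        classification = NATIVE
    elif all_foreign and mito_origin in (FOREIGN, UNKNOWN):
        classification = FOREIGN
    elif all_het:
        classification = "F1_hybrid_candidate"
    else:
        classification = "later_generation_or_unresolved"
    calls = [
        LocusCall(locus=f"locus{i + 1}", pairs={tuple(sorted(pair))}, origins=origins)
        for i, (pair, origins) in enumerate(locus_calls)
    ]
    return HybridCall(sample, mito_origin, calls, classification)


def genotype_sample(
    sample: str,
    observations: list[DiploidObservation],
    panels: dict[str, AllelePanel],
    mito_observed: NamedSequence | None = None,
    mito_references: list[NamedSequence] | None = None,
    mito_origins: dict[str, str] | None = None,
) -> HybridCall:
    """End-to-end genotyping: decompose each locus, then classify.

    Loci whose decomposition is ambiguous (zero or several consistent pairs)
    force the classification to ``later_generation_or_unresolved``.
    """
    if not observations:
        raise DataError("no locus observations supplied")
    mito_origin = UNKNOWN
    if mito_observed is not None and mito_references:
        mito_origin = assign_mito_origin(mito_observed, mito_references, mito_origins or {})

    locus_calls: list[LocusCall] = []
    resolved: list[tuple[tuple[str, str], tuple[str, str]]] = []
    for obs in observations:
        panel = panels.get(obs.locus)
        if panel is None:
            raise DataError(f"no panel for locus {obs.locus!r}")
        pairs = consistent_pairs(obs, panel)
        origins = None
        if len(pairs) == 1:
            (pair,) = pairs
            origins = (panel.origin_of(pair[0]), panel.origin_of(pair[1]))
            resolved.append((pair, origins))
        locus_calls.append(LocusCall(obs.locus, pairs, origins))

    if len(resolved) == len(observations):
        call = classify_sample(mito_origin, resolved, sample=sample)
        classification = call.classification
    else:
        classification = "later_generation_or_unresolved"
    return HybridCall(sample, mito_origin, locus_calls, classification)
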