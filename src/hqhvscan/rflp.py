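"""In-silico restriction digestion and PCR-RFLP assay design.

Models linear PCR amplicons cut by type II restriction enzymes with
(possibly degenerate) recognition sites.  A diploid sample's band pattern is
the multiset union of its two allele digests — both chromosomes amplify and
digest independently, and band intensity is not modeled.  Whether two
patterns can be told apart on a gel is parameterized by a minimal detectable
fragment size and a length resolution (defaults chosen for a 3% agarose gel).

Built-in enzymes are the two used for the sika deer assays: Rsa I (GT^AC)
for cytochrome b / C02 and HpyCH4IV (A^CGT) for C22.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from Bio.Seq import Seq

from .errors import DataError
from .seqio import IUPAC_SETS, NamedSequence


@dataclass(frozen=True)
class Enzyme:
    """Restriction enzyme: IUPAC recognition site and top-strand cut offset."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self):
        if len(self.recognition) < 4:
            raise DataError(f"{self.name}: recognition site shorter than 4 bp")
        if not (0 <= self.cut_offset <= len(self.recognition)):
            raise DataError(f"{self.name}: cut offset outside recognition site")
        bad = set(self.recognition) - set(IUPAC_SETS)
        if bad:
            raise DataError(f"{self.name}: invalid recognition characters {bad}")
        if set(self.recognition) == {"N"}:
            raise DataError(f"{self.name}: recognition site is all-N")

    @property
    def is_palindromic(self) -> bool:
        return str(Seq(self.recognition).reverse_complement()) == self.recognition


RSA_I = Enzyme("RsaI", "GTAC", 2)
HPYCH4IV = Enzyme("HpyCH4IV", "ACGT", 1)
BUILTIN_ENZYMES: dict[str, Enzyme] = {e.name: e for e in (RSA_I, HPYCH4IV)}


@dataclass
class FragmentPattern:
    """Multiset of restriction-fragment lengths from one digestion."""

    fragments: Counter
    source: str

    @property
    def total_bp(self) -> int:
        return sum(length * k for length, k in self.fragments.items())

    def sorted_lengths(self) -> list[int]:
        return sorted(self.fragments.elements())


@dataclass(frozen=True)
class GelModel:
    """Detectability model for agarose electrophoresis."""

    min_detectable: int = 50
    resolution: int = 20

    def __post_init__(self):
        if self.min_detectable <= 0 or self.resolution <= 0:
            raise DataError("gel parameters must be positive")

    def visible_bands(self, pattern: FragmentPattern) -> list[int]:
        return [l for l in pattern.sorted_lengths() if l >= self.min_detectable]

    def equivalent(self, a: FragmentPattern, b: FragmentPattern) -> bool:
        """True when the two patterns cannot be told apart on this gel."""
        va, vb = self.visible_bands(a), self.visible_bands(b)
        if len(va) != len(vb):
            return False
        return all(abs(x - y) < self.resolution for x, y in zip(va, vb))

    def distinguishing_bands(self, a: FragmentPattern, b: FragmentPattern) -> int:
        """Number of visible bands left unmatched after greedy pairing."""
        va, vb = self.visible_bands(a), self.visible_bands(b)
        i = j = matched = 0
        while i < len(va) and j < len(vb):
            if abs(va[i] - vb[j]) < self.resolution:
                matched += 1
                i += 1
                j += 1
            elif va[i] < vb[j]:
                i += 1
            else:
                j += 1
        return (len(va) - matched) + (len(vb) - matched)


def _check_digestible(seq: NamedSequence) -> None:
    bad = set(seq.residues) - set("ACGT")
    if bad:
        raise DataError(
            f"{seq.name!r} contains ambiguity codes {sorted(bad)}: "
            "resolve alleles before digestion"
        )


def _top_strand_matches(residues: str, pattern: str) -> list[int]:
    """Start positions of all (overlapping) IUPAC-pattern matches."""
    sets = [IUPAC_SETS[c] for c in pattern]
    L = len(pattern)
    return [
        i for i in range(len(residues) - L + 1)
        if all(residues[i + k] in sets[k] for k in range(L))
    ]


def find_sites(seq: NamedSequence, enzyme: Enzyme) -> list[int]:
    """Top-strand cut coordinates (0-based, between bases), sorted, unique.

    For a non-palindromic recognition site the reverse-complement strand is
    also searched, with the mirrored cut offset.  Cuts at the very ends of a
    linear molecule (which would release an empty fragment) are dropped.
    """
    _check_digestible(seq)
    L = len(enzyme.recognition)
    cuts = {m + enzyme.cut_offset for m in _top_strand_matches(seq.residues, enzyme.recognition)}
    if not enzyme.is_palindromic:
        rc_pattern = str(Seq(enzyme.recognition).reverse_complement())
        mirrored = L - enzyme.cut_offset
        cuts |= {m + mirrored for m in _top_strand_matches(seq.residues, rc_pattern)}
    return sorted(c for c in cuts if 0 < c < len(seq))


def digest(seq: NamedSequence, enzyme: Enzyme) -> FragmentPattern:
    """Digest a linear molecule; fragment lengths always sum to its length."""
    cuts = find_sites(seq, enzyme)
    bounds = [0, *cuts, len(seq)]
    fragments = Counter(b - a for a, b in zip(bounds, bounds[1:]))
    return FragmentPattern(fragments, source=f"{seq.name}/{enzyme.name}")


def diploid_pattern(allele_a: NamedSequence, allele_b: NamedSequence, enzyme: Enzyme) -> FragmentPattern:
    """Band pattern of a diploid: multiset union of the two allele digests."""
    pa, pb = digest(allele_a, enzyme), digest(allele_b, enzyme)
    return FragmentPattern(pa.fragments + pb.fragments, source=f"{allele_a.name}+{allele_b.name}/{enzyme.name}")


def select_diagnostic_enzymes(
    group_a: list[NamedSequence],
    group_b: list[NamedSequence],
    catalog: list[Enzyme] | None = None,
    gel: GelModel | None = None,
) -> list[tuple[Enzyme, dict]]:
    """Search a catalog for enzymes whose digests separate two allele groups.

    An enzyme is diagnostic when all alleles within each group give
    gel-equivalent patterns and the two group patterns are distinguishable.
    Results are sorted by number of distinguishing bands (descending), ties
    broken by enzyme name.
    """
    if not group_a or not group_b:
        raise DataError("both allele groups must be non-empty")
    catalog = list(BUILTIN_ENZYMES.values()) if catalog is None else catalog
    if not catalog:
        raise DataError("empty enzyme catalog")
    gel = gel or GelModel()
    results = []
    for enz in catalog:
        pats_a = [digest(s, enz) for s in group_a]
        pats_b = [digest(s, enz) for s in group_b]
        uniform_a = all(gel.equivalent(pats_a[0], p) for p in pats_a[1:])
        uniform_b = all(gel.equivalent(pats_b[0], p) for p in pats_b[1:])
        n_dist = gel.distinguishing_bands(pats_a[0], pats_b[0])
        diagnostic = uniform_a and uniform_b and not gel.equivalent(pats_a[0], pats_b[0])
        results.append((
            enz,
            {
                "diagnostic": diagnostic,
                "uniform_within_groups": uniform_a and uniform_b,
                "distinguishing_bands": n_dist if diagnostic else 0,
                "group_a_bands": gel.visible_bands(pats_a[0]),
                "group_b_bands": gel.visible_bands(pats_b[0]),
            },
        ))
    results.sort(key=lambda item: (-item[1]["distinguishing_bands"], item[0].name))
    return results


def read_enzyme_catalog(path: str) -> list[Enzyme]:
    """Read a TSV catalog (name, recognition, cut_offset); '#' lines ignored."""
    enzymes: list[Enzyme] = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise DataError(f"{path}:{i}: expected 3 tab-separated columns")
            try:
                enzymes.append(Enzyme(parts[0], parts[1].upper(), int(parts[2])))
            except ValueError:
                raise DataError(f"{path}:{i}: cut_offset must be an integer")
    if not enzymes:
        raise DataError(f"{path}: no enzymes found")
    return enzymes
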