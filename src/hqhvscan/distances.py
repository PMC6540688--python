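"""Uncorrected p-distance with pairwise deletion and "average states" handling.

The p-distance between two pre-aligned sequences is the fraction of compared
sites at which they differ.  Sites where either sequence is undetermined
(``N``) or gapped (``-``) are excluded from the comparison (pairwise
deletion).

Diploid Sanger sequences carry IUPAC ambiguity codes at heterozygous sites.
In ``average_states`` mode an ambiguous site contributes its expected
mismatch under independent uniform resolution of each sequence's state set:

    d_site = 1 - |S_a n S_b| / (|S_a| * |S_b|)

so e.g. A vs R (={A,G}) contributes 1/2 and R vs R contributes 1/2 (of the
four ordered resolutions, AA and GG match).  ``strict`` mode compares
characters literally and is intended for haploid markers (mitochondrial
cytochrome b) without ambiguity codes.

The across-pair variance of a set of pairwise distances uses divisor n
(population variance); with three taxa there are exactly three pairs and this
is the only reading that reproduces published 4-decimal variance values from
their printed distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .seqio import IUPAC_SETS, NamedSequence

MODES = ("strict", "average_states")

# 256x256 lookup tables over ASCII codes: per-site mismatch contribution and
# comparability mask.  N and '-' are non-comparable (pairwise deletion).
_EXCLUDED = {"N", "-"}


def _build_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    avg = np.zeros((256, 256), dtype=np.float64)
    strict = np.zeros((256, 256), dtype=np.float64)
    mask = np.zeros((256, 256), dtype=bool)
    codes = [c for c in IUPAC_SETS if c not in _EXCLUDED]
    for a in codes:
        sa = IUPAC_SETS[a]
        for b in codes:
            sb = IUPAC_SETS[b]
            ia, ib = ord(a), ord(b)
            mask[ia, ib] = True
            avg[ia, ib] = 1.0 - len(sa & sb) / (len(sa) * len(sb))
            strict[ia, ib] = 0.0 if a == b else 1.0
    return avg, strict, mask


_AVG_TABLE, _STRICT_TABLE, _COMPARABLE = _build_tables()


@dataclass(frozen=True)
class DistanceResult:
    pair: tuple[str, str]
    distance: float
    sites_compared: int


def p_distance(a: NamedSequence, b: NamedSequence, mode: str = "strict") -> DistanceResult:
    """Uncorrected p-distance between two pre-aligned sequences.

    Raises if the lengths differ or no site is comparable in this pair.
    """
    if mode not in MODES:
        raise DataError(f"unknown distance mode {mode!r}")
    if len(a) != len(b):
        raise DataError(
            f"length mismatch: {a.name!r} has {len(a)} bp, {b.name!r} has {len(b)} bp"
        )
    ia = np.frombuffer(a.residues.encode(), dtype=np.uint8)
    ib = np.frombuffer(b.residues.encode(), dtype=np.uint8)
    comparable = _COMPARABLE[ia, ib]
    n = int(comparable.sum())
    if n == 0:
        raise DataError(f"no comparable sites between {a.name!r} and {b.name!r}")
    table = _AVG_TABLE if mode == "average_states" else _STRICT_TABLE
    dist = float(table[ia[comparable], ib[comparable]].sum() / n)
    return DistanceResult((a.name, b.name), dist, n)


def variance_across_pairs(distances: list[float]) -> float:
    """Population variance (divisor n) of a set of pairwise distances."""
    if len(distances) < 2:
        raise DataError("variance requires at least 2 pairwise distances")
    return float(np.var(np.asarray(distances, dtype=float)))


def distance_matrix(
    sequences: list[NamedSequence], mode: str = "strict"
) -> tuple[list[str], np.ndarray]:
    """Symmetric p-distance matrix over a set of equal-length sequences."""
    if len(sequences) < 2:
        raise DataError("distance matrix requires at least 2 sequences")
    labels = [s.name for s in sequences]
    n = len(sequences)
    mat = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                res = p_distance(sequences[i], sequences[j], mode=mode)
            except DataError as exc:
                raise DataError(f"pair ({labels[i]}, {labels[j]}): {exc}") from exc
            mat[i, j] = mat[j, i] = res.distance
    return labels, mat
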