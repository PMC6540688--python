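"""Independent reference implementations used to cross-check the package.

These deliberately take a different route from the library code: per-site
enumeration instead of set-intersection arithmetic for distances, and
regex-based splitting instead of positional scanning for digestion.
"""

import re
from collections import Counter

from hqhvscan import Enzyme
from hqhvscan.seqio import IUPAC_SETS

_CLASS = {c: "[" + "".join(sorted(IUPAC_SETS[c])) + "]" for c in IUPAC_SETS}


def average_states_oracle(a: str, b: str):
    """Expected mismatch under uniform resolution, by per-site enumeration."""
    total, n = 0.0, 0
    for ca, cb in zip(a, b):
        if ca in "N-" or cb in "N-":
            continue
        resolutions = [
            (ra, rb) for ra in sorted(IUPAC_SETS[ca]) for rb in sorted(IUPAC_SETS[cb])
        ]
        total += sum(ra != rb for ra, rb in resolutions) / len(resolutions)
        n += 1
    return (total / n, n) if n else (None, 0)


def regex_cut_oracle(residues: str, enzyme: Enzyme) -> list:
    """Cut coordinates via regex lookahead (overlapping matches)."""
    pattern = "(?=" + "".join(_CLASS[c] for c in enzyme.recognition) + ")"
    cuts = {m.start() + enzyme.cut_offset for m in re.finditer(pattern, residues)}
    return sorted(c for c in cuts if 0 < c < len(residues))


def regex_split_oracle(residues: str, enzyme: Enzyme) -> Counter:
    cuts = regex_cut_oracle(residues, enzyme)
    bounds = [0, *cuts, len(residues)]
    return Counter(b - a for a, b in zip(bounds, bounds[1:]))
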