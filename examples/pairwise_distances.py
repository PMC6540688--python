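"""Uncorrected p-distances with heterozygote-aware averaging.

Compares strict distances (literal site mismatches, for haploid markers
like mitochondrial cytochrome b) with average-states distances, where an
IUPAC heterozygote code contributes its expected mismatch over uniform
resolutions — e.g. A vs R(=A/G) counts 0.5.  Also shows the across-pair
variance used to rank candidate regions, and the NEXUS export consumed by
phylogenetic-network software.
"""

import tempfile
from pathlib import Path

from hqhvscan import (
    NamedSequence,
    distance_matrix,
    p_distance,
    variance_across_pairs,
    write_nexus_distances,
)

red_deer = NamedSequence("red_deer", "ACGTACGTACGTACGTACGT")
elk = NamedSequence("elk", "ACGTACGAACGTACGTACGT")
diploid = NamedSequence("diploid_sample", "ACGTACGRACGTACGTACGY")

strict = p_distance(red_deer, elk, mode="strict")
print(f"strict p-distance red_deer vs elk: {strict.distance:.4f} "
      f"over {strict.sites_compared} sites")

avg = p_distance(red_deer, diploid, mode="average_states")
print(f"average-states p-distance red_deer vs diploid: {avg.distance:.4f} "
      "(two heterozygous sites contribute 0.5 each)")

three_pair = [0.01, 0.042, 0.04]
print(f"across-pair variance of {three_pair}: "
      f"{variance_across_pairs(three_pair):.4f} (divisor n)")

labels, matrix = distance_matrix([red_deer, elk, diploid], mode="average_states")
out = Path(tempfile.mkdtemp()) / "distances.nex"
write_nexus_distances(labels, matrix, out)
print(f"\nNEXUS distance matrix written to {out}:")
print(out.read_text())
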