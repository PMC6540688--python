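"""Design a PCR-RFLP assay separating native from foreign alleles.

The foreign allele carries a SNP that creates a Rsa I site (GT^AC) absent
from the native allele, so a single digestion distinguishes the two — and a
heterozygous F1 shows both the cut and the uncut bands, exactly the pattern
used to spot hybrids on a gel.
"""

from hqhvscan import (
    BUILTIN_ENZYMES,
    GelModel,
    NamedSequence,
    digest,
    diploid_pattern,
    select_diagnostic_enzymes,
)

native = NamedSequence("native_J1", "C" * 150 + "GTTC" + "C" * 146)
foreign = NamedSequence("foreign_O1", "C" * 150 + "GTAC" + "C" * 146)

results = select_diagnostic_enzymes([native], [foreign], gel=GelModel())
print("enzyme search (3% agarose, >=50 bp visible, 20 bp resolution):")
for enzyme, verdict in results:
    print(f"  {enzyme.name:10s} diagnostic={verdict['diagnostic']} "
          f"native bands {verdict['group_a_bands']} "
          f"foreign bands {verdict['group_b_bands']}")

rsa = BUILTIN_ENZYMES["RsaI"]
print(f"\nnative digest:  {digest(native, rsa).sorted_lengths()} bp")
print(f"foreign digest: {digest(foreign, rsa).sorted_lengths()} bp")
het = diploid_pattern(native, foreign, rsa)
print(f"heterozygote:   {het.sorted_lengths()} bp "
      "(uncut native band plus both foreign cut products)")
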