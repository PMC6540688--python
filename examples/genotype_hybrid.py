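"""Classify a sample as a first-generation hybrid candidate.

Simulates the direct Sanger trace of an F1 cross between a native and a
foreign allele at two nuclear loci, decomposes each trace against the
allele panel, combines with a foreign mitochondrial haplotype, and applies
the classification rule table: heterozygous native/foreign at every
diagnostic locus -> F1 hybrid candidate.
"""

import numpy as np

from hqhvscan import AllelePanel, NamedSequence, genotype_sample, simulate_f1

rng = np.random.default_rng(8)


def make_locus(locus, n_diagnostic_sites):
    res = "".join(rng.choice(list("ACGT"), size=80))
    native = NamedSequence(f"J_{locus}", res)
    mutated = list(res)
    for pos in rng.choice(80, size=n_diagnostic_sites, replace=False):
        mutated[pos] = str(rng.choice([b for b in "ACGT" if b != mutated[pos]]))
    foreign = NamedSequence(f"O_{locus}", "".join(mutated))
    panel = AllelePanel(locus, [native, foreign],
                        {native.name: "native", foreign.name: "foreign"})
    return panel, native, foreign


panels, observations = {}, []
for locus, sites in (("C02", 5), ("C22", 3)):
    panel, native, foreign = make_locus(locus, sites)
    panels[locus] = panel
    obs = simulate_f1(native, foreign, het_miscall_rate=0.0, seed=3,
                      sample="Msk", locus=locus)
    observations.append(obs)
    print(f"{locus}: observed trace has "
          f"{sum(c not in 'ACGT' for c in obs.residues)} heterozygous site(s)")

mito_refs = [NamedSequence("hap_native", "ACGTACGT"), NamedSequence("hap_foreign", "TGCATGCA")]
call = genotype_sample(
    "Msk", observations, panels,
    mito_observed=NamedSequence("Msk_mito", "TGCATGCA"),
    mito_references=mito_refs,
    mito_origins={"hap_native": "native", "hap_foreign": "foreign"},
)

print(f"\nmitochondrial origin: {call.mito_origin} (maternal lineage)")
for lc in call.locus_calls:
    print(f"{lc.locus}: consistent allele pair(s) {sorted(lc.pairs)} "
          f"origins {lc.origins}")
print(f"classification: {call.classification}")
print("\nEvery nuclear locus is heterozygous with one native and one foreign "
      "allele and the maternal line is foreign — the signature of a "
      "first-generation cross (labelled a candidate, not proof).")
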