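# Methods

## Problem setting

Hybridization between an introduced population and a native relative can
erode the native gene pool through introgression. Detecting it requires
nuclear markers that are (a) reliably amplifiable and Sanger-sequenceable,
(b) divergent enough between the source taxa to assign allele origin, and
(c) drawn from single-copy regions so that paralogy does not masquerade as
polymorphism. `hqhvscan` implements the desk half of that program: finding
such markers in mapped public NGS data, quantifying their divergence,
turning them into restriction-digest assays, and reading multilocus
genotypes back into a hybrid/native/foreign classification.

## Consensus construction

Each sample's inferred sequence over an interval is built positionwise
from its biallelic SNP calls and a depth track: depth below `min_depth`
(default 1, i.e. any coverage is trusted) gives `N`; a homozygous-alt call
substitutes the alternate base; a heterozygous call gives the two-state
IUPAC code of {ref, alt}; otherwise the reference base stands. The depth
mask wins over calls at the same position, conflicting calls at one
position are a hard error (they indicate an upstream caller problem rather
than something to paper over), and only two-state ambiguity codes can be
produced since inputs are biallelic SNPs.

## HQHV window scan

Windows of `window_len` (default 500 bp — the span one Sanger read can
confirm) are tiled at `step` (default = window length; sliding windows are
a flag away). Four filters run in a fixed order so that each window has
exactly one rejection reason and the report categories partition the
evaluated windows:

| filter | statistic | default rule |
|---|---|---|
| coverage | window mean depth ÷ sample global mean depth | reject if any sample deviates from 1 by more than `cov_tol` = 0.1 |
| nhet | (N + heterozygous consensus positions) ÷ window length | reject if ≥ `max_nhet_frac` = 0.01 in any sample |
| density | distinct variant positions (union over samples) ÷ window length | reject unless strictly > `min_snp_density` = 0.01 |
| distance | pairwise consensus p-distances (average-states) | retain iff the minimum ≥ `min_pair_distance` = 0.001 |

Rationale for the less obvious choices:

- **Coverage as a ratio to the sample's own global mean.** The point of
  the coverage rule is to exclude duplicated genomic regions, which show
  up as relative coverage inflation (≈ fold × mean); an absolute depth
  band would conflate library size with copy number. The baseline is the
  arithmetic mean over every position of the sample's depth tracks.
- **Union density.** Distinct variant positions across all samples is the
  quantity relevant to *between-taxon* diversity; a per-sample density
  mode would double-count shared variation. The inequality is strict: at
  500 bp, 5 variants (exactly 1/100 bp) fails, 6 passes.
- **Variance reported, not filtered.** The across-pair variance of the
  pairwise distances is computed (divisor *n*, see below) and reported for
  every candidate, but by default is not a filter: empirically useful
  candidate regions routinely show variances well below any threshold that
  distances themselves would pass, and the two criteria are nearly
  redundant when only three pairs exist. An opt-in `min_pair_variance`
  restores variance filtering for users who want it.
- **Flank check instead of primer design.** `check_flanks` verifies that
  `flank_len` (default 25 bp) on each side is free of variant or N/het
  positions in every sample — the property that makes conserved primers
  possible. Thermodynamic primer design is deliberately out of scope;
  candidates at contig edges are unsuitable outright.

## Distances

The p-distance is the uncorrected mismatch fraction over compared sites;
sites where either sequence is `N` or `-` are excluded (pairwise
deletion), and alignment is assumed done upstream. For diploid Sanger
sequences, **average-states** mode treats an IUPAC code as a uniform
distribution over its state set and scores a site by the expected
mismatch under independent resolution:

    d_site = 1 − |S_a ∩ S_b| / (|S_a| · |S_b|)

so A vs R = 1/2, R vs R = 1/2 (of AA, AG, GA, GG only the homozygous
resolutions match), R vs Y = 1. On ambiguity-free input this reduces
exactly to strict mode. The implementation uses a precomputed 256×256
contribution table; the test suite checks it against an independent
per-site enumeration of all joint resolutions.

**Variance divisor.** The variance across the three species pairs uses
divisor *n* (population variance): the three printed 4-decimal variance
cells of the source data are all reproduced from their own printed
distances under divisor *n*, and none under *n* − 1, which settles the
convention empirically. Reports round to 4 decimals; internal values are
full precision. With exactly two samples there is a single pair and the
variance is reported as 0.

## Restriction digestion and assay design

Recognition sites may contain degenerate IUPAC characters; query
sequences may not (alleles must be resolved before digestion — a diploid
trace is digested as its two alleles, never as an ambiguous string).
Matching scans every position of the top strand (overlaps included); for
non-palindromic sites the reverse-complement pattern is also searched with
the mirrored cut offset. Molecules are linear amplicons: fragments are the
gaps between consecutive cut coordinates and always sum to the sequence
length; cuts that would release an empty fragment at an end are dropped.
The top-strand cut coordinate is the fragment boundary, which for
staggered palindromic cutters (e.g. HpyCH4IV, 2-nt 5′ overhangs) means
strand-flip symmetry of fragment lengths holds only up to the overhang;
for blunt cutters (Rsa I) it is exact.

A diploid's band pattern is the multiset union of its two allele digests
(both chromosomes amplify and digest independently; intensity is not
modeled). Gel distinguishability is parameterized by `min_detectable`
(default 50 bp — smaller fragments run off or are too faint on 3%
agarose) and `resolution` (default 20 bp): two patterns are
gel-equivalent iff, after dropping invisible fragments, their sorted band
lists have equal length and every aligned pair differs by less than the
resolution. An enzyme is *diagnostic* for two allele groups when each
group is internally gel-uniform and the groups' patterns are
distinguishable; candidates are ranked by the number of unmatched bands.
Partial digestion, star activity and methylation sensitivity are not
modeled.

## Genotype decomposition and classification

A diploid observation is matched against every unordered pair from the
locus's allele panel (including self-pairs): a pair is consistent iff at
every determined position the observed IUPAC state set equals the set of
the two allele bases. `N` is uninformative — Sanger dropouts should not
veto otherwise perfect pairs — so low-quality traces may return several
consistent pairs, and a trace no pair explains returns the empty set
(novel-allele flag). Panel origin tags (`native`/`foreign`/`unknown`) are
user metadata from control populations, never inferred.

Classification is a pure rule table over the mitochondrial origin (exact
haplotype match against tagged references) and the per-locus origin
pairs: all-native loci with native/unknown mito → `native`; all-foreign
with foreign/unknown mito → `foreign`; heterozygous native/foreign at
*every* locus → `F1_hybrid_candidate` regardless of mito (the maternal
line only tells which direction the cross went); everything else,
including unresolved or ambiguous loci, → `later_generation_or_unresolved`.
With two or three markers, multilocus heterozygosity is strong but not
conclusive evidence of a first-generation cross, hence "candidate".

## Synthetic data

The generator emulates the scan's upstream evidence: a uniform-random
reference, per-sample biallelic SNP calls, Poisson(`depth_mean`, default
30×) depth, optional fold-inflated duplicated blocks, optional
low-coverage masked stretches (25 bp units at total rate `n_mask_rate`)
and optional per-sample heterozygous sites at rate `het_rate`. Noise
rates default to 0 so that the canonical datasets isolate the signal
under study; tests switch them on explicitly. All draws flow from one
`numpy` generator seeded by the config, making outputs byte-identical
across runs.

**Density control.** Each planted block's number of distinct variant
positions is a Binomial(len, density) draw conditioned (by rejection) to
lie within 0.5 SD of its mean, and background variants are placed one
stratum at a time (500 bp strata, same conditioned draw). A plain
binomial draw would leave a ~24% chance per block that a block planted at
1.5× the density threshold falls at or below it (and a ~10% chance per
100 kb that a background window spuriously exceeds it), making
recovery experiments fail on a large fraction of seeds for reasons that
have nothing to do with the scanner; the conditioned draw keeps the
across-seed mean at n·p while guaranteeing the designed separation, which
is the property such experiments exist to probe. Carrier subsets within a
planted block cycle through a shuffled enumeration of all non-empty
proper sample subsets, so every sample pair is separated whenever the
block holds at least as many variants as there are subsets (6 at three
samples; planted blocks at the default design hold 7–8).

**What passing tests do and do not show.** The simulator exercises the
scanner's decision logic — filter thresholds, ordering, accounting,
recovery — under controlled separation. It does not model read-level
error, mapping bias, indels, linked variation or realistic coalescent
structure, so green tests certify the algorithm, not performance on any
particular real genome.

## Problem sizes and numerics

The canonical recovery dataset is 100 kb × 3 samples (200 windows),
which the scan processes in well under a second; oracle sweeps use 1,000
random instances each. Distance agreement with the enumeration oracle is
asserted to 1e−12; digestion agreement and fragment-length conservation
are exact. NEXUS export rejects asymmetry beyond 1e−12. Internal
coordinates are 0-based half-open everywhere; all human-facing strings
(FASTA record names, region reports, BED is the exception by format) are
1-based inclusive.

## Known limitations

- Consumes upstream SNP calls as given: no genotype likelihoods, base
  qualities or indel handling.
- Pre-aligned input is assumed for distances; no aligner is bundled.
- The average-states formalization is the expected-mismatch definition
  above; bit-exact agreement with any particular network program's
  internal normalization is not guaranteed.
- Mitochondrial origin assignment is exact-match only; divergent novel
  haplotypes come back `unknown` rather than being placed
  phylogenetically.
- The enzyme catalog is user-supplied TSV plus two built-ins; no REBASE
  ingestion.
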