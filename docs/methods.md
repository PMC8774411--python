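# Methods

## Setting

A reverse genetic screen on a genotyped breeding population flags a
haplotype with a significant deficit of homozygous animals — the signature
of a linked recessive lethal. `recleth` covers everything downstream of
that flag: finding the causal candidate in sequenced carrier/non-carrier
genomes, classifying its protein consequence, and validating it in the
genotyped cohort and in deliberate carrier × carrier ("at-risk") matings.

## Concordance filter

Candidates must satisfy, within the mapped region extended by `flank_bp`
(default 1,000,000 bp) and with call quality strictly greater than
`min_qual` (default 30):

1. the alternate allele differs from the reference assembly;
2. heterozygous in **every** sequenced haplotype carrier;
3. homozygous reference in **every** other sequenced genome (the
   within-breed non-carriers *and* the unrelated breeds; an explicit
   non-carrier id set may be supplied instead).

A missing genotype at any required sample fails the variant. This is the
conservative direction for a screen: a false positive costs a manual
genome-browser check, while a false negative discards the causal variant.
Each dropped variant records exactly one first-fail reason in the fixed
order region → quality → carrier condition → non-carrier condition →
impact, so the funnel counts are reproducible and monotone. The filter is
idempotent and anti-monotone in the non-carrier constraint set (removing a
required sample can only grow the survivor set); both properties are
tested against a brute-force per-variant predicate.

## Consequence engine

The engine handles exactly what the screen needs: single-nucleotide
substitutions against one transcript model. The model stores genomic
exons in transcript order, the strand, the spliced sense-strand sequence,
the 1-based transcript offset of the CDS start and the CDS length
(terminal stop included; the reference protein length excludes it, so a
498-residue protein has a 1497-nt CDS). Mapping is by cumulative exon
arithmetic; on the minus strand alleles are reverse-complemented. A
reference-consistency check (model base vs strand-adjusted VCF REF) is a
hard error, because a silent coordinate slip would invalidate every call.

Classification translates the reference and mutated CDS in full and
compares: an earlier in-frame stop is `stop_gained` (impact HIGH, and the
truncated length always equals codon_index − 1), an amino-acid change is
`missense` (MODERATE), no protein change is `synonymous` (LOW), UTR /
intronic / intergenic positions are MODIFIER. A substitution destroying
the terminal stop is reported as `stop_lost` but kept at MODERATE: HIGH is
reserved for stop-gains, the one severity class this screen acts on.
InDels pass through unclassified (`unsupported`, MODIFIER, with a
warning) rather than erroring, so a mixed input VCF can still be swept.

### Coding-coordinate dialects

Strict HGVS counts c.1 at the A of the initiator ATG (`dialect="cds"`).
Annotation pipelines sometimes number through the 5′UTR from transcript
base 1; `dialect="transcript"` reproduces that convention. The packaged
gene-model fixture uses a 190-nt 5′UTR so that the stop-gain at CDS
position 331 (codon 111) sits at transcript position 521 and the
transcript dialect prints `c.521G>T` — the printed form for this variant.
The 190-nt UTR is a coordinate-reconciling assumption of the fixture, not
an annotated UTR length, and the strict-HGVS name of the same call is
`c.331G>T`.

## Statistics

- **Homozygote deficiency**: p = P(X ≤ O) for X ~ Poisson(λ = E), with
  deficit D = (E − O)/E. The Poisson lower tail at (O = 3, E = 72) gives
  3.49 × 10⁻²⁷, matching the screen's published value, which is the
  evidence for this model choice; an exact binomial lower tail is provided
  for sensitivity analysis. Accuracy of the tail is verified to ≥ 6
  significant digits against 80-digit term-by-term summation for E ≤ 200.
- **Association**: two-sided Fisher exact test by the probability-mass
  rule, verified against exhaustive rational-arithmetic enumeration of the
  hypergeometric support for tables with N ≤ 40.
- **Hardy–Weinberg**: Pearson χ² against n(1−q̂)², 2nq̂(1−q̂), nq̂² with q̂
  from the same counts, df = 1, *no* continuity correction — Yates'
  correction would give p ≈ 0.52 for counts (5, 6, 5) where the
  uncorrected test gives the canonical 0.317. Monomorphic samples return
  χ² = 0, p = 1 with a warning.
- **Segregation**: offspring genotype counts pooled over matings, each
  lamb contributing its parental pair's Mendelian class probabilities to
  the expectation; genotypes impossible given the parents are flagged as
  Mendelian errors and excluded with a log record. df is (#classes with
  nonzero expectation − 1), or 1 in the Hardy-Weinberg-style mode.
- **Exact rank-sum**: the permutation distribution of the group-A rank sum
  is built by dynamic programming over doubled midranks (doubling makes
  midranks integral under ties), exact for n_A + n_B ≤ 25; two-sided
  p = 2·min(tails) capped at 1. Written in-package because the available
  exact implementations decline tied data.
- **Attributable mortality**: q²/m, assuming Hardy–Weinberg conception
  frequencies and full juvenile lethality of homozygotes — an upper-bound
  style estimate since partial survival to weaning reduces it. The
  "1 in N" form rounds 1/fraction to the nearest of {10, 20, 25, 50, 100}.
- **Concordance audit**: expected mapping non_carrier↔hom_ref,
  carrier_het↔het, carrier_hom↔hom_alt; the two scientifically distinct
  discordance classes (haplotype-negative variant carriers =
  recombination-shortened haplotypes; haplotype-positive non-carriers =
  array genotyping/phasing error) are reported separately. Unknown status
  or missing genotype is counted as missing, never as discordant.

Percentages round half-up to the nearest integer. No multiple-testing
adjustment is applied: the study design tests one pre-specified variant.

## Synthetic data

The generator reproduces the *structure* of the study data, at the
study's scale, from a single integer seed (fixed seed ⇒ byte-identical
files):

- **Cohort** (default n = 2952 conceived, q = 0.06): genotypes at
  Hardy–Weinberg conception frequencies; homozygous-alternate individuals
  survive to genotyping age with probability 3/72 (the observed/expected
  ratio of the screen) and dead ones never enter the cohort; heterozygotes
  carry an unrecognized recombination-shortened haplotype with probability
  9/408 (called non-carrier); homozygous-reference animals are mis-called
  carrier with probability 3/2543. The haplotype is abstracted to a status
  label — its 27 marker alleles are not simulated individually because
  only their downstream consequence (status/genotype discordance) feeds
  the analysis; the marker count is kept in the config for documentation.
- **At-risk matings** (default 17 ewes, 3 rams, all heterozygous):
  pregnancy ~ Bernoulli(0.65); litters are twins with probability 0.45
  (16 lambs from 11 pregnancies); lamb genotypes Mendelian; birthweight
  N(4.9, 1.0²) kg for males, N(3.9, 0.6²) kg for females; ADG over days
  0–15 is N(330, 40²) g/day minus 120 g/day for homozygous-alternate
  lambs, consistent with the one surviving affected lamb's 327.8 g/day
  being the top of its group; affected lambs die uniformly on days 15–25
  unless they escape (probability 0.2, the observed 1-in-5 survivor);
  unaffected lambs are censored at day 180.
- **Fixtures**: the sequenced-panel fixture embeds the 11 published
  candidate variants (positions, alleles, qualities verbatim) as
  heterozygous in 2 of 88 genomes, plus decoys each violating exactly one
  filter condition while satisfying the rest — region decoys sit more
  than 1 Mb beyond the extended window so any flank interpretation gives
  the same result. The gene-model fixture is described above.

What the generator does **not** emulate: read-level sequencing error and
coverage (genotypes are drawn, not called), linkage structure beyond the
one causal site, pedigree beyond parent–offspring, litter-size and
seasonal effects on growth, and age-structured death hazards (lethality is
a single Bernoulli survival-to-genotyping event). Passing tests therefore
demonstrate correctness of the *inference chain* under the stated
population model, not robustness to upstream calling artifacts.

## Numerical and design notes

- VCF QUAL values are rounded to 3 decimals on read (htslib stores QUAL in
  single precision; rounding removes the float32 representation artifact
  so written files round-trip exactly). Only GT is interpreted; `|` is
  treated as `/`; multi-allelic records are rejected with a logged reason
  (the screen considers biallelic polymorphisms) unless splitting is
  requested.
- Genomic coordinates are 1-based inclusive everywhere a user sees them;
  interval arithmetic inside functions is 0-based half-open.
- The pipeline is a deterministic single-pass in-memory run (< 1 s on the
  packaged fixtures); reports are written atomically (temp file + rename),
  and the report embeds seed, a canonical-JSON config hash and the package
  version. Incremental stage caching was considered and rejected: at this
  problem size it only adds staleness failure modes.
- Simulation-backed tests use n = 10⁵ cohorts for parameter recovery and
  10⁴ offspring for Mendelian-ratio checks — large enough that 3-standard-
  error bands are tight relative to the effects tested, while the whole
  suite stays in seconds.

## Limitations

- The consequence engine is single-transcript and SNV-only by design; no
  splice-site, NMD or regulatory prediction.
- The Fisher p-value underflows to 0.0 below ~5 × 10⁻³²⁴ (double
  precision); at that magnitude only the bound matters.
- The deficiency test treats E as known; uncertainty in the expected count
  (estimated upstream from haplotype frequencies) is not propagated.
- The attributable-mortality estimate inherits its assumptions (HWE at
  conception, full lethality, independence of other death causes) and
  should be read as an order-of-magnitude management figure.
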