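# Methods

## The matching model

A gene's catalogue is a set of named star alleles, each an exact set of
defining variants keyed positionally by `(chrom, pos, ref, alt)` (1-based VCF
convention, anchored indels, `chr` prefixes stripped). rsids ride along for
reporting but never participate in identity: they are unstable across dbSNP
builds, and the VCF is positional.

A phased diploid sample contributes two haplotype observations per gene: the
set of non-reference variants each haplotype carries at the gene's definition
positions, plus two quality flags (missing genotype at a definition position,
unphased heterozygote at a definition position). Matching is a total function
on observations:

1. any missing/unphased flag → `Amb` (reasons `MISSING_GT` / `UNPHASED`);
2. empty variant set → the reference allele `*1`;
3. exactly one allele whose defining set equals the observed set → that
   allele (`EXACT_MATCH`);
4. two or more alleles with that property → `Amb` (`MULTI_MATCH`);
5. some allele's defining set strictly contained in the observation → `Amb`
   (`SUPERSET`), reporting the variants unexplained by the largest contained
   set;
6. otherwise → `Amb` (`NO_MATCH`).

"Complete match" is thus implemented as exact set equality, with supersets
ambiguous. A containment-with-uniqueness rule plus a multi-match tiebreak
gives the same answer on every case we test; equality is the simpler uniform
rule and is the one implemented. The reference call is an *absence claim*, so
it additionally requires clean flags: an unverifiable absence (missing
genotype) is `Amb`, never `*1`.

Two asymmetries of real phased call sets are modelled explicitly rather than
hidden:

- **A definition site with no record in the file** is indistinguishable from
  homozygous reference at scan time. The scanner reports such sites in a
  `SiteCoverage` object so pipelines can warn, but calls proceed as if
  reference — this is exactly how an uncalled single-base deletion turns a
  true carrier into an apparent `*1` carrier, and the simulator can reproduce
  it (`drop_sites`).
- **Unphased heterozygotes** poison both haplotypes (either could carry the
  variant), while unphased *homozygotes* are phase-unambiguous and accepted.

Diplotypes preserve GT order (`hap1|hap2`) with `Amb` rendered `*Amb`; no
lower-allele-first normalisation is applied at call time. Unordered
normalisation (`*1/*61`, ascending allele number) is applied only where
pairs are pooled: diplotype frequency tables (on request), unique-diplotype
counts, novelty, and concordance comparison.

## External CYP2D6 calls

CYP2D6's structural complexity (CYP2D7 hybrids, copy-number alleles) is out
of scope for VCF matching; diplotypes for it are ingested from a
copy-number-aware caller's per-sample table. A row is retained iff
`Filter == "PASS"` and `Call_info == "unique_match"` — case-sensitive exact
string comparisons, since these are literal flag values — and its genotype
string becomes the diplotype verbatim (the caller is authoritative; no
re-validation against the definition table). All other rows map to
`*Amb|*Amb` with the rejected class recorded, keeping every input sample
visible in the output; a `drop_filtered` flag omits them instead, since it
is not knowable whether a downstream database should display or drop them.

## Summaries and novelty

Haplotype frequencies are counts over the `2N` haplotype slots; diplotype
frequencies over `N` samples. `*Amb` is a first-class label, excludable with
renormalisation. The per-gene summary counts distinct non-ambiguous alleles
and unordered diplotypes, and reports the allele count as a proportion of
the catalogue size. The catalogue denominator is whatever the loaded
definition set contains (reference included); published catalogue counts use
varying conventions, so the denominator can be overridden with an explicit
integer. The proportion is rounded half-up to 2 decimals (a convention
verifiable against published tables: 14/75 → 0.19, 22/42 → 0.52,
24/408 → 0.06).

Novelty (alleles/diplotypes observed here but not in a reference call set)
conservatively excludes ambiguous calls and any allele token carrying a copy
suffix (`*2x2`, with `×` normalised to `x`) or a `+`-joined tandem
arrangement — those reflect structural genotypes, not new sequence-defined
alleles — on both sides of the set difference.

## Concordance

Diplotype labels are parsed into pairs of allele tokens with copy counts;
`|` and `/` separators, whitespace, `×`, parenthesised tentative calls, and
composite `+` tokens are all accepted. Two diplotypes are concordant iff
their unordered token multisets agree, so a phased call always matches its
unordered counterpart, and copy counts must agree exactly. Tentative
reference calls count as concordant when they match. Because benchmark
publications rarely state whether ambiguous calls sit in the denominator,
both policies are computed and reported: `COUNT_DISCORDANT` (default) and
`EXCLUDE` (ambiguous pairs removed from the denominator). Percentages round
to the nearest integer. With an empty denominator the percent is undefined
and reported as `None`/"NA".

## Simulator

The simulator emulates the phased-cohort input, not sequencing: unrelated
haplotypes are drawn i.i.d. from per-gene star-allele frequencies; each trio
child receives one haplotype from each parent, without recombination
(pharmacogene definition regions are short relative to recombination
distances) and with hap1 paternal by construction. Genotypes follow
deterministically from the allele's defining set, one biallelic record per
defining variant, so the emitted VCF is byte-identical for a given config
and seed (numpy `default_rng`). Artifact knobs inject the failure modes the
matcher must handle: `drop_sites` (records absent from the file),
`missing_rate` (per site × sample missing genotypes), `unphase_rate` (per
site × sample unphased heterozygotes).

What the simulator does **not** model: genotyping error, phase switch errors
(beyond wholesale unphasing), linkage between genes, population structure,
recombination within a gene, structural variation and copy number. Passing
round-trip tests therefore demonstrate that the annotation machinery is
lossless on clean phased input with distinct defining sets — not that the
approach is robust to upstream calling or phasing error; the worked
discordance cases show precisely how such upstream defects propagate.

## QC filters

Per-site metrics and default retention thresholds: missing genotype rate
(fraction of samples with any uncalled allele) < 0.05; Hardy-Weinberg exact
test P-value > 1e-10; Mendelian error rate ≤ 0.05; minor allele count ≥ 2.
All four are overridable. The HWE test is the exact conditional test:
conditioning on the observed allele counts, it sums the probabilities of all
heterozygote counts whose conditional probability does not exceed the
observed one (two-sided, "no more likely" summation), computed in log space
with `scipy.special.gammaln` and normalised within the conditional
distribution for stability; a relative tolerance of 1e-12 guards the
"≤ observed" comparison against round-off. Monomorphic sites have a single
outcome and P = 1. The Mendelian check is per-site genotype consistency (a
child allele pair must be assemblable from one paternal and one maternal
allele), with the denominator restricted to fully genotyped trios; with no
evaluable trio the rate is 0 and the check passes. Multiallelic records are
evaluated with alternate alleles pooled. Filtering is idempotent by
construction (metrics depend only on the record's genotypes).

## Problem sizes and numerical choices

The test and acceptance workloads run at desk scale as the package's own
validation design: round-trip recovery uses 1,000 samples (100 trios) over
two genes; the matcher-oracle suite uses 10,000 random catalogue/haplotype
instances over a 10-variant pool; HWE is checked against exact
`fractions.Fraction` enumeration for all genotype configurations with ≤ 50
alleles. Frequencies are reported at 6 decimals, proportions at 2 (half-up);
frequency-sum invariants are asserted to 1e-9.

## Known limitations

- Suballeles (`*2.001`) and structural allele definitions are not modelled;
  definition tables must be pre-collapsed to core alleles.
- Input VCFs are assumed normalised (left-aligned, anchored); no
  re-normalisation is performed.
- Haplotype-level concordance and phenotype translation (metaboliser status,
  activity scores) are out of scope.
- The definition TSV is this package's own dialect; converting a live
  catalogue export into it is an adapter step outside core scope.
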