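# starallele

Star-allele diplotype annotation of phased pharmacogene cohorts.

Pharmacogene haplotypes are catalogued as **star alleles**: a named allele
such as CYP2C19\*2 is defined by an exact set of variants, and `*1` denotes
the reference haplotype. Given a phased multi-sample VCF and a PharmVar-style
definition table, `starallele` assigns each sample a **diplotype** — the
ordered pair of star alleles on its two haplotypes — by *strict matching*:

> haplotype *h* is annotated allele *A* iff the set of non-reference variants
> observed on *h* at the gene's definition positions equals *A*'s defining
> set exactly; if no allele (or more than one) matches completely, or a
> genotype is missing or unphased at a definition position, *h* is annotated
> ambiguous (`*Amb`).

Strictness is the point: a haplotype carrying the two variants that define
CYP2C19\*35 *plus* an extra definition-position variant is not called \*35 —
it is `*Amb`, because it is not a complete match to any single catalogue
entry. Phase order is preserved in output (`*61|*1`, not `*1|*61`).

Around the matcher the package provides what a cohort-annotation study needs:

- **`starallele.definitions`** — parse/validate/serialise star-allele
  definition TSVs (`gene allele chrom pos ref alt rsid`).
- **`starallele.vcfio`** — project phased VCF samples (cyvcf2) onto a gene's
  definition positions, with multiallelic decomposition and explicit
  site-coverage reporting (a definition site with no VCF record behaves as
  homozygous reference — exactly how an uncalled deletion silently masks a
  true carrier).
- **`starallele.cyp2d6`** — ingest an external copy-number-aware CYP2D6
  caller's table, retaining only `Filter == PASS` and
  `Call_info == unique_match` rows as named diplotypes.
- **`starallele.summaries`** — haplotype/diplotype frequency tables, per-gene
  unique-allele summaries with catalogue-coverage proportions, novelty
  against a reference call set.
- **`starallele.concordance`** — diplotype-label parsing (`*2x2/*10`,
  `(*1/*4)`, `*36/*36 + *10`) and call-set concordance with both ambiguity
  policies.
- **`starallele.simulate`** — seeded phased-cohort simulator (trios
  supported) with truth tables and artifact injection, plus the standard
  cohort QC filters: missing rate < 5%, Hardy-Weinberg exact-test
  P > 1e-10, Mendelian error rate ≤ 5%, minor allele count ≥ 2.

## Worked example

Simulate a 100-sample CYP2C19 cohort (10 trios), annotate it, and summarise:

```sh
starallele simulate --defs defs.tsv --freqs freqs.tsv \
    --n 100 --trios 10 --seed 17 -o sim
starallele annotate --vcf sim/cohort.vcf --defs defs.tsv \
    --gene CYP2C19 -o calls
starallele summarize --calls calls/calls.csv --defs defs.tsv \
    --gene CYP2C19 --normalize-unordered -o summ
```

`calls/calls.csv` begins:

```
sample,gene,hap1,hap2,diplotype,reason1,reason2,source
S0001,CYP2C19,*2,*1,*2|*1,EXACT_MATCH,REFERENCE,ENGINE
S0002,CYP2C19,*2,*1,*2|*1,EXACT_MATCH,REFERENCE,ENGINE
S0003,CYP2C19,*1,*1,*1|*1,REFERENCE,REFERENCE,ENGINE
```

and the summaries read:

```
gene,label,count,frequency
CYP2C19,*1,127,0.635000
CYP2C19,*2,50,0.250000
CYP2C19,*35,23,0.115000

gene,n_diplotypes,n_alleles,n_pharmvar,proportion
CYP2C19,6,3,4,0.75
```

The 200 haplotype slots split 127/50/23 across `*1`/`*2`/`*35` — close to
the simulated frequencies 0.6/0.25/0.15 — and the cohort shows 3 of the 4
catalogued alleles (proportion 0.75) across 6 distinct unordered diplotypes.
Because this cohort is artifact-free and the fixture alleles have pairwise
distinct defining sets, every call equals the simulator's truth.

Comparing a call set against a reference (e.g. a consensus benchmark table)
prints both ambiguity policies:

```
$ starallele concordance --a a.csv --b b.csv
overlapping (sample, gene) pairs: 3
amb-excluded pairs:               0
concordant:                       1
concordance (COUNT_DISCORDANT): 33%
  discordant NA19122: *2|*Amb vs *2/*35
  discordant HG01190: *61|*1 vs *2/*61
...
concordance (EXCLUDE): 50%
```

`*1|*2` vs `*2/*1` counts concordant (phase is ignored when comparing with
an unordered reference), while `*2|*Amb` vs `*2/*35` is discordant under the
default policy and excluded under `EXCLUDE`.

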