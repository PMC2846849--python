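# mitoburden

Mitochondrial DNA case-control variant analysis: variant identification
against a circular reference mitogenome, codon-level annotation under the
vertebrate mitochondrial genetic code (translation table 2), synonymous /
non-synonymous and OXPHOS-complex classification, novelty flagging,
threshold-based pathogenicity and ROS/LHON screening, and per-gene
case-control burden statistics (exact Fisher tests by hypergeometric
enumeration, uncorrected Pearson χ², cohort relative risks with Katz
95% confidence intervals).

The package ships:

- the 37-gene NC_012920 (rCRS) coding-region coordinate layout as package
  data (the reference *sequence* is an optional user-supplied FASTA —
  coordinate arithmetic such as codon indexing needs no sequence);
- verbatim TSV transcriptions of a published primary-congenital-glaucoma
  case/control variant study (132 case variants, 58 control variants, a
  35-patient variant matrix, and 13 per-gene carrier-count rows), used as
  the reproduction surface — including the originals' typography quirks,
  which the loaders normalize but never silently repair;
- a synthetic-data module generating circular genomes with valid reading
  frames and seeded case/control cohorts with known planted truth.

## Command line

```
mitoburden simulate  --seed 4 --n-cases 12 --n-controls 12 --out-dir sim/
mitoburden call      --reference sim/reference.fasta --samples sim/samples.fasta --out calls.tsv
mitoburden annotate  --variants calls.tsv --reference sim/reference.fasta \
                     --features sim/features.tsv --out annotated.tsv
mitoburden burden    --counts counts.tsv --n-cases 35 --n-controls 40 --out burden.tsv
mitoburden screen    --variants calls.tsv --scores scores.tsv --out screen.tsv
mitoburden reproduce --out-dir reports/
```

`reproduce` regenerates every tally and statistic from the packaged study
tables (annotated table with reconciliation column, tally summary with
percentages, burden table, risk screen) and exits non-zero if any expected
value fails to reproduce. Exit codes: 0 success, 1 usage, 2 data
validation, 3 reproduction failure.

Omitting `--reference` runs annotation in coordinate-only mode (gene and
codon index, no codon/amino-acid recomputation). Two classification
pathways exist and are never mixed: sequence-based (codon recomputation)
and record-based (comparison of a table row's two printed amino-acid
names); the packaged-table tallies use the record-based pathway because
several printed rows carry codon columns inconsistent with their
amino-acid columns — the reconciliation report lists them.

## Layout

| module | contents |
| --- | --- |
| `mitoburden.genome` | circular genome, gene features, mito genetic code, codon arithmetic |
| `mitoburden.variants` | variant model, notation parsing/formatting, TSV/VCF I/O |
| `mitoburden.calling` | Needleman–Wunsch alignment and variant calling |
| `mitoburden.annotate` | gene/codon annotation, tallies, reconciliation |
| `mitoburden.stats` | 2×2 exact/asymptotic tests, relative risks, burden tables |
| `mitoburden.risk` | score-threshold pathogenicity calls, ROS/LHON screens |
| `mitoburden.simulate` | synthetic genomes and cohorts with truth tables |
| `mitoburden.fixtures` | packaged study-table loaders |
| `mitoburden.cli` | `mitoburden` entry point |
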