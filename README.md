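# mgecds

Retrieve protein-coding sequences of mobile genetic elements (MGEs) —
retrotransposons and DNA transposons — from a genome assembly, starting
from the standard output files of de-novo repeat discovery, similarity
masking and conserved-domain search. `mgecds` is aimed at researchers who
want ready-to-analyse element copies (coding sequences, flanks, genomic
coordinates, length statistics) without hand-rolling the glue between
those tools. The heavy external programs are never executed: their output
*files* are the inputs, so every step is reproducible and restartable.

## What it computes

Given an assembly, a classified repeat-consensus library
(`name#Type/Subtype` headers), repeat-match coordinates (masker `.out`
dialect or BED) and conserved-domain hits (12-column tabular), the
pipeline runs four stages:

1. **consensus** — select consensuses whose `Type/Subtype` classification
   contains the user's keyword (case-insensitive substring, so `LINE`,
   `LINE/L1` and `Penelope` all work); unclassified records are set aside
   and can be promoted later from a saved CENSOR HTML report.
2. **coords** — merge matches whose gap ≤ *d* (the `--merge` parameter)
   into single regions per element copy, transitively and strand-blind;
   each region inherits the strand of its longest constituent match and is
   excised from the assembly, reverse-complemented when on the minus
   strand. Maskers fragment diverged element internals, so *d* should
   approach the expected ORF length (≈2000 bp for a typical
   *Penelope*-like element): larger *d* gives provably fewer, longer
   regions.
3. **orfs** — find open reading frames (default: ≥1000 bp including the
   terminal stop, first ATG after the previous in-frame stop, plus strand,
   standard genetic code — all adjustable, including any-sense starts and
   six-frame scans) and keep only ORFs that fully contain a hit of *every*
   required conserved-domain type (e.g. reverse transcriptase **and**
   endonuclease) at e-value ≤ 0.01.
4. **flanks** — extend validated coding sequences with genomic flanks in
   element orientation, clipped at contig boundaries.

Every stage writes the conventional file inventory
(`MGE_consensi.fa`, `genome.out.bed`, `MGE_excised_matches2000.fa`,
`MGE_cds1000_with_domains_e01.fa`,
`MGE_cds1000_with_domains_e01_extended_L100R100.fa`, …), a plain-text
`.stats` file of length statistics per sequence set, and a JSON manifest
with record counts so filter attrition is auditable. `--from-stage` /
`--to-stage` re-enter the pipeline from persisted intermediates with
byte-identical results.

## Worked example

The package ships a generator of ground-truthed toy genomes with planted
retroelement copies (intact, domain-missing, stop-disrupted, and
annotation-fragmented), which doubles as a demonstration input:

```bash
mgecds make-fixtures --outdir fx --seed 3
mgecds run --assembly fx/genome.fa --lib fx/library.fa \
    --coords fx/genome.out --hits fx/domain_hits.tsv --cdd fx/domains.csv \
    --mge-type Penelope --merge 2000 --outdir run
```

prints the manifest:

```
consensi        2   run/genome/MGE_consensi.fa
unknown_consensi 2  run/genome/Unknown_consensi.fa.classified
matches_bed     60  run/genome/genome.out.bed
excised         50  run/genome/MGE_excised_matches2000.fa
matches_with_hits 50 run/genome/MGE_matches_with_hits_e01.fa
cds             40  run/genome/MGE_cds1000.fa
validated_cds   30  run/genome/MGE_cds1000_with_domains_e01.fa
validated_tsv   30  run/genome/MGE_cds1000_with_domains_e01.tsv
flanked         30  run/genome/MGE_cds1000_with_domains_e01_extended_L0R0.fa
```

Reading the attrition: 60 match rows merge into 50 regions at `--merge
2000` (each fragmented element's two rows re-join); 40 of the excised
regions contain an ORF ≥ 1000 bp (the 10 stop-disrupted copies do not);
30 ORFs carry both required domains below e-value 0.01 (the 10
domain-missing copies fail) — exactly the 20 intact + 10 fragmented
elements that were planted. Re-running with `--merge 500` leaves the
fragmented elements split and recovers only the 20 intact copies.

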