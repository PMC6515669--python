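# Methods

## Problem and model

Eukaryotic genomes carry large numbers of mobile genetic elements (MGEs).
De-novo repeat discovery yields family consensuses classified as
`Type/Subtype`; a homology masker then reports *matches* — genomic
intervals similar to those consensuses; a PSSM search reports conserved
protein-domain alignments on excised matches. `mgecds` turns these three
artefacts into validated element coding sequences. Its model of an
element copy is purely positional: a copy is a merged cluster of matches;
its coding capacity is an ORF on the (re-oriented) cluster sequence; its
validity is full containment of one qualifying domain alignment per
required domain type inside that ORF.

## Coordinates

All internal intervals are 0-based half-open on the forward strand of
their reference (contig or excised match). The masker `.out` dialect and
BLAST tabular columns are 1-based inclusive; parsers convert by exactly
(begin−1, end) and writers invert it. Masker strand `C` maps to `-`;
tabular rows with qstart > qend are swapped and flagged as reverse-frame
hits. A single convention internally removes the usual off-by-one bug
class and matches BED.

## Merging (the `merge_dist` parameter, bp, default 2000)

Per contig, matches sorted by start are coalesced transitively whenever
the gap to the growing cluster, measured between half-open ends
(`next.start − cluster_end`), is ≤ `merge_dist`; `merge_dist = 0`
therefore joins overlapping and abutting matches and equals plain
interval union. Merging ignores strand, because maskers frequently
annotate fragments of one element with alternating strands; the region
inherits the strand of its longest constituent match, ties resolving to
`+`. Three properties hold universally and are asserted as such: region
count is non-increasing, maximum region length non-decreasing, and summed
coverage non-decreasing in `merge_dist`. Median length is *not* monotone
for arbitrary inputs and is deliberately not asserted. The default of
2000 bp reflects the practical optimum for retroelement retrieval — about
the expected ORF length, since larger annotation gaps inside one element
are unlikely.

## ORF definition

Within each reading frame (three plus-strand frames by default; six under
`strand_policy="both"`), one ORF is reported per terminating stop codon:
from the first ATG after the previous in-frame stop (`atg_only`, the
maximal ATG-initiated variant) or from the codon after the previous stop
(`any_sense`) to the stop, stop included in the span and counted by the
`min_orf_len` filter (default 1000 bp), excluded from the translation. A
frame that reaches the sequence end without a stop yields an *open-ended*
ORF flagged as such — these are truncated copies at match boundaries;
they are reported rather than dropped because they are filterable
downstream. Translation uses the selected NCBI table (default 1);
codons containing ambiguity characters translate to `X` and never count
as stops. Minus-strand ORFs keep their coordinates on the excised match's
plus strand, with the reading orientation carried separately.

## Domain validation

An ORF becomes a validated CDS iff for every required domain type (from
the two-column domain/PSSM table) some hit has a PSSM of that type,
e-value ≤ `evalue_max` (default 0.01, the conventional PSSM-search
cut-off), an interval fully inside the ORF span, and frame orientation
consistent with the ORF (reverse-frame hits support minus-strand ORFs
only). Full containment is the strict reading of "domain within the ORF";
partial overlaps do not qualify. The lowest-e-value hit per type is
recorded. The validated set is monotone in `evalue_max` by construction.
Separately, `MGE_matches_with_hits_eX.fa` keeps every excised match with
at least one passing hit of any type — a coarser, domain-agnostic set.

## Genome projection and flanks

A position *p* on an excised region maps to `region.start + p` for `+`
regions and `region.end − p` (mirrored) for `−` regions; the genome
strand of an ORF is the XOR of region strand and ORF strand. Re-excising
the projected interval and re-orienting reproduces the ORF sequence
byte-exactly (a tested invariant). Flanks are taken in **element
orientation**: the left flank is upstream of the ORF 5′ end on the
element strand, i.e. genomic downstream for minus-strand elements. This
choice (the alternative would be genomic left/right) is made because
flanks feed strand-relative analyses — target-site duplications,
promoters. Flanks clip silently at contig boundaries; requested and
achieved extents are both recorded.

## Descriptive statistics

Each output sequence set gets n, min, max, mean, median (mean of the
middle pair for even n), sample standard deviation (n−1 denominator; a
single observation reports sd = 0 with an explanatory note so the file
schema stays fixed), and an integer-binned histogram with
Freedman–Diaconis-style width, always written as text; PNG rendering is
flag-gated so nothing depends on image output.

## Synthetic fixture generator

The generator plants element copies into uniform random background — which
is stop-codon rich, making spurious long ORFs vanishingly improbable —
and emits the matching annotation files, all deterministic from one seed.
Planted ORFs are 1800 bp (2700 bp for fragmented copies), comfortably
above the 1000 bp default; an in-frame stop is forced immediately
upstream of each planted ATG so the recovered ORF equals the planted one
exactly. Categories: *intact* (full ORF, RT-like and EN-like segments
inside, both emitted as hits at e = 1e-30); *missing_domain* (EN emitted
only as a decoy hit at e = 0.5, for threshold tests); *disrupted* (a
premature stop splits the ORF into ~900 bp halves); *fragmented* (the
element is contiguous in the genome but its annotation is split into two
match rows around a 1500 bp unannotated internal gap, the way maskers
fragment diverged internals). Domain-hit fixtures are keyed by the
excised-region identifiers produced at a stated merge distance, exactly
as a PSSM search over the excised FASTA would be; a hit row is emitted
only where the domain interval lies inside a single region.

What the fixtures do *not* emulate: sequence divergence between copies,
substitution/indel evolution, nested insertions, realistic repeat
landscapes, or PSSM scoring itself (hit coordinates are planted, not
computed). Passing the planted-recovery tests therefore demonstrates the
correctness of the coordinate logic, merging, ORF finding, validation and
staging — not the sensitivity of any upstream similarity search.

## Staging and determinism

Stages form the fixed order consensus → coords → orfs → flanks;
`from_stage`/`to_stage` select a contiguous slice. A stage consumes
either the in-memory product of the previous stage or the persisted file
in the run directory (excised FASTA whose headers are parseable region
ids; a TSV sidecar of validated CDS records), which makes restarts
byte-identical to single runs — a tested invariant. The analysis stages
are fully deterministic; the only randomness in the package is the
fixture generator's seed. Problem sizes used by the default test suite
and the acceptance script — a 5 × 120 kb genome with 50 planted elements,
a few hundred random sequences and match sets for the oracle checks —
were chosen as the smallest sets that exercise every category and
parameter regime.

## Known limitations

- Distance merging cannot separate two genuinely distinct copies closer
  than `merge_dist`, nor re-join fragments farther apart than it;
  masker-ID-based defragmentation is out of scope.
- Keyword selection is substring-based; a keyword like `L1` will also
  match classifications containing it as a fragment (e.g. `L1-Tx1`).
- The CENSOR HTML layout is not standardised; the parser targets the
  first table with ≥2 columns and a Class/Repeat-labelled column and
  errors rather than guessing otherwise.
- Open-ended ORF reporting and strict hit containment are documented
  choices; both can bias counts relative to tools that decide otherwise.
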