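# Methods

## Scope and assumptions

`mtxannot` implements the decision layer of a tiered metatranscriptomic
annotation workflow; it does not run aligners, rRNA predictors, short-read
classifiers or EC predictors. Each external tool is represented by its
standard output format, and the package's contract is the set of rules applied
to those files: read bookkeeping, hit acceptance, tie-breaking, ensemble
merging, consensus and report construction. Two modelling assumptions carry
through everything:

1. **Pairs are one datum.** The forward and reverse mates of a pair derive
   from the same transcript, share a read id, and are always assigned to one
   gene (the higher-scoring mate decides, ties keep the forward mate's gene).
   Polycistronic transcripts violate this; in the data this workflow targets
   the discordant-pair fraction is small, and the single-gene assignment is
   accepted as the simpler accounting.
2. **Each read counts once.** The gene-to-read map rejects a second
   assignment of any read id, multi-mapped reads are never fractionally
   split (the first, highest-scoring acceptable match wins), and the read
   ledger guarantees that terminal category counts sum to the raw input.

## Parameters

| Parameter | Default | Units / range | Role |
|---|---|---|---|
| `cigar_coverage_min` | 0.90 | fraction of read | SAM-tier acceptance: summed M/=/X lengths ÷ read length (soft-clips count against coverage) |
| `identity_min` | 85 | % | m8-tier acceptance, clause 1 |
| `aln_len_fraction_min` | 65 | % of query length | m8-tier acceptance, clause 2; query length is floor(nt/3) residues for translated searches |
| `bitscore_min` | 60 | bits | m8-tier acceptance, clause 3 |
| `ec_evalue_low` / `ec_evalue_high` | 1e−5 / 1e−10 | e-value | similarity cutoff for the PRIAM∩DIAMOND component of the low/high EC report |
| `priam_prob_min` | 0.5 | probability | extra PRIAM floor applied only in the high-stringency report |
| consensus weights | 0.6 / 0.2 / 0.2 | — | gene-lookup / each classifier; must sum to 1 |
| `taxa_cutoff` | 0.01 | fraction of reads | abundance floor for an emitted taxon group in the rollup |
| `heatmap_top_n` | 20 | taxa | columns of the superpathway matrix before the residual `Other` |
| `chunk_size` | 50,000 | reads | parallel-style chunking of the annotation input; results are chunk-invariant |
| `filter_stringency` | `high` | high/low | pair behaviour of the host/vector/rRNA filters |
| `low_quality_mean_phred` | 20 | phred | mean-quality floor when the package itself flags low-quality reads |
| `bwa_contig_params` | B=40, O=60, E=10, L=50 | — | informational: the aligner settings assumed for read-vs-contig-gene SAM inputs; the package only parses the result |

All acceptance comparisons are closed at the threshold ("falls below …
rejected": a value exactly at the cutoff passes).

## Numerical and tie-break choices

- **Best hit**: earliest maximal score in report order — a later hit must
  *strictly* exceed the running best to replace it.
- **Consensus majority**: strict `> W/2` on float weight sums, where W counts
  only non-abstaining (taxid ≠ 0) sources; unclassified sources abstain rather
  than diluting present votes. Equal-depth majority ties resolve to the LCA of
  the tied nodes. With the default 0.6/0.2/0.2 weights no exact-boundary float
  case arises (the only near-boundary sums, 0.2 vs 0.2 and 0.4 vs 0.2, compare
  identical binary representations).
- **EC co-occurrence order**: reduce to the two highest-scoring ECs first
  (score ties break lexicographically on the EC string), then validate the
  surviving pair against the curated pair set; an unsupported pair keeps its
  higher-scoring member only. Deleting both would discard profile-tool calls
  that the ensemble rule says are always kept.
- **High ⊆ low EC reports**: the high report is computed as the restriction of
  the co-occurrence-filtered low report to ECs that also pass the
  high-stringency merge. Filtering the stringencies independently can select,
  for a gene with ≥ 3 calls, a high-report EC the low filter dropped; the
  restriction makes the subset invariant hold by construction.
- **Taxon rollup**: reads enter at the named rank of their consensus node
  (`no_rank` nodes roll to the nearest named ancestor). At each rank from
  species to phylum, groups at or above the cutoff are emitted; sub-cutoff
  groups are pooled with sub-cutoff siblings into their shared next-rank
  ancestor. Mass still sub-cutoff at phylum, reads with taxid 0, and
  assignments above phylum go to `Other`, so the rollup conserves counts and
  every non-`Other` group clears the cutoff.
- **Degenerate inputs**: empty FASTQ/report files produce empty (but valid)
  tables; percentages with a zero denominator are defined as 0; `lca` of an
  empty set, RPKM with zero length/total, and N50 of an empty list are
  errors, not defaults.
- **Quality histogram**: per-read mean phred, floored into integer bins 0–41
  (the bin width is a package choice; nothing upstream prescribes one).

## The synthetic generator

`mtxannot.simulate` emulates a small community metatranscriptome with full
ground truth. Defaults, chosen once as a realistic post-depletion gut-style
sample: 5 species on distinct genera of a balanced 7-rank taxonomy, 20 genes
per species of 600–1500 bp, 100 bp paired reads, contaminant fractions 5 %
host / 2 % vector / 30 % rRNA-tRNA / 3 % low-quality, substitution rate 0.
Classifier errors use a confusable-sibling model (a wrong call is a congeneric
species), which makes the consensus rule's behaviour observable. Alignment
reports are constructed so the acceptance rules recover the planted truth
exactly at zero noise: correct hits sit safely above every threshold, missed
reads receive only sub-threshold hits, and spurious hits are either
sub-threshold or strictly lower-scored than the correct hit. All outputs are
byte-deterministic under a fixed seed (the read stream and the gene-sequence
stream are keyed separately so they can never collide).

What the generator does **not** model — and hence what passing tests do not
show about real data: indels and quality-by-cycle error profiles, chimeric or
assembled reads (the end-to-end run treats all putative mRNA as unassembled;
contig-gene mapping and N50/L50 are exercised on dedicated contig fixtures),
strain-level reference redundancy, classifier biases beyond the sibling
model, and database incompleteness.

## Pipeline orchestration

Stages run in a fixed order (ledger → gene annotation → enzyme annotation →
consensus → reports), each writing its outputs plus a JSON checkpoint. A rerun
skips stages whose checkpoint parses and whose outputs exist; a corrupt
checkpoint or missing output reruns that stage from its beginning (stage-level
resume only — within-stage sharded resume is deliberately out of scope).
Interim files honour the `keep`/`compress`/`delete` policy. One sample per
invocation. Reports are written in sorted order, so identical inputs give
byte-identical outputs regardless of `chunk_size`.

The host/vector/rRNA filter stage consumes per-mate read-id hit lists
(TSV: read id, mate) rather than raw aligner output, since producing those
alignments is outside the package; the synthetic generator writes the lists
from truth, and users of real aligners can produce them with a one-line
extraction from their filter tool's report.

## Problem sizes

The test suite and the acceptance script use 5 species × 10,000 read pairs
for recovery and noise-response checks, 1,000 randomized instances per
decision rule for oracle-equivalence checks, and 100 randomized 30-pair
mini-runs for ledger conservation; these sizes give 4σ binomial resolution of
about ±1 % on the measured rates. Larger simulations scale linearly and
change nothing structural.

## Known limitations

- The weighted-lineage majority rule is this package's own formalisation of
  "weighted consensus over a simplified taxonomy tree"; it is not a
  re-implementation of any published consensus tool's scoring internals.
- Duplicate collapsing is exact full-length identity (a 100 %-identity
  emulation); near-duplicate clustering is out of scope.
- Merged-pair reads are accepted as input (`mate=merged` singletons) but the
  generator does not produce them, so merge-specific paths are unit-tested
  only.
- Vector-vs-host precedence when both filters hit the same pair is not
  externally specified; filters apply in the order host, vector, rRNA, so the
  first-listed category wins.
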