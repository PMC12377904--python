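# Methods

## Problem and model

Given one genome assembly per member of a defined microbial community and
shotgun paired-end reads from a sample, estimate each strain's relative
abundance. The obstacle is intra-species redundancy: strains may share most
of their genome, so reads from shared regions cannot be assigned. Discarding
them (the only assignment-free option) biases any length-normalized metric
against redundant strains.

The estimator used here normalizes fragment counts by *uniquely mappable
sites* rather than genome length. For a reference slice (subcontig) with
`U` community-unique canonical k-mers receiving `F` perfectly-and-
unambiguously mapped fragments out of `T` total mapped fragments in the
sample:

```
FUKM = F / ((U / 1e3) * (T / 1e6))
```

Under uniform sequencing, both `F` and `U` scale with the fraction of the
subcontig that is unique to it, so their ratio tracks coverage — and hence
cell abundance — regardless of how much of the strain is shared.

## Reference database (preprocess)

* **Subcontig splitting.** Contigs are cut into equal cores of at most the
  *smallest N50 among all input assemblies* (override available): pieces =
  `ceil(L / max_size)`, core = `ceil(L / pieces)`, last core absorbs the
  remainder. This equalizes effective build quality across strains and
  yields several independent abundance estimates per strain, which the
  percentile summary uses to shrug off multi-copy outliers (plasmids,
  transposons). Each subcontig's sequence carries 500 b flanks (truncated at
  contig ends) so fragments straddling a cut still map; fragments falling
  entirely inside a flank match two subcontigs and are tossed as ambiguous —
  the same k-mers are duplicated and thus non-unique, so numerator and
  denominator stay consistent.
* **Minimum contig size.** Contigs under 10 kb are stored flagged
  `excluded`: they never produce a FUKM estimate, but their k-mers still
  mark community k-mers as non-unique and reads may still map to them (and
  count toward `T`). Small contigs are disproportionately multi-copy
  elements; treating their k-mers as unique would misdirect reads.
* **k-mer size.** `k = 2 * read_length + 1` (301 for 150 b paired reads;
  forced odd so no k-mer equals its own reverse complement). A k-mer the
  size of the sequenced fragment span makes "unique k-mer" nearly synonymous
  with "site where a pair can map uniquely"; smaller k under-normalizes
  highly similar strains.
* **Uniqueness counting.** Every A/C/G/T-only window contributes the 64-bit
  hash (blake2b, 8-byte digest — stable across platforms and runs) of its
  canonical form (lexicographic min of window and reverse complement).
  A subcontig's `unique_kmers` is the number of its windows whose hash has
  total multiplicity exactly 1 across *all* subcontigs of the community,
  duplicates within a subcontig included. Windows containing other
  characters are skipped entirely. Hash collisions in a 64-bit space are
  negligible at the tens-of-millions-of-k-mers scale this targets.

## Mapping contract (quantify)

A fragment is counted iff both mates match a subcontig exactly, end to end,
on opposite strands in convergent orientation with non-negative inner gap,
and all such placements lie on a single subcontig. Multiple placements on
one subcontig count once for it; placements on two or more subcontigs (e.g.
shared regions of near-clonal strains, or a fragment inside an overlap
flank) discard the fragment; mismatch-tolerant alignment is deliberately
absent — an errored read is simply lost, which the normalization absorbs.
Before mapping, 3' poly-G runs of >= 10 bases are trimmed and pairs with any
remaining N or a mate shorter than 50 b are dropped.

The built-in mapper indexes every 31-base window of every subcontig
(2-bit-packed, sorted array); a mate's leading 31-mer proposes candidate
placements verified by full-string comparison. Alignments produced
externally under the same contract can be imported from SAM/BAM instead:
templates with a primary, properly-paired, NM=0, full-length-match alignment
are counted.

Quality scores are ignored throughout: a perfect match is a sequence-level
criterion.

## Abundance summaries

Per strain, over its non-excluded subcontigs with `unique_kmers > 0`
(FUKM is undefined at zero unique k-mers; such subcontigs are dropped from
the lists, though their fragments stay in `T`):

* **mFUKM** — median subcontig FUKM (even counts: mean of the central pair).
* **wpFUKM** (reported abundance) — sort subcontigs by FUKM ascending (ties
  broken by subcontig ID for determinism); return the FUKM of the first
  subcontig at which the running unique-k-mer total reaches `p`% of the
  strain's total, default `p = 60`. Weighting by unique k-mers lets the
  regions that actually carry mapping information dominate. Higher `p`
  trades false negatives for false positives in presence calling;
  `present` is defined as `wpFUKM > 0`.
* **Relative abundance** — each strain's share of summed wpFUKM (all zeros
  when nothing maps).
* **FPKM baseline** — the same perfect-unique fragment counts summed per
  strain, divided by genome kilobases and millions of mapped fragments;
  reported alongside as the un-normalized comparator.

## Simulator

The generator emulates the benchmark conditions the method targets:

* **Genomes.** I.i.d. random ancestor at a chosen GC (default 0.5);
  descendants by i.i.d. substitution at a given per-base divergence.
  Canned builders: `divergent_community` (n strains at 3% from a common
  ancestor, ~6% pairwise) and `clonal_pairs_community` (8 lineages at 3%
  from the ancestor, the first 4 paired with a 0.1%-divergent twin —
  12 strains mixing easy and near-clonal targets). At k = 301, 0.1%
  divergence leaves ~26% of a twin's k-mers unique — a deliberately harsh
  but solvable case.
* **Assemblies.** Random cut points, retried until the piece N50 is within
  a factor of two of the target; concatenation always reconstructs the
  genome.
* **Compositions.** uniform; log-normal (sigma 1); zero-inflated log-normal
  (absence probability 0.25); exponential; log-step (2 tiers, 30-fold step);
  missing (uniform with a chosen/random subset absent). All normalized to
  sum to 1.
* **Reads.** Abundances are relative cell abundances: fragment counts are
  multinomial with weights `abundance x genome_length`, so expected coverage
  is proportional to abundance. Fragment starts are uniform along contigs
  (contigs chosen proportional to length); insert length is normal
  (mean 400, sd 50 — a generic short-insert library) resampled into
  `[2 x read_length, contig_length]`; mates read convergently from opposite
  strands; errors are i.i.d. substitutions at a configurable rate (default
  0). Not modeled: indels, quality-dependent error profiles, GC bias,
  duplicates, reads spanning contig joins. Since the mapper rejects any
  imperfect read outright, a substitution rate is the only error dimension
  that affects this method; conclusions about error-model-specific behavior
  (e.g. platform artifacts) cannot be drawn from these simulations.
* **Determinism.** All randomness derives from one integer seed through
  numpy `SeedSequence` spawn keys; FASTQ/FASTA/database outputs are written
  with fixed gzip metadata so repeated runs are byte-identical.

`strain_unique_kmer_fractions` reports each strain's community-unique k-mer
fraction, the screening statistic used when assembling realistic communities
(near-clonal duplicates score a few percent; divergent strains near 1).

## Benchmark statistics

Truth and estimate are normalized to compositions before comparison.
Jensen-Shannon divergence uses log base 2 (range [0, 1]) with the
`0 * log 0 = 0` convention, so strains absent from both vectors are inert —
absent-strain handling by convention rather than row-dropping. CV uses the
sample (n-1) standard deviation, in percent. The log-space Pearson
correlation takes log10 of both vectors and substitutes zeros with the
minimum finite log10 across both minus 1. Presence F1 treats "present"
(abundance > 0) as the positive class. `benchmark_run` drives
simulate -> map -> summarize for a list of designs and scores wpFUKM and
FPKM side by side.

## Default parameters

| parameter | default | unit | rationale |
| --- | --- | --- | --- |
| max subcontig size | smallest genome N50 | b | equalize build quality across strains |
| min contig size | 10 000 | b | below this, likely multi-copy; exclude from FUKM |
| overlap | 500 | b | longer than a typical insert's read span |
| read length | 150 | b | short-read default; k = 2x150+1 = 301 |
| wpFUKM percentile | 60 | % | balances false positives (higher p) vs false negatives (lower p) |
| filter: min mate length | 50 | b | drop uninformative stubs after trimming |
| filter: max N per mate | 0 | count | an N can never match exactly |
| poly-G run threshold | 10 | b | two-color chemistry artifact length |
| insert size | 400 +/- 50 | b | generic paired-end library |

## Problem sizes used in validation

The shipped tests and the acceptance script run entirely on simulated
communities sized for a laptop-class machine: 100 kb genomes for the
12-strain near-clonal benchmark (~40x coverage, 160 k read pairs), 50 kb
genomes for the 10-strain composition-recovery designs (depth set so the
least-abundant present strain sees ~12x coverage, capped at 400 k pairs),
and kilobase-scale communities for the oracle-equivalence suites (uniqueness
counts vs a plain-dictionary tally; mapper verdicts vs an all-offsets scan).
These sizes give per-strain sampling noise of a couple of percent, small
relative to every asserted margin.

## Known limitations

* Exact matching means sequencing errors cost fragments; at high error
  rates or very low depth, low-abundance strains lose presence calls first
  (lower `p` mitigates, at the cost of false negatives elsewhere).
* A strain whose genome is entirely shared (zero unique k-mers everywhere)
  is unquantifiable by construction and is reported with a
  `no_usable_subcontigs` flag.
* Fragments with mates that overlap each other (insert < 2 reads) are
  rejected by the non-negative-inner-gap rule.
* Abundances are relative; absolute quantification (copies per gram)
  requires external calibration.
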