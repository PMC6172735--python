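# Methods

## Classification model

A read sequenced from a xenograft belongs to the graft or the host genome;
aligned to both references, its species of origin is, with high
probability, the reference it matches better. The discriminating statistic
is the per-read edit distance

    ED = soft-clipped bases + inserted bases + NM,

with the clip and insertion counts taken from the CIGAR string and NM from
the aligner's mismatch tag. For a read pair the two mate distances are
averaged; a mate that did not map (or was never emitted by the aligner,
which is indistinguishable at this layer) contributes the unmapped penalty
instead. Distances are kept as exact half-integers (`fractions.Fraction`),
so tie detection involves no epsilon.

Decision rule, per read (pair): no mapping to either reference → NEITHER;
mapping to one reference only → that species; mapping to both → the lower
ED wins, equality is a TIE and the read is written to neither output. A
would-be graft call whose ED exceeds `max_edit_distance` becomes
CAP_EXCEEDED and is kept out of the graft output.

Two defined-behavior choices deserve note:

* **The ED formula is applied literally.** The SAM specification defines NM
  as mismatches plus inserted *and deleted* bases, so `S + I + NM` counts
  insertions twice for a spec-conforming aligner. The literal sum is the
  published definition of the statistic and is the default; the
  `nm_decompose` switch subtracts CIGAR I and D bases from NM first for
  users who prefer `S + I + mismatches`. Both paths are tested against
  independently recomputed alignment components. Deletions and splice
  skips (N) contribute nothing of their own, which is what keeps the
  statistic applicable to spliced RNA alignments.
* **The cap applies to the graft side only.** The product being protected
  is the filtered graft BAM; the cap keeps poorly matching reads out of
  it. Host-side calls are not capped, and capped reads are itemized
  separately in the report (not folded into TIE or HOST), so the cap's
  effect is auditable. Whether capped reads should instead count as host
  is a judgment call; reporting them separately preserves both readings.

Scoring uses primary alignments only. Secondary and supplementary records
are carried along and written or dropped with their primary's bundle;
supplementary (chimeric) records get no special treatment beyond that.

**Strict filtering** is the conservative baseline: a read (pair) with any
primary mate mapped to the host reference is host, whatever the distances.
With the cap disabled, every read strict filtering keeps is also kept by
edit-distance filtering (strict keeps only host-unmapped reads, which the
edit-distance rule assigns to the graft by the single-reference rule); the
containment is exercised across randomized fixtures in the tests.

## Pipeline

Each sample is processed in two passes. The host-aligned BAM is reduced to
a query-name → score table and its records discarded; the graft-aligned
BAM is then streamed, collated by name, classified, and written. This makes
the pipeline order-agnostic — shuffled inputs produce identical decisions
and reports — at the cost of memory proportional to the number of distinct
read names (a name-grouped fast path that emits bundles as names change is
available for collated inputs). All output records, including the optional
host BAM, are drawn from the **graft-aligned** input so that every product
remains analyzable against the graft reference; the host BAM contributes
scores, never records. A consequence: a read unmapped in the graft BAM can
never appear in any output, whatever its host-side alignment. The appended
@PG header line records the tool, version and parameters, including this
record-provenance choice.

A mapped record without an NM tag is a fatal error rather than a silent
zero: the statistic is undefined without it, and reconstructing NM from MD
tags is out of scope. Batches run samples independently (optionally in
parallel processes); one sample's failure is recorded in its result slot
and the rest proceed.

## Synthetic xenograft model

The simulator provides what real PDX data cannot: per-read ground truth.

**Genomes.** An ancestor sequence of i.i.d. uniform bases is evolved along
two independent branches. Each site substitutes with probability *d* per
branch (default 0.08), drawing uniformly from the three other bases, so
two genomes differ at a site with probability 2d(1−d) + (2/3)d² — the
oracle used by the divergence-recovery tests. A conserved fraction
(default 10%, in 1 kb blocks spread evenly with random offsets)
substitutes at a lower rate (default 0.01), emulating exon-like conserved
sequence where graft and host reads genuinely resemble each other — the
regime that produces ties. Indels occur per site at rate 1e-4 per branch
(geometric lengths, mean 2 bp, capped at 10 bp). Coordinate maps between
each genome and the ancestor are recorded so the homologous locus of any
read is computable in both genomes. The default divergence is deliberately
coarser than the real human–mouse genome-wide picture; what matters for
exercising the classifier is the contrast between diverged bulk and a
conserved fraction, not phylogenetic realism.

**Reads.** Uniform fragment starts, both strands equally, FR mate
orientation with Normal insert sizes (default 300 ± 30, truncated below at
the read length), i.i.d. per-base substitution errors (default 1%), no
quality model (all bases Q40). Defaults are 100 bp paired-end reads.
Mixtures take exact counts — `round(fraction × total)` graft reads — and
shuffle deterministically.

**Alignment emulator.** Instead of requiring an external aligner, each
read is aligned to the homologous window of each genome, found through the
coordinate maps. Windows untouched by any indel take a vectorized ungapped
path: full-length match CIGAR with NM equal to the Hamming mismatch count.
Windows crossed by an indel, and ungapped hits below the identity floor,
go through affine-gap alignment (Biopython `PairwiseAligner`; match +1,
mismatch −4, gap open −6, gap extend −1, free end gaps) with read
overhangs emitted as soft clips. A read with fewer than 80% of its bases
matching is emitted as unmapped to that genome. NM is written
SAM-conformingly (mismatches + inserted + deleted bases), which is
precisely what makes the literal-vs-decomposed formula switch testable.
The emulator knows each read's true locus, so it cannot produce spurious
mappings to paralogous loci; random placement noise of a real aligner is
out of its scope, and headline numbers from emulated alignments are
accordingly a clean-mapping best case.

**What passing tests show.** The simulation demonstrates that the
classifier separates reads whose references differ at the modeled
divergence, with ties confined to conserved windows that happen to contain
no discriminating site. It does not model exome capture bias, PCR
duplicates, base-quality-dependent error, structural variants, or
multi-mapping artifacts of real aligners; real-data performance claims are
outside what these tests establish.

## Problem sizes and determinism

The end-to-end benchmark (`run_mixing_benchmark`, also what
`scripts/acceptance.py` runs) uses a 1 Mb ancestor, 50,000 read pairs per
species mixed 50:50 (100,000 pairs total), and finishes in about half a
minute on one CPU. At these sizes the binomial tolerances in the tests
(±5 standard deviations) are far below the margins being asserted. All
randomness flows from a single user seed through numpy `SeedSequence`
spawn keys, so every stage is independently reproducible; the same seed
yields byte-identical genomes, reads and alignments.

## Known limitations

* Memory of the default collation path scales with distinct read names;
  very large BAMs should be name-collated first and use the fast path.
* CRAM, MD-based NM reconstruction, and coordinate-sorted/indexed outputs
  are not provided.
* The strict-mode report counts a host-mapped pair as HOST even when the
  graft side is also mapped — by design, that is the baseline's defining
  behavior.
* The emulator writes one primary record per read and never emits
  secondary alignments; secondary-propagation behavior is exercised with
  hand-built fixtures instead.
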