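# Methods

## Scope and model

pirnakit re-creates, at desk scale, the standard computational workflow for
characterizing piRNA populations in mouse testis small-RNA-seq libraries:

1. **Preprocessing** — clip the 3' sequencing adapter from each read, filter
   clipped inserts to the piRNA length window (closed interval 24–32 nt),
   and collapse identical inserts into counted unique sequences.
2. **Alignment** — map each unique sequence to both strands of every
   reference sequence allowing at most one substitution over the whole read
   (Hamming distance ≤ 1, no indels).
3. **Hierarchical annotation** — assign each read to the first category, in
   priority order (piRNA clusters → coding RNA → non-coding RNA → repeats →
   introns), that yields at least one alignment; unaligned reads go to the
   "other" sink.
4. **Metrics** — normalized length spectra, first-nucleotide (1U)
   composition, per-cluster counts, and between-library per-length ratios.
5. **Ping-pong analysis** — the 5'-5' overlap profile of opposite-strand
   read pairs on a transposon consensus, and sense/antisense 5'-end
   coverage along it.

Because raw testis libraries are not bundled, a synthetic generator
produces libraries with the same statistical structure plus a ground-truth
table, so every stage is validated by parameter recovery rather than by
eyeballing plots.

## Preprocessing

The adapter is searched as a prefix alignment against every read suffix,
left to right; a start qualifies when the overlap is at least
`min_overlap` (default 5 nt) and the mismatches are at most
`floor(max_adapter_mismatch_rate × overlap)` (default rate 0.1). The
leftmost qualifying start wins, which prevents a spurious adapter-like
k-mer near the read's 3' end from shortening the insert when the true
occurrence lies earlier. Reads with no qualifying start are dropped unless
`keep_unclipped` is set; an insert of length zero is always dropped.
Inserts containing N are discarded after clipping — under the one-mismatch
rule they essentially never map, so discarding them is explicit and
counted. The clipper's overlap/mismatch defaults are package decisions;
they are not derived from any published library protocol.

The miRNA count used for normalization is the total multiplicity of
clipped reads of 21–23 nt, with no requirement that they map to an
annotated miRNA locus. This is the simpler of the two possible readings
of "miRNA reads (21–23 nt)" and is applied consistently.

## Alignment

"One mismatch allowed" is implemented as whole-read Hamming distance ≤ 1.
(Seed-restricted mismatch models used by some genome aligners differ in
corner cases; the whole-read model is the simplest faithful reading and
is exhaustively checkable.) The production path is a pigeonhole seed
index: any placement with at most one mismatch contains at least one
error-free read half, so exact lookups of the two halves enumerate every
candidate, which is then verified base by base. The oracle
(`brute_force_align`) slides the read along every reference position on
both strands and counts mismatches with vectorized comparisons; the test
suite asserts exact hit-set equality between the two paths on planted and
random reads at both mismatch limits. N in read or reference counts as a
mismatch at that position, even opposite another N.

Coordinates are 0-based half-open on the plus strand everywhere. A
minus-strand hit means the read equals the reverse complement of the
reference window; its biological 5' end is at plus-strand position
`end − 1`. All hits are reported — no best-stratum filtering and no hit
cap — so downstream modules own all weighting policy.

## Annotation

Categories are consulted strictly in catalog order and the first category
with a hit wins; later categories are never consulted for that read.
"Other" means "unaligned to any provided set": no whole genome is
provided at desk scale, so there is no distinction between unannotated
genome-mappers and true orphans. Annotation ignores strand; strand enters
only the ping-pong and coverage analyses. Multi-hit reads keep every hit
within the winning category; quantification (below) apportions their
counts fractionally.

## Metrics and normalization

Two normalization schemes are wired to library kind: total-RNA libraries
are normalized by their miRNA counts; immunoprecipitation libraries by
their total clipped read counts ("total reads" is taken as reads after
clipping, before the length filter — the more inclusive reading). Either
scheme can be overridden per library in the config.

Per-cluster counts: a read with k hits in the winning cluster category
contributes count/k to each hit's cluster, so read mass is conserved
across clusters before top-N truncation. The Top-50 table ranks clusters
per library (whether published Top-50 rankings are per-library or fixed
by the control is not documented anywhere; per-library is this package's
choice). Between-library comparisons report per-length ratios b/a with a
the control; lengths where the control abundance is zero are reported as
undefined (NaN), never infinite.

## Ping-pong profile

With a plus-strand 5' end at plus coordinate p and a minus-strand 5' end
at plus coordinate q, the pair's 5'-5' overlap is k = q − p + 1, so the
canonical ping-pong pair gives k = 10. Every (plus, minus) combination
contributes the product of the two reads' weights to its offset;
percentages are taken over offsets 1..K (default K = 20). Computation is
a cross-correlation of the two per-position weight vectors (K dot
products), verified in tests against a literal double loop over pairs.
Pair weighting defaults to abundance (count products); unique-sequence
weighting is available via a flag. Multi-hit reads contribute to each of
their element hits with weight 1/k_hits, consistent with cluster
counting. The z-score summary at offset 10 — (value − mean of other
offsets) / sd of other offsets — is reported as undefined when the sd is
zero (flat or single-spike profiles); it is a diagnostic, not a headline
statistic, as is the 10A fraction.

## Synthetic generator

The generator emulates three read populations: miRNA-like (21–23 nt,
drawn from non-coding RNA references), MILI-piRNA-like (25–28 nt) and
MIWI-piRNA-like (29–32 nt), with piRNA inserts drawn from piRNA clusters
and from a 6-kb LINE1-like element that lives inside the repeat category
(as LINE1 does in RepeatMasker-style annotations). Length distributions
default to uniform over each population's window. Cluster choice is
rank-weighted (∝ 1/rank), emulating the dominance of the top pachytene
piRNA-producing loci. Defaults: 2,000 miRNA / 8,000 MILI / 8,000 MIWI
reads; u1_fraction 0.8 (pachytene piRNA libraries show a strong first-U
bias, typically near 75–85%); pingpong_fraction 0.1; pingpong_offset 10;
a10_fraction 0.7; element_fraction 0.15; error_rate 0.001 per base;
adapter = the Illumina small-RNA 3' adapter prefix
`AGATCGGAAGAGCACACGTCT`. Real libraries' adapters and error profiles are
protocol-dependent; these defaults are exposed in the config.

Bias forcing always substitutes the target position: the first base of a
primary (non-responder) piRNA insert becomes U with probability
u1_fraction and a uniformly chosen non-U base otherwise, so the empirical
first-U fraction converges to u1_fraction exactly; position 10 of a
responder is forced the same way toward A. Responders are exempt from 1U
forcing (and primaries from 10A): a read forced at two positions would
sit at Hamming distance 2 from its source and become unmappable under the
one-mismatch rule, and biologically the 1U mark belongs to primary and
the 10A mark to secondary piRNAs. Consequence: an error-free read equals
its reference window except possibly at the one forced position; the
truth table stores the final insert sequence so tests can assert this
exactly.

Ping-pong pairs are planted by making a fraction of each piRNA population
minus-strand responders whose 5' ends sit exactly `pingpong_offset − 1`
positions 3' of a randomly chosen plus-strand element read (the
initiator); the remaining element-derived reads are placed uniformly on
both strands, giving the profile a well-defined flat null. If responders
are requested but no plus-strand element read would exist, the generator
deterministically converts one read into an initiator. An element shorter
than the longest read plus the offset is a configuration error.

What the generator does **not** model: indels, position-dependent quality
(qualities are constant Phred 40 and ignored), PCR duplicates, ligation
bias, secondary structure, isomiR/trimming heterogeneity, and a full
genome background (the "other" fraction of synthetic libraries comes only
from reads mutated beyond one mismatch). Passing recovery tests therefore
demonstrates correctness of the analysis logic under the stated
generative model, not robustness to every artifact of real libraries.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng` seeded from the
  config seed plus a fixed stream tag per stage; FASTQ bytes and the truth
  table are bit-identical across runs with the same config.
- Collapsed reads are ordered lexicographically; hits are ordered by
  (category priority, reference, start, strand); TSVs are written with a
  fixed float format — together these make pipeline outputs byte-stable.
- Fractions that should sum to 1 are checked to 1e-9; spectra windows pad
  explicit zeros over 15–40 nt for display but never drop observed lengths.
- Zero normalizers are data errors, surfaced with the offending field
  name; an empty opposite-strand pair set is *not* an error (all-zero
  profile with total weight 0).
- Config files are flat key-value YAML; unknown keys are rejected and
  validation reports every violation at once.

## Problem sizes

Recovery analyses use libraries of 6,000–34,000 reads against catalogs of
roughly 25–40 kb, and oracle comparisons use 1,000 reads against a 5-kb
catalog — sizes at which binomial sampling intervals for the planted
fractions are a fraction of a percentage point wide, and the exhaustive
alignment oracle remains exact rather than sampled. Statistical
tolerances in tests are pre-computed 99% binomial intervals or 4-sd
delta-method bounds derived from the planted parameters, never fitted to
observed output.

## Known limitations

- The aligner is desk-scale by design: lazy k-mer tables over tens of
  kilobases of references, not a genome-scale index.
- "Other" conflates unannotated-genome reads with unmappable reads.
- The ping-pong profile weights pairs by abundance products; statistics
  on it (the z-score) assume offsets are exchangeable under the null,
  which is approximate on short elements.
- No statistical tests are attached to spectrum differences; the package
  reports effect sizes (ratios), matching how such panels are typically
  presented.
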