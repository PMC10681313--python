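# pirnakit

Desk-scale analysis of piRNA populations in testis small-RNA-seq
libraries, for researchers studying piRNA biogenesis and transposon
silencing in the male germline.

piRNAs are 24–32 nt small RNAs bound by PIWI-clade Argonaute proteins; in
adult mouse testis they split into two populations distinguishable by
length — MILI-bound piRNAs (25–28 nt) and MIWI-bound piRNAs (29–32 nt) —
while miRNAs occupy 21–23 nt. pirnakit implements the standard workflow
used to characterize these populations:

- **Preprocessing**: 3' adapter clipping, length filtering to the closed
  window [24, 32] nt, and collapsing to unique sequences with counts.
- **Alignment**: mapping to both strands of reference sequence sets with
  at most one substitution (whole-read Hamming distance ≤ 1), via a
  pigeonhole seed index verified against an exhaustive oracle.
- **Hierarchical annotation**: each read is assigned to the first
  category, in priority order — piRNA clusters, coding RNA, non-coding
  RNA, repeats, introns — that yields an alignment; unaligned reads fall
  to "other".
- **Metrics**: length spectra normalized by miRNA counts (total-RNA
  libraries) or total reads (IP libraries), first-nucleotide (1U)
  composition, Top-50 per-cluster counts with fractional multi-hit
  apportioning, and between-library per-length ratios.
- **Ping-pong signature**: the 5'-5' overlap profile of opposite-strand
  pairs on a transposon consensus (for a plus 5' end p and a minus 5' end
  q on plus coordinates, the overlap is k = q − p + 1; slicer-driven
  amplification peaks at k = 10), plus sense/antisense 5'-end coverage.
- **Synthetic libraries**: a generator that plants the three populations,
  a configurable 1U bias, ping-pong pairs at a fixed offset with a 10A
  bias, a 3' adapter and per-base errors — with a ground-truth table, so
  the whole pipeline is testable by parameter recovery without any
  external data.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

```python
import pirnakit as pk

cfg = pk.SimConfig(seed=42, n_mirna=1000, n_mili=4000, n_miwi=4000,
                   error_rate=0.0, pingpong_fraction=0.3, element_fraction=0.3)
catalog = pk.build_reference_catalog(cfg)
reads, truth = pk.simulate_library(cfg, catalog)

pre = pk.preprocess_library(reads, pk.PreprocessParams(adapter=cfg.adapter))
print("clipped:", pre.stats["n_clipped"], "retained 24-32:", pre.stats["n_retained"],
      "unique:", pre.stats["n_unique"])
print("miRNA (21-23 nt) count:", pk.mirna_count(pre.clipped))

index = pk.build_index(catalog)
annotated = pk.annotate_library(pre.collapsed, index)
comp = pk.annotation_composition(annotated, catalog.category_names)
print("composition:", {k: round(v, 3) for k, v in comp.items() if v})
print("first-nt:", {k: round(v, 3) for k, v in pk.first_nt_composition(pre.collapsed).items()})

element = catalog.find(catalog.element_name)
eindex = pk.SeedIndex(pk.ReferenceCatalog([("element", {catalog.element_name: element})]))
fives = pk.collect_five_primes(pk.align_library(pre.collapsed, eindex), catalog.element_name)
profile = pk.pingpong_profile(fives, 20)
print("ping-pong peak offset:", int(profile.offsets[profile.percentages.argmax()]),
      "| %% pairs at 10: %.1f" % profile.percentages[9],
      "| z: %.1f" % pk.pingpong_zscore(profile))
```

Output:

```
clipped: 9000 retained 24-32: 8000 unique: 7511
miRNA (21-23 nt) count: 1000
composition: {'piRNA_cluster': 0.483, 'repeat': 0.517}
first-nt: {'A': 0.121, 'C': 0.124, 'G': 0.118, 'U': 0.637}
ping-pong peak offset: 10 | % pairs at 10: 25.3 | z: 69.4
```

Reading it: all 9,000 reads clip cleanly (error rate 0); the 1,000
miRNA-length reads are excluded by the 24–32 nt filter, leaving the 8,000
piRNA reads. Annotation splits them between clusters and the repeat
category (the LINE1-like element lives among the repeats; here 30% of
piRNAs were element-derived plus 30% responders). The first-nucleotide U
fraction reflects that only primary piRNAs carry the planted 0.8 U bias
(responders carry 10A instead), and the 5'-5' overlap profile peaks at
exactly 10 nt — the planted ping-pong signature.

## Command line

Every stage is a subcommand of the `pirnakit` console script: `simulate`,
`clip`, `filter`, `collapse`, `align`, `annotate`, `metrics`, `pingpong`,
and `run-all`, which drives the full pipeline from a flat YAML config
(library entries as `library.<name>.fastq` / `.kind`, catalog entries as
`catalog.<category>` in `catalog_order`). Unknown keys are rejected and
validation reports all problems at once. Exit codes: 0 success, 2 config
error, 3 data error.

```sh
pirnakit simulate --seed 1 --out sim/
pirnakit run-all --config run.yaml
```

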