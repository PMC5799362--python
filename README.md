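# uorfscan

Upstream open reading frame (uORF) discovery and mutation screening for
cancer genomics.

## The problem

uORFs are short ORFs in the transcript leader sequence (TLS, the 5' UTR):
an AUG upstream of the main coding sequence (CDS) paired with a
downstream in-frame stop codon (TAA/TAG/TGA). Scanning ribosomes often
initiate at these upstream AUGs, so uORFs constitutively *repress*
translation of the downstream CDS. A somatic point mutation that destroys
a uORF start codon (loss-of-uAUG), its stop codon (loss-of-uStop) or the
strength of its Kozak initiation context can therefore de-repress a
downstream proto-oncogene — a translational route to overexpression that
ordinary protein-coding variant annotation does not look for.

`uorfscan` implements the computational machinery for finding such
events:

1. **Discovery** (`uorfscan.uorf_discovery`) — per coding transcript,
   extract the spliced TLS (introns excluded) with a bidirectional
   spliced↔genomic coordinate map; report every AUG fully inside the TLS
   with its *closest* in-frame stop. A uAUG with no in-TLS stop is kept
   but flagged CDS-overlapping and contributes no stop to the uStop
   catalog. The Kozak context of each uAUG is classified from the core
   positions −3 and +4 of the optimal context `GCCGCCAUGR` (R = purine):
   2 core matches = strong, 1 = intermediate, 0 = weak. Outputs: BED12
   uORFs, BED codon tracks, TSV catalog.
2. **Screen filtering** (`uorfscan.screen_filter`) — per-site, per-sample
   amplicon base tallies become candidate mutation calls when covered by
   ≥ 10 reads with more than 10% of reads deviating from the reference
   base (a heterozygous mutation in a 50%-pure tumor deviates in ~25% of
   reads), unless the non-reference reads are scattered over several
   bases (noise exclusion); candidates matching a known-polymorphism
   catalog are partitioned out.
3. **Variant annotation** (`uorfscan.variant_annotation`) — subset
   somatic VCFs to the uORF codon (and optionally Kozak-window)
   positions, intersect across callers in matched tumor/normal mode,
   gate on ≥ 10 reads in both tumor and normal, and classify each SNV:
   `loss_of_uAUG` (always a near-cognate mutant codon), `loss_of_uStop`,
   `stop_retained`, `kozak_alteration`, or `complex` for non-SNVs.
4. **Synthetic data** (`uorfscan.synthetic_data`) — seeded generators for
   every input (genome FASTA, refGene-style transcript table, VCFs per
   pseudo-caller, base-count TSV) with an exact ground-truth manifest, so
   the whole pipeline is testable offline.

## Worked example

The package ships the five Sanger-verified uORF-associated mutations
(*BLK*, *EPHB1*, *JAK2*, *MAP2K6*, *CHD1L*) as a built-in worked example:

```sh
python examples/annotate_variants.py
```

prints

```
BLK     chr8:11351560 G>T [CA1] loss_of_uAUG     ATG -> ATT (near-cognate)
EPHB1   chr3:134514263 A>G [MC1] loss_of_uAUG     ATG -> GTG (near-cognate)
EPHB1   chr3:134514263 A>G [CX1] loss_of_uAUG     ATG -> GTG (near-cognate)
JAK2    chr9:5021969 G>A [NHL1] loss_of_uAUG     ATG -> ATA (near-cognate)
MAP2K6  chr17:67410881 T>C [CA2] loss_of_uAUG     ATG -> ACG (near-cognate)
CHD1L   chr1:146731516 G>T [CX2] kozak_alteration Kozak intermediate -> intermediate

variant-level tally : {'kozak_alteration': 1, 'loss_of_uAUG': 4}
recurrent variants  : 1 (the EPHB1 event was seen in two samples)
```

Four mutations delete a uORF initiation codon (each mutant codon is
near-cognate — one base away from AUG, so residual initiation is
possible); the fifth changes a non-core Kozak base, leaving the context
class intermediate. The *EPHB1* event recurs in two samples, so the
variant-level tally counts five distinct mutations from six
per-sample effects.

The other example scripts each demonstrate one capability:

* `examples/find_uorfs.py` — discovery on a synthetic genome, catalog
  totals, shared-stop and CDS-overlap bookkeeping.
* `examples/screen_filter_demo.py` — the screen filter's decision
  boundaries (coverage gate, strict 10% trigger, noise exclusion).
* `examples/simulate_cohort_demo.py` — full synthetic study: 22 planted
  start-loss and 31 stop-loss SNVs recovered exactly after four-caller
  consensus.

A thin CLI wires the same stages for shell use:

```sh
uorf-scan simulate --seed 1 --out-dir sim
uorf-scan find --fasta sim/genome.fa --refgene sim/refgene.txt --out-prefix out
uorf-scan screen-call --counts sim/counts.tsv --design sim/design.tsv --out calls.tsv
uorf-scan annotate --catalog out.catalog.tsv --caller m2=sim/caller_mutect2.vcf \
    --caller mu=sim/caller_muse.vcf --fasta sim/genome.fa --out effects.tsv
```

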