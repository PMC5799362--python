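# Methods

## The uORF model

A uORF is defined on the *spliced* transcript leader sequence (TLS): the
concatenated exonic sequence upstream of the annotated CDS start, in
transcript orientation. Discovery applies three rules:

1. Every `ATG` whose three bases lie fully inside the TLS opens a uORF.
   Codons are never allowed to straddle the TLS/CDS boundary: the scan
   operates on the extracted leader only.
2. The uORF terminates at the *closest* downstream in-frame stop codon
   (`TAA`, `TAG`, `TGA`) fully inside the TLS. Because the scan is
   5'→3' and "closest" is the first in-frame stop, there are no ties and
   no randomness anywhere in discovery. Several in-frame uAUGs may share
   one termination codon; they are grouped by a shared-stop identifier,
   which is why the unique-uStop count is always ≤ the unique-uAUG
   count.
3. A uAUG with no in-frame stop inside the TLS is retained and flagged
   `cds_overlapping` — its ORF runs into or past the CDS — but it
   contributes nothing to the uStop catalog. This keeps
   overlapping-uORF biology visible while excluding stop codons that lie
   downstream of the CDS start from codon-level tallies.

Codons containing `N` never match as start or stop: on masked or
ambiguous sequence the scanner makes no call rather than a guess.

### Kozak context

The initiation context is classified from the window covering positions
−6..−1 and +4 relative to the A of the AUG, against the optimal context
`GCCGCCAUGR`. Only the two *core* positions are scored: −3 and +4. The
default match rule is purine (A or G) at both positions, since the
optimal context ends in R; an exact-G rule is available per position via
`KozakPolicy`. Two core matches = strong, one = intermediate, none =
weak. The +4 base is the next spliced base after the AUG — a TLS base
for internal uAUGs, the first CDS base when the uAUG abuts the CDS
(leaders capture that base at extraction time, so Kozak classification
needs no further genome access). A window position upstream of the
transcript 5' end, or an `N` at a core position, renders the strength
`undetermined`. The policy in force is recorded in every output header.

Whether positions −6..−4 also count as "core" is genuinely ambiguous in
the field's 0/1/2-match convention; this package counts −3/+4 only,
which reproduces the three-class (strong/intermediate/weak) scheme.

### Coordinates and isoform deduplication

Internally everything is 0-based half-open (BED convention); conversion
to 1-based happens only at the VCF and base-count-file boundaries.
Spliced↔genomic projection uses an explicit per-base coordinate map, so
codons split by introns project to multi-block BED records and re-splice
exactly.

Catalogs support two counting modes. `by-genomic-position` (default for
genome-wide tallies) deduplicates identical (contig, strand, codon
blocks) across isoforms so shared exons are not double-counted;
`per-transcript` keeps one entry per isoform for screen bookkeeping. How
published genome-wide codon counts were deduplicated across isoforms is
generally not stated by screening studies, so both modes are first-class
rather than one being resolved as "correct".

## The screen filter

Input is a per-site, per-sample base tally (A/C/G/T/DEL). Decision
sequence, with every site receiving exactly one status:

* `low_coverage` — total reads < `min_reads` (default 10, inclusive);
* `no_call` — aggregate deviation (non-reference reads / total) ≤
  `min_deviation` (default 0.10, *strict*: "more than 10%");
* `excluded_noise` — ≥ 2 distinct alternate bases and the top alternate
  carries < `noise_top_alt_fraction` (default 2/3) of the non-reference
  reads. This codifies as a rule what targeted screens do by manual
  inspection: a pattern like 7 reference reads plus one read each of C,
  G and T is a probable artifact, while a clean 25% single-alternate
  heterozygote is kept. The 2/3 default is the loosest simple fraction
  that separates those two patterns; it is configurable.
* `candidate` — otherwise. Ties between equally supported alternates
  break lexicographically (deterministic output). Deletions count toward
  the deviation and may be the top alternate; multi-base deletion/repeat
  regions are handled only via the known-variant catalog, not called de
  novo.

The deviation trigger is deliberately aggregate (not per-alternate): a
heterozygous mutation in a sample of 50% tumor purity deviates in ~25%
of reads, comfortably above the 10% trigger, and tumor samples can be
genetically heterogeneous. `candidate` calls matching a known-variant
catalog are relabelled `known_snp`; matching is allele-aware for VCF
catalogs and position-only for BED catalogs (which carry no alleles).

`coverage_summary` reports the full site × sample design (missing cells
count as zero reads), the fraction of cells reaching `min_reads`, and
the read share of the top q% of sites (floor(n·q/100) sites, at least
one) — the standard skew statistic for pooled amplicon libraries.

## Variant annotation

Caller VCFs are read with plus-strand alleles and 1-based positions
converted to internal coordinates, multi-allelic records split. The
analysis chain:

1. **Subset** to catalog positions (codon bases, optionally the Kozak
   window). Zero contig-name overlap between variants and catalog
   aborts as an assembly mismatch — never a warning.
2. **Consensus** across callers on the key (contig, pos, ref, alt,
   sample pair); the default requirement is *all* supplied callers
   (maximum specificity), `required=1` degrades to the deduplicated
   union, and the kept-set size is monotone non-increasing in the
   requirement.
3. **Coverage gate**: ≥ `min_reads` in both tumor and matched normal.
4. **Classification**: the plus-strand alternate is complemented onto
   the transcript strand and substituted into the catalog codon. Any
   single-base change of `ATG` is `loss_of_uAUG` and by construction
   near-cognate (differs from AUG at exactly one position — such codons
   can retain weak initiation, which is why the mutant codon is always
   reported). Stop substitutions split into `stop_retained` (stop →
   different stop: 4 of the 27 single-base stop substitutions) and
   `loss_of_uStop` (stop → sense: the other 23). Kozak-window hits are
   `kozak_alteration` with strength re-evaluated before and after.
   Multi-nucleotide and indel records are reported as `complex`, never
   silently dropped. A reference allele disagreeing with the catalog or
   the genome raises an error (fail-loud).
5. **Tabulation** at two levels: per effect (one per isoform hit) and
   per distinct variant (contig, pos, alt) — the genomic roll-up used
   for cohort tallies. A variant hitting elements of several isoforms
   counts once per classification at the variant level; this roll-up is
   a documented package choice, since cohort studies rarely state how
   isoform-shared codons were counted. Recurrence means the identical
   variant in ≥ 2 sample pairs; "novel" means absent from the supplied
   known-variant catalog (always a local file, never a network query).

## The synthetic-data generator

The generator emulates the structure of a targeted uORF mutation study:
multi-exon transcripts on both strands with planted uORFs (plain,
in-frame pairs sharing one stop, CDS-overlapping, intron-split start
codons, plus non-coding decoys), somatic SNVs with intended
consequences, per-caller VCFs, and amplicon base counts. Defaults:

| parameter | default | rationale |
|---|---|---|
| TLS length | 50–500 nt | typical human leader lengths |
| uORF prevalence | 0.55 | fraction of human leaders carrying ≥ 1 AUG-uORF |
| GC content | 0.45 | genome-scale human-like background |
| tumor purity | 0.5 | the screen's minimum tumor-cell content; het VAF 0.25 |
| sequencing error | 0.005/base | Illumina-class substitution noise |
| depth model | log-normal, median 103, σ 1.5 | the skewed per-site efficiency of pooled PCR amplicons |
| exons per transcript | 1–4 | enough to exercise splice-aware projection |

Exactness guarantee: background TLS sequence is scrubbed of stray AUGs,
and planted uORFs of interior in-frame stops, by substituting `C` — a
base that occurs in neither `ATG` nor any stop codon, so a scrub can
never create a new start or stop. A final independent re-scan asserts
that the planted feature set is *exactly* the discoverable set, which is
what lets tests compare the discovery catalog to the manifest with
equality rather than tolerance. Kozak classes recorded in the manifest
are the realized classes of the generated sequence.

Base counts at a cell carrying a planted heterozygous variant draw the
alternate with probability `purity/2·(1−e) + e/3` (homozygous:
`purity·(1−e) + e/3`); all other cells carry error-only alternates at
`e/3` per base. Per-site efficiency is log-normal with mean 1, shared by
all samples of a site (the screen's skew was site-specific, not
sample-specific); `depth_sigma = 0` gives exact constant depth for
closed-form checks. A single global seed fans out to per-stage child
seeds by stable SHA-256 hashing of the stage name, so identical seeds
give byte-identical files and partial re-runs are reproducible.

What the generator does **not** emulate: read-level artifacts (PCR
chimeras, strand bias, mapping error), sample-to-sample DNA quality
variation, multi-base indels and repeat regions, and linkage between
variants. Passing tests therefore demonstrate the correctness of the
*algorithms* on structurally realistic inputs, not performance on real
tumor sequencing data.

## Problem sizes and numerical choices

The test suite and acceptance script run synthetic cohorts of 48–70
transcripts on 120–180 kb genomes with 55–75 planted variants — small
enough to run in seconds while exercising both strands, intron-split
codons, shared stops and CDS-overlap cases; these sizes are the
package's chosen verification scale. Oracle checks compare the scanner
against an independent quadratic re-implementation on 110–150 random
leaders (lengths 0–1000, GC 30–70%). Tolerances: the purity check uses
±0.01 on a binomial fraction at depth 10⁴ (≫ 3 binomial SDs); the
log-normal coverage check uses ±2% against a numerically integrated
expectation; everything structural (codon sets, planted counts,
round-trips) is compared exactly. Cohort-scale published quantities that
depend on controlled-access tumor data or a specific annotation snapshot
are out of scope by design; the pipeline is verified against synthetic
ground truth instead.

## Known limitations

* Near-cognate (non-AUG) starts are not scanned; only AUG-initiated
  uORFs are catalogued.
* GTF/GFF3 ingestion is not provided; transcript models come from
  refGene-style tables (15 or 16 columns, auto-detected).
* Indels are classified `complex` only; their downstream frame effects
  are not modelled.
* The screen filter calls single positions; haplotype or multi-site
  evidence is not combined.
* No NMD prediction, conservation scoring or translation-efficiency
  modelling is attempted.
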