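"""Built-in worked example: five Sanger-verified uORF-associated mutations.

A targeted deep-sequencing screen of human malignancies verified five
somatic/novel uORF-associated point mutations: loss of the uORF
initiation codon in *BLK* (ATG->ATT), *EPHB1* (ATG->GTG, seen in a
mammary carcinoma and a colon-cancer xenograft), *JAK2* (ATG->ATA) and
*MAP2K6* (ATG->ACG), plus one Kozak-window alteration in *CHD1L*
(ttgTggATGA -> ttgTgtATGA at position -1). This module encodes those
five events — hg19 coordinates, reference and mutant alleles, codon
context — as a ready-made catalog + variant set, so the consequence
classifier can be demonstrated and regression-tested without any genome
download. All records are laid out on the plus strand, matching the
transcript-strand codons as printed.
"""

from __future__ import annotations

from .genome_io import VariantRecord, positions_to_blocks
from .uorf_discovery import UORF, KozakContext, KozakPolicy, UORFCatalog

#: gene, contig, 1-based coordinate of the mutated base, ref, alt,
#: element, position within the element, affected sample pairs
VERIFIED_MUTATIONS = (
    ("BLK", "chr8", 11351560, "G", "T", "uAUG", 2, ("CA1",)),
    ("EPHB1", "chr3", 134514263, "A", "G", "uAUG", 0, ("MC1", "CX1")),
    ("JAK2", "chr9", 5021969, "G", "A", "uAUG", 2, ("NHL1",)),
    ("MAP2K6", "chr17", 67410881, "T", "C", "uAUG", 1, ("CA2",)),
    ("CHD1L", "chr1", 146731516, "G", "T", "uKozak", -1, ("CX2",)),
)

_CHD1L_WINDOW = "ttgTggATGA"  # reference Kozak context of the CHD1L uAUG


def _uaug_record(gene: str, contig: str, codon_positions: tuple[int, int, int]) -> UORF:
    return UORF(
        transcript_id=gene,
        gene_symbol=gene,
        contig=contig,
        strand="+",
        uaug_offset=0,
        ustop_offset=None,
        cds_overlapping=False,
        length_nt=None,
        stop_codon=None,
        start_positions=codon_positions,
        stop_positions=None,
        start_blocks=tuple(positions_to_blocks(codon_positions)),
        stop_blocks=None,
        span_blocks=tuple(positions_to_blocks(codon_positions)),
        kozak=KozakContext(window="." * 3 + "." + ".." + "ATG.",
                           core_matches=0, strength="undetermined"),
        kozak_genomic={},
        shared_stop_group=None,
    )


def verified_mutation_catalog() -> tuple[UORFCatalog, list[VariantRecord]]:
    """The five verified events as (uORF catalog, plus-strand variants)."""
    records: list[UORF] = []
    variants: list[VariantRecord] = []
    for gene, contig, coord1, ref, alt, element, where, samples in VERIFIED_MUTATIONS:
        pos = coord1 - 1  # printed 1-based -> internal 0-based
        if element == "uAUG":
            start = tuple(range(pos - where, pos - where + 3))
            records.append(_uaug_record(gene, contig, start))
        else:  # the CHD1L Kozak-window event: ATG begins right after -1
            start = (pos + 1, pos + 2, pos + 3)
            rec = _uaug_record(gene, contig, start)
            rec.kozak = KozakContext(window=_CHD1L_WINDOW, core_matches=1,
                                     strength="intermediate")
            rec.kozak_genomic = {where: pos}
            records.append(rec)
        for sample in samples:
            variants.append(
                VariantRecord(contig=contig, pos=pos, ref=ref, alt=alt,
                              sample_pair_id=sample)
            )
    catalog = UORFCatalog(records, policy=KozakPolicy(), dedupe="per-transcript")
    return catalog, variants


def classify_verified_mutations() -> dict:
    """Run the five events through subset -> classify -> tabulate."""
    from .variant_annotation import classify_effect, subset_to_catalog, tabulate_effects

    catalog, variants = verified_mutation_catalog()
    pairs = subset_to_catalog(variants, catalog, kozak_window=True)
    effects = [classify_effect(v, h, policy=catalog.policy) for v, h in pairs]
    return tabulate_effects(effects)
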