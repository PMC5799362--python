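"""Consequence annotation of somatic variants on uORF elements.

The whole-exome side of the analysis: caller VCFs are subset to the
genomic positions of uORF initiation (uAUG) and termination (uStop)
codons (optionally the surrounding Kozak window), intersected across
callers in matched tumor/normal mode, gated on coverage in both tumor and
normal, and classified:

* ``loss_of_uAUG``   — single-base change of an AUG; by construction the
  mutant codon is always near-cognate (differs from AUG at one position).
* ``loss_of_uStop``  — stop codon changed to a sense codon.
* ``stop_retained``  — stop codon changed to a different stop codon.
* ``kozak_alteration`` — a base of the Kozak window (-6..-1, +4) changed;
  strength is re-evaluated before and after.
* ``complex``        — multi-nucleotide or indel record (reported, never
  silently dropped).

VCF alleles are plus-strand; complementation to the transcript strand
happens here. A reference allele that disagrees with the catalog (or the
genome, when provided) aborts loudly — silent coordinate drift is the
dominant failure mode in this domain.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .genome_io import (
    GenomeSequence,
    SiteBaseCount,
    VariantRecord,  # re-exported surface
    complement_base,
)
from .uorf_discovery import (
    STOP_CODONS,
    CatalogHit,
    KozakPolicy,
    UORFCatalog,
    kozak_strength_of_window,
)

__all__ = [
    "VariantRecord",
    "UORFEffect",
    "AssemblyMismatchError",
    "ReferenceMismatchError",
    "subset_to_catalog",
    "consensus",
    "coverage_gate",
    "classify_effect",
    "tabulate_effects",
]

logger = logging.getLogger(__name__)

_KOZAK_REL_TO_WINDOW_INDEX = {-6: 0, -5: 1, -4: 2, -3: 3, -2: 4, -1: 5, 4: 9}


class AssemblyMismatchError(ValueError):
    """Variants and catalog share no contig names — wrong genome assembly."""


class ReferenceMismatchError(ValueError):
    """A variant's reference allele disagrees with the catalog/genome."""


@dataclass
class UORFEffect:
    """A variant's consequence on one uORF element of one isoform."""

    variant: VariantRecord
    element: str  # uAUG | uStop | uKozak
    transcript_id: str
    ref_codon: str | None
    alt_codon: str | None
    classification: str
    near_cognate: bool = False
    kozak_before: str | None = None
    kozak_after: str | None = None


def subset_to_catalog(
    variants: Sequence[VariantRecord],
    catalog: UORFCatalog,
    kozak_window: bool = False,
) -> list[tuple[VariantRecord, CatalogHit]]:
    """Pair each variant with every uORF element whose footprint it hits.

    A variant can hit elements of several isoforms; one pairing is emitted
    per hit. With ``kozak_window`` the positions -6..-1 and +4 of every
    uAUG are matched too. Zero contig-name overlap between non-empty
    variant and catalog sets raises :class:`AssemblyMismatchError`.
    """
    variants = list(variants)
    if variants and catalog.records:
        if not ({v.contig for v in variants} & catalog.contigs):
            raise AssemblyMismatchError(
                "no contig names shared between variants and uORF catalog; "
                "inputs are probably on different assemblies"
            )
    index = catalog.position_index(kozak_window=kozak_window)
    pairs: list[tuple[VariantRecord, CatalogHit]] = []
    for v in variants:
        for hit in index.get((v.contig, v.pos), ()):
            pairs.append((v, hit))
    return pairs


def consensus(
    variant_sets: Mapping[str, Sequence[VariantRecord]],
    required: int | None = None,
) -> list[VariantRecord]:
    """Keep variants reported by at least ``required`` callers.

    ``variant_sets`` maps caller id -> that caller's records; the matching
    key is (contig, pos, ref, alt, sample pair). ``required`` defaults to
    *all* supplied callers (the matched-mode maximum-specificity filter);
    ``required=1`` yields the de-duplicated union. Output records carry
    the supporting caller set and are deterministically sorted.
    """
    if required is None:
        required = len(variant_sets)
    support: dict[tuple, set[str]] = defaultdict(set)
    first_seen: dict[tuple, VariantRecord] = {}
    for caller, records in variant_sets.items():
        for r in records:
            k = r.key()
            support[k].add(caller)
            first_seen.setdefault(k, r)
    kept = []
    for k, callers in support.items():
        if len(callers) >= required:
            r = first_seen[k]
            kept.append(
                VariantRecord(
                    contig=r.contig, pos=r.pos, ref=r.ref, alt=r.alt,
                    sample_pair_id=r.sample_pair_id,
                    caller_id="consensus",
                    callers=tuple(sorted(callers)),
                )
            )
    kept.sort(key=lambda r: r.key())
    return kept


def coverage_gate(
    variant: VariantRecord,
    tumor_counts: Mapping[tuple[str, int], SiteBaseCount],
    normal_counts: Mapping[tuple[str, int], SiteBaseCount],
    min_reads: int = 10,
) -> tuple[bool, str]:
    """True when the variant position carries >= ``min_reads`` reads in
    both the tumor and the matched normal; otherwise (False, reason)."""
    key = (variant.contig, variant.pos)
    tumor = tumor_counts.get(key)
    normal = normal_counts.get(key)
    if tumor is None or normal is None:
        return False, "uncovered"
    if tumor.total < min_reads:
        return False, f"tumor_reads<{min_reads}"
    if normal.total < min_reads:
        return False, f"normal_reads<{min_reads}"
    return True, "pass"


def _substitute(codon: str, index: int, base: str) -> str:
    return codon[:index] + base + codon[index + 1 :]


def classify_effect(
    variant: VariantRecord,
    hit: CatalogHit,
    policy: KozakPolicy | None = None,
    genome: GenomeSequence | None = None,
) -> UORFEffect:
    """Classify one variant's consequence on one uORF element.

    The plus-strand alternate allele is complemented onto the transcript
    strand before substitution into the catalog's codon. Non-SNV records
    are classified ``complex`` without substitution.
    """
    policy = policy or KozakPolicy()
    record = hit.record

    if variant.is_complex:
        ref_codon = "ATG" if hit.element == "uAUG" else record.stop_codon
        return UORFEffect(
            variant=variant, element=hit.element,
            transcript_id=record.transcript_id,
            ref_codon=ref_codon if hit.element != "uKozak" else None,
            alt_codon=None, classification="complex",
        )

    if genome is not None:
        genome_ref = genome.base(variant.contig, variant.pos)
        if genome_ref != variant.ref:
            raise ReferenceMismatchError(
                f"{variant.contig}:{variant.pos}: VCF ref {variant.ref!r} "
                f"disagrees with genome base {genome_ref!r}"
            )

    minus = record.strand == "-"
    ref_tx = complement_base(variant.ref) if minus else variant.ref
    alt_tx = complement_base(variant.alt) if minus else variant.alt

    if hit.element in ("uAUG", "uStop"):
        ref_codon = "ATG" if hit.element == "uAUG" else record.stop_codon
        idx = hit.codon_index
        if ref_codon[idx] != ref_tx:
            raise ReferenceMismatchError(
                f"{variant.contig}:{variant.pos}: VCF ref {variant.ref!r} maps to "
                f"transcript base {ref_tx!r} but catalog codon {ref_codon} has "
                f"{ref_codon[idx]!r} at index {idx} ({record.transcript_id})"
            )
        alt_codon = _substitute(ref_codon, idx, alt_tx)
        if hit.element == "uAUG":
            classification = "loss_of_uAUG" if alt_codon != "ATG" else "none"
            near = sum(a != b for a, b in zip(alt_codon, "ATG")) == 1
        else:
            if alt_codon in STOP_CODONS:
                classification = "stop_retained" if alt_codon != ref_codon else "none"
            else:
                classification = "loss_of_uStop"
            near = False
        return UORFEffect(
            variant=variant, element=hit.element,
            transcript_id=record.transcript_id,
            ref_codon=ref_codon, alt_codon=alt_codon,
            classification=classification, near_cognate=near,
        )

    # uKozak
    window = record.kozak.window
    widx = _KOZAK_REL_TO_WINDOW_INDEX[hit.kozak_rel]
    window_ref = window[widx].upper()
    if window_ref != ref_tx.upper():
        raise ReferenceMismatchError(
            f"{variant.contig}:{variant.pos}: VCF ref maps to transcript base "
            f"{ref_tx!r} but Kozak window {window} has {window_ref!r} at "
            f"relative position {hit.kozak_rel} ({record.transcript_id})"
        )
    alt_char = alt_tx.upper() if widx in (3, 9) else alt_tx.lower()
    window_after = _substitute(window, widx, alt_char)
    _, before = kozak_strength_of_window(window, policy)
    _, after = kozak_strength_of_window(window_after, policy)
    return UORFEffect(
        variant=variant, element="uKozak",
        transcript_id=record.transcript_id,
        ref_codon=None, alt_codon=None,
        classification="kozak_alteration",
        kozak_before=before, kozak_after=after,
    )


def tabulate_effects(
    effects: Sequence[UORFEffect],
    known_sites: Mapping[tuple[str, int], set[str] | None] | None = None,
) -> dict:
    """Deterministic summary of classified effects.

    Counts are reported at two levels: per effect (one per isoform hit)
    and per distinct variant (contig, pos, alt), the genomic roll-up a
    cohort tally uses. Recurrence means the identical variant seen in >= 2
    sample pairs; "novel" means absent from the supplied known-variant
    catalog.
    """
    by_classification: dict[str, int] = defaultdict(int)
    by_sample: dict[str, int] = defaultdict(int)
    variant_classes: dict[tuple[str, int, str], set[str]] = defaultdict(set)
    variant_samples: dict[tuple[str, int, str], set[str]] = defaultdict(set)
    for e in effects:
        by_classification[e.classification] += 1
        by_sample[e.variant.sample_pair_id] += 1
        vkey = (e.variant.contig, e.variant.pos, e.variant.alt)
        variant_classes[vkey].add(e.classification)
        variant_samples[vkey].add(e.variant.sample_pair_id)

    variants_by_classification: dict[str, int] = defaultdict(int)
    for vkey, classes in variant_classes.items():
        for c in classes:
            variants_by_classification[c] += 1

    recurrent = sorted(
        vkey for vkey, samples in variant_samples.items() if len(samples) >= 2
    )

    n_known = n_novel = 0
    if known_sites is not None:
        for contig, pos, alt in variant_classes:
            alleles = known_sites.get((contig, pos), "absent")
            if alleles != "absent" and (alleles is None or alt in alleles):
                n_known += 1
            else:
                n_novel += 1

    return {
        "n_effects": len(effects),
        "n_variants": len(variant_classes),
        "by_classification": dict(sorted(by_classification.items())),
        "variants_by_classification": dict(sorted(variants_by_classification.items())),
        "by_sample": dict(sorted(by_sample.items())),
        "recurrent_variants": recurrent,
        "n_recurrent": len(recurrent),
        "n_known": n_known if known_sites is not None else None,
        "n_novel": n_novel if known_sites is not None else None,
    }
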