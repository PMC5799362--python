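"""Candidate-mutation calling for the MID-tagged amplicon deep-sequencing screen.

Each targeted genomic base in each sample yields a per-base read tally.
A site qualifies for analysis when it carries at least ``min_reads``
patient-specific reads (default 10); it becomes a candidate call when the
aggregate deviation from the reference base exceeds ``min_deviation``
(strictly more than 10% of reads by default — a heterozygous mutation in a
sample of 50% tumor purity deviates in ~25% of reads). Sites whose
non-reference reads are scattered over several bases (no single alternate
reaching ``noise_top_alt_fraction`` of them) are excluded as probable
sequencing noise: this codifies the screen's manual exclusion of patterns
like 7 reference reads plus one read each of the other three bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_io import SiteBaseCount  # re-exported surface

__all__ = [
    "SiteBaseCount",
    "ScreenThresholds",
    "CandidateCall",
    "call_site",
    "partition_known",
    "coverage_summary",
    "target_gene_union",
]

logger = logging.getLogger(__name__)

_ALT_ORDER = ("A", "C", "DEL", "G", "T")  # lexicographic tie-break order


@dataclass(frozen=True)
class ScreenThresholds:
    """Screen filter thresholds.

    ``min_reads`` is inclusive (>= 10 reads), ``min_deviation`` strict
    (> 10% of reads), following the screen's wording. The noise rule keeps
    a call only when the top alternate base accounts for at least
    ``noise_top_alt_fraction`` of all non-reference reads (default 2/3:
    the 7/1/1/1 pattern is excluded, a clean 25% single-alternate
    heterozygote is kept).
    """

    min_reads: int = 10
    min_deviation: float = 0.10
    noise_top_alt_fraction: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if not (0.0 < self.min_deviation < 1.0):
            raise ValueError("min_deviation must be in (0, 1)")
        if not (0.0 < self.noise_top_alt_fraction <= 1.0):
            raise ValueError("noise_top_alt_fraction must be in (0, 1]")


@dataclass
class CandidateCall:
    """The screen filter's verdict on one site in one sample."""

    site: SiteBaseCount
    status: str  # low_coverage | no_call | candidate | excluded_noise | known_snp
    top_alt_base: str | None = None
    deviation_fraction: float | None = None
    top_alt_fraction_of_nonref: float | None = None


def call_site(
    site: SiteBaseCount, thresholds: ScreenThresholds | None = None
) -> CandidateCall:
    """Apply the screen filter to one site/sample base tally.

    Every site receives exactly one status. Deletions count toward the
    non-reference deviation and may be the top alternate. Ties between
    equally supported alternates break lexicographically.
    """
    th = thresholds or ScreenThresholds()
    total = site.total
    if total < th.min_reads:
        dev = (total - site.counts[site.ref_base]) / total if total else None
        return CandidateCall(site=site, status="low_coverage", deviation_fraction=dev)

    nonref = total - site.counts[site.ref_base]
    deviation = nonref / total
    if deviation <= th.min_deviation:
        return CandidateCall(site=site, status="no_call", deviation_fraction=deviation)

    alts = [
        (b, site.counts[b]) for b in _ALT_ORDER
        if b != site.ref_base and site.counts[b] > 0
    ]
    top_base, top_count = max(alts, key=lambda bc: (bc[1], ), default=(None, 0))
    # max() keeps the first of equally supported alternates; _ALT_ORDER is
    # lexicographic, so the tie-break is deterministic.
    top_fraction = top_count / nonref if nonref else 0.0
    status = "candidate"
    if len(alts) >= 2 and top_fraction < th.noise_top_alt_fraction:
        status = "excluded_noise"
    return CandidateCall(
        site=site,
        status=status,
        top_alt_base=top_base,
        deviation_fraction=deviation,
        top_alt_fraction_of_nonref=top_fraction,
    )


def partition_known(
    calls: Iterable[CandidateCall],
    known_sites: Mapping[tuple[str, int], set[str] | None],
) -> tuple[list[CandidateCall], list[CandidateCall]]:
    """Split candidate calls into known polymorphisms and the rest.

    ``known_sites`` maps (contig, pos) to an allele set (allele-aware
    matching) or ``None`` (position-only matching, e.g. a BED catalog of
    long deletion/repeat regions). A candidate matching the catalog is
    re-labelled ``known_snp``; every other call passes through unchanged.
    The partition is exhaustive and disjoint.
    """
    known: list[CandidateCall] = []
    rest: list[CandidateCall] = []
    for call in calls:
        matched = False
        if call.status == "candidate":
            alleles = known_sites.get((call.site.contig, call.site.pos), "absent")
            if alleles != "absent":
                matched = alleles is None or call.top_alt_base in alleles
        if matched:
            call.status = "known_snp"
            known.append(call)
        else:
            rest.append(call)
    return known, rest


def coverage_summary(
    counts: Iterable[SiteBaseCount],
    design_sites: Sequence[tuple[str, str, int]],
    samples: Sequence[str],
    thresholds: ScreenThresholds | None = None,
    top_q_percent: float = 5.0,
) -> dict:
    """Coverage bookkeeping over the full site x sample design.

    ``design_sites`` lists (site_id, contig, pos 0-based); every designed
    cell missing from ``counts`` counts as zero reads. Reported are the
    cell count, the fraction of cells reaching ``min_reads``, and the
    share of all reads carried by the top ``top_q_percent`` of sites
    (floor of n_sites * q / 100 sites, at least one).
    """
    th = thresholds or ScreenThresholds()
    pos_to_site = {(contig, pos): site_id for site_id, contig, pos in design_sites}
    sample_set = set(samples)

    cell_totals: dict[tuple[str, str], int] = {}
    site_totals: dict[str, int] = {site_id: 0 for site_id, _, _ in design_sites}
    for c in counts:
        site_id = pos_to_site.get((c.contig, c.pos))
        if site_id is None or c.sample_id not in sample_set:
            continue
        cell_totals[(site_id, c.sample_id)] = (
            cell_totals.get((site_id, c.sample_id), 0) + c.total
        )
        site_totals[site_id] += c.total

    n_sites, n_samples = len(design_sites), len(samples)
    n_cells = n_sites * n_samples
    n_covered = sum(1 for t in cell_totals.values() if t >= th.min_reads)

    totals = np.sort(np.array(list(site_totals.values()), dtype=float))[::-1]
    grand_total = float(totals.sum())
    n_top = max(1, int(n_sites * top_q_percent / 100.0)) if n_sites else 0
    top_share = float(totals[:n_top].sum() / grand_total) if grand_total > 0 else 0.0

    return {
        "n_sites": n_sites,
        "n_samples": n_samples,
        "n_cells": n_cells,
        "n_covered_cells": n_covered,
        "covered_fraction": n_covered / n_cells if n_cells else 0.0,
        "top_q_percent": top_q_percent,
        "n_top_sites": n_top,
        "top_site_read_share": top_share,
        "total_reads": int(grand_total),
    }


def target_gene_union(*gene_sets: Iterable[str]) -> set[str]:
    """Union of the configured target gene sets (e.g. tyrosine kinases,
    validated proto-oncogenes, candidate genes), warning on overlap."""
    union: set[str] = set()
    for i, genes in enumerate(gene_sets):
        genes = set(genes)
        overlap = union & genes
        if overlap:
            logger.warning(
                "target_gene_union: set %d overlaps previous sets: %s",
                i, sorted(overlap),
            )
        union |= genes
    return union
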