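"""Shared fixtures: hand-built transcripts with exact coordinates and an
independent (quadratic) uORF scanner used as the oracle."""

from __future__ import annotations

import pytest

from uorfscan.genome_io import (
    GenomeSequence,
    TranscriptModel,
    complement_base,
    positions_to_blocks,
)
from uorfscan.uorf_discovery import TranscriptLeader

STOPS = {"TAA", "TAG", "TGA"}


def naive_uorf_scan(seq: str) -> list[tuple[int, int | None]]:
    """Brute-force re-implementation of the uORF rule: every ATG fully in
    the leader paired with the closest downstream in-frame stop fully in
    the leader (None when absent). Independent of the package's scanner."""
    out = []
    for i in range(len(seq)):
        if seq[i : i + 3] == "ATG":
            stop = None
            for j in range(i + 3, len(seq) - 2, 3):
                if seq[j : j + 3] in STOPS:
                    stop = j
                    break
            out.append((i, stop))
    return out


def plant_transcript(
    tls: str,
    cds: str,
    strand: str = "+",
    introns: dict[int, int] | None = None,
    utr3: str = "",
    contig: str = "c1",
    pad: int = 25,
    tid: str = "T1",
    gene: str = "G1",
) -> tuple[GenomeSequence, TranscriptModel, list[int]]:
    """Embed one transcript with known spliced sequence into a C-padded
    contig. ``introns`` maps a spliced index to the intron length inserted
    immediately before that base. Returns genome, model and the full
    spliced->genomic coordinate list."""
    spliced = tls + cds + utr3
    introns = dict(introns or {})
    total = len(spliced) + sum(introns.values())
    seq = ["C"] * (pad + total + pad)
    coords: list[int] = []
    if strand == "+":
        g = pad
        for i in range(len(spliced)):
            if i in introns:
                g += introns[i]
            coords.append(g)
            g += 1
    else:
        g = pad + total - 1
        for i in range(len(spliced)):
            if i in introns:
                g -= introns[i]
            coords.append(g)
            g -= 1
    for i, base in enumerate(spliced):
        seq[coords[i]] = base if strand == "+" else complement_base(base)
    genome = GenomeSequence({contig: "".join(seq)})
    exons = positions_to_blocks(coords)
    if strand == "+":
        cds_start = coords[len(tls)]
        cds_end = coords[len(tls) + len(cds) - 1] + 1
    else:
        cds_end = coords[len(tls)] + 1
        cds_start = coords[len(tls) + len(cds) - 1]
    model = TranscriptModel(
        transcript_id=tid,
        gene_symbol=gene,
        contig=contig,
        strand=strand,
        exons=exons,
        cds_start_genomic=cds_start,
        cds_end_genomic=cds_end,
    )
    model.validate()
    return genome, model, coords


def make_leader(seq: str, cds_first_base: str = "G", origin: int = 100,
                tid: str = "L1") -> TranscriptLeader:
    """A plus-strand, intron-free leader with contiguous coordinates."""
    return TranscriptLeader(
        transcript_id=tid,
        gene_symbol=tid,
        contig="cX",
        strand="+",
        sequence=seq,
        coord_map=tuple(range(origin, origin + len(seq))),
        cds_first_base=cds_first_base,
        cds_first_base_genomic=origin + len(seq),
    )


@pytest.fixture
def small_cohort():
    """One modest synthetic study shared by the slower integration tests."""
    from uorfscan.synthetic_data import simulate_cohort

    return simulate_cohort(
        seed=11,
        n_coding=40,
        n_noncoding=8,
        n_start_loss=10,
        n_stop_loss=12,
        n_kozak=2,
        n_background=8,
        mean_depth=150.0,
        depth_sigma=0.5,
    )
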