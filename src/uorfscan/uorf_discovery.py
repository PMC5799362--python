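"""Genome-wide discovery of upstream open reading frames (uORFs).

For every coding transcript the spliced transcript leader sequence (TLS,
the 5' UTR) is extracted with a bidirectional spliced<->genomic coordinate
map. Every AUG fully inside the TLS opens a uORF; its closest in-frame
stop codon (TAA/TAG/TGA) fully inside the TLS terminates it. A uAUG with
no in-frame stop before the CDS is kept but flagged CDS-overlapping, and
its (downstream) stop is excluded from the uStop catalog. The Kozak
context around each uAUG is classified from the two core positions -3 and
+4 of the optimal context GCCGCCAUGR: two matches = strong, one =
intermediate, none = weak.

Discovery is fully deterministic: leaders are scanned 5'->3' and the
"closest stop" rule has no ties by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genome_io import (
    BedFeature,
    GenomeSequence,
    TranscriptModel,
    positions_to_blocks,
    read_bed,
    write_bed,
)

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
PURINES = frozenset({"A", "G"})

#: Kozak window positions relative to the A of the AUG (the +4 position is
#: the first base after the AUG on the spliced transcript).
KOZAK_UPSTREAM_RELS = (-6, -5, -4, -3, -2, -1)
KOZAK_RELS = KOZAK_UPSTREAM_RELS + (4,)


class ModelInconsistencyError(ValueError):
    """Transcript annotation contradicts itself (e.g. CDS start outside exons)."""


# ---------------------------------------------------------------------------
# Kozak


@dataclass(frozen=True)
class KozakPolicy:
    """How the two core Kozak positions are matched.

    ``purine`` accepts A or G (the R of GCCGCCAUGR); ``exact-G`` requires G.
    """

    match_rule_minus3: str = "purine"
    match_rule_plus4: str = "purine"

    def __post_init__(self) -> None:
        for rule in (self.match_rule_minus3, self.match_rule_plus4):
            if rule not in ("purine", "exact-G"):
                raise ValueError(f"unknown Kozak match rule {rule!r}")

    def matches(self, rel: int, base: str) -> bool | None:
        """True/False for a core match; None when the base is unavailable."""
        base = base.upper()
        if base not in "ACGT":
            return None
        rule = self.match_rule_minus3 if rel == -3 else self.match_rule_plus4
        return base in PURINES if rule == "purine" else base == "G"

    def describe(self) -> str:
        return f"minus3={self.match_rule_minus3},plus4={self.match_rule_plus4}"


@dataclass(frozen=True)
class KozakContext:
    """Window covering -6..-1, the AUG, and +4; core-match count; strength.

    The window is printed with upstream context in lowercase except the
    core -3 base, and the AUG and +4 base in uppercase (unavailable
    positions are '.'), e.g. ``gccGccATGG``.
    """

    window: str
    core_matches: int
    strength: str  # strong | intermediate | weak | undetermined


def _strength_from_cores(minus3: bool | None, plus4: bool | None) -> tuple[int, str]:
    if minus3 is None or plus4 is None:
        return (int(bool(minus3)) + int(bool(plus4)), "undetermined")
    n = int(minus3) + int(plus4)
    return n, {2: "strong", 1: "intermediate", 0: "weak"}[n]


def format_kozak_window(chars: Sequence[str]) -> str:
    """Format the 7 context characters (-6..-1, +4) plus the AUG."""
    up = [c.upper() if c != "." else "." for c in chars]
    low = [c.lower() if c != "." else "." for c in chars]
    return "".join(low[0:3]) + up[3] + "".join(low[4:6]) + "ATG" + up[6]


def kozak_strength_of_window(window: str, policy: KozakPolicy) -> tuple[int, str]:
    """Core-match count and strength from a formatted 10-character window."""
    minus3 = policy.matches(-3, window[3])
    plus4 = policy.matches(4, window[9])
    return _strength_from_cores(minus3, plus4)


# ---------------------------------------------------------------------------
# Transcript leader


@dataclass
class TranscriptLeader:
    """Spliced TLS in transcript orientation plus its genomic coordinate map.

    ``coord_map[i]`` is the genomic position of spliced base ``i``; it is
    strictly monotone within each exon block (increasing on +, decreasing
    on -). ``cds_first_base`` is the first CDS base on the transcript
    strand — the +4 Kozak position of a uAUG that abuts the CDS.
    """

    transcript_id: str
    gene_symbol: str
    contig: str
    strand: str
    sequence: str
    coord_map: tuple[int, ...]
    cds_first_base: str
    cds_first_base_genomic: int | None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.coord_map):
            raise ValueError(
                f"{self.transcript_id}: sequence and coord_map lengths differ"
            )
        self._spliced_of: dict[int, int] | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    def genomic_of(self, i: int) -> int:
        return self.coord_map[i]

    def spliced_of(self, genomic_pos: int) -> int:
        if self._spliced_of is None:
            self._spliced_of = {g: i for i, g in enumerate(self.coord_map)}
        return self._spliced_of[genomic_pos]

    def genomic_blocks(self, start: int, end: int) -> list[tuple[int, int]]:
        """Project the spliced interval ``[start, end)`` to sorted genomic
        half-open blocks."""
        return positions_to_blocks(self.coord_map[start:end])


def extract_leader(model: TranscriptModel, genome: GenomeSequence) -> TranscriptLeader:
    """Extract the spliced TLS of a coding transcript, intronic sequence
    excluded, in transcript orientation. An empty TLS is legal."""
    if not model.is_coding:
        raise ModelInconsistencyError(f"{model.transcript_id}: non-coding transcript")

    if model.strand == "+":
        cds_first = model.cds_start_genomic
        if not any(s <= cds_first < e for s, e in model.exons):
            raise ModelInconsistencyError(
                f"{model.transcript_id}: CDS start not covered by any exon"
            )
        pieces = []
        coords: list[int] = []
        for s, e in model.exons:
            lo, hi = s, min(e, cds_first)
            if lo < hi:
                pieces.append(genome.fetch(model.contig, lo, hi))
                coords.extend(range(lo, hi))
        sequence = "".join(pieces)
        cds_base = genome.base(model.contig, cds_first)
        cds_base_genomic = cds_first
    else:
        cds_first = model.cds_end_genomic - 1  # first CDS base on - strand
        if not any(s <= cds_first < e for s, e in model.exons):
            raise ModelInconsistencyError(
                f"{model.transcript_id}: CDS start not covered by any exon"
            )
        plus_pieces = []
        plus_coords: list[int] = []
        boundary = model.cds_end_genomic
        for s, e in model.exons:
            lo, hi = max(s, boundary), e
            if lo < hi:
                plus_pieces.append(genome.fetch(model.contig, lo, hi))
                plus_coords.extend(range(lo, hi))
        from .genome_io import reverse_complement

        sequence = reverse_complement("".join(plus_pieces))
        coords = plus_coords[::-1]
        cds_base = genome.base(model.contig, cds_first, strand="-")
        cds_base_genomic = cds_first

    return TranscriptLeader(
        transcript_id=model.transcript_id,
        gene_symbol=model.gene_symbol,
        contig=model.contig,
        strand=model.strand,
        sequence=sequence,
        coord_map=tuple(coords),
        cds_first_base=cds_base,
        cds_first_base_genomic=cds_base_genomic,
    )


def filter_coding(models: Iterable[TranscriptModel]) -> list[TranscriptModel]:
    """Keep transcripts with an annotated CDS, preserving order."""
    models = list(models)
    kept = [m for m in models if m.is_coding]
    removed = len(models) - len(kept)
    if removed:
        logger.info("filter_coding: removed %d non-coding transcripts", removed)
    if not kept and models:
        logger.warning("filter_coding: no coding transcripts remain")
    return kept


# ---------------------------------------------------------------------------
# uORFs


@dataclass
class UORF:
    """One discovered uORF on one transcript isoform."""

    transcript_id: str
    gene_symbol: str
    contig: str
    strand: str
    uaug_offset: int
    ustop_offset: int | None
    cds_overlapping: bool
    length_nt: int | None
    stop_codon: str | None
    start_positions: tuple[int, ...]  # genomic pos of the 3 AUG bases, tx order
    stop_positions: tuple[int, ...] | None
    start_blocks: tuple[tuple[int, int], ...]
    stop_blocks: tuple[tuple[int, int], ...] | None
    span_blocks: tuple[tuple[int, int], ...]
    kozak: KozakContext
    kozak_genomic: dict[int, int]  # Kozak rel position -> genomic position
    shared_stop_group: str | None

    @property
    def uaug_key(self) -> tuple[str, str, tuple[tuple[int, int], ...]]:
        return (self.contig, self.strand, self.start_blocks)

    @property
    def ustop_key(self) -> tuple[str, str, tuple[tuple[int, int], ...]] | None:
        if self.stop_blocks is None:
            return None
        return (self.contig, self.strand, self.stop_blocks)


def kozak_context(
    leader: TranscriptLeader, uaug_offset: int, policy: KozakPolicy | None = None
) -> KozakContext:
    """Classify the Kozak context of the AUG at ``uaug_offset``.

    The window is assembled on the spliced transcript (splice junctions are
    invisible); the +4 base is the next spliced base after the AUG — a TLS
    base for internal uAUGs, the first CDS base when the AUG abuts the CDS.
    Positions upstream of the transcript 5' end are '.' and make the
    strength undetermined, as does an N at a core position.
    """
    policy = policy or KozakPolicy()
    seq = leader.sequence
    if seq[uaug_offset : uaug_offset + 3] != "ATG":
        raise ValueError(f"{leader.transcript_id}: no ATG at offset {uaug_offset}")
    chars = []
    for rel in KOZAK_UPSTREAM_RELS:
        idx = uaug_offset + rel
        chars.append(seq[idx] if idx >= 0 else ".")
    plus4_idx = uaug_offset + 3
    chars.append(seq[plus4_idx] if plus4_idx < len(seq) else leader.cds_first_base)
    window = format_kozak_window(chars)
    core_matches, strength = kozak_strength_of_window(window, policy)
    return KozakContext(window=window, core_matches=core_matches, strength=strength)


def _kozak_genomic_positions(leader: TranscriptLeader, uaug_offset: int) -> dict[int, int]:
    out: dict[int, int] = {}
    for rel in KOZAK_UPSTREAM_RELS:
        idx = uaug_offset + rel
        if idx >= 0:
            out[rel] = leader.coord_map[idx]
    plus4_idx = uaug_offset + 3
    if plus4_idx < len(leader):
        out[4] = leader.coord_map[plus4_idx]
    elif leader.cds_first_base_genomic is not None:
        out[4] = leader.cds_first_base_genomic
    return out


def scan_uorfs(
    leader: TranscriptLeader, policy: KozakPolicy | None = None
) -> list[UORF]:
    """Find every uORF in a transcript leader, scanning 5'->3'.

    Each AUG fully inside the TLS is paired with the closest downstream
    in-frame stop fully inside the TLS; AUGs without one are flagged
    CDS-overlapping. Codons containing N never match as start or stop.
    """
    policy = policy or KozakPolicy()
    seq = leader.sequence
    n = len(seq)
    uorfs: list[UORF] = []
    for i in range(0, n - 2):
        if seq[i : i + 3] != "ATG":
            continue
        ustop = None
        j = i + 3
        while j + 3 <= n:
            codon = seq[j : j + 3]
            if codon in STOP_CODONS:
                ustop = j
                break
            j += 3
        kz = kozak_context(leader, i, policy)
        kz_genomic = _kozak_genomic_positions(leader, i)
        start_positions = tuple(leader.coord_map[i : i + 3])
        start_blocks = tuple(leader.genomic_blocks(i, i + 3))
        if ustop is None:
            uorfs.append(
                UORF(
                    transcript_id=leader.transcript_id,
                    gene_symbol=leader.gene_symbol,
                    contig=leader.contig,
                    strand=leader.strand,
                    uaug_offset=i,
                    ustop_offset=None,
                    cds_overlapping=True,
                    length_nt=None,
                    stop_codon=None,
                    start_positions=start_positions,
                    stop_positions=None,
                    start_blocks=start_blocks,
                    stop_blocks=None,
                    span_blocks=tuple(leader.genomic_blocks(i, n)),
                    kozak=kz,
                    kozak_genomic=kz_genomic,
                    shared_stop_group=None,
                )
            )
        else:
            uorfs.append(
                UORF(
                    transcript_id=leader.transcript_id,
                    gene_symbol=leader.gene_symbol,
                    contig=leader.contig,
                    strand=leader.strand,
                    uaug_offset=i,
                    ustop_offset=ustop,
                    cds_overlapping=False,
                    length_nt=ustop + 3 - i,
                    stop_codon=seq[ustop : ustop + 3],
                    start_positions=start_positions,
                    stop_positions=tuple(leader.coord_map[ustop : ustop + 3]),
                    start_blocks=start_blocks,
                    stop_blocks=tuple(leader.genomic_blocks(ustop, ustop + 3)),
                    span_blocks=tuple(leader.genomic_blocks(i, ustop + 3)),
                    kozak=kz,
                    kozak_genomic=kz_genomic,
                    shared_stop_group=None,
                )
            )
    # uORFs sharing one termination codon form a group
    by_stop: dict[int, list[int]] = {}
    for k, u in enumerate(uorfs):
        if u.ustop_offset is not None:
            by_stop.setdefault(u.ustop_offset, []).append(k)
    for stop_off, members in by_stop.items():
        group = f"{leader.transcript_id}:stop@{stop_off}"
        for k in members:
            uorfs[k].shared_stop_group = group
    return uorfs


# ---------------------------------------------------------------------------
# Catalog


@dataclass
class CatalogHit:
    """A genomic position's membership in one uORF element of one isoform."""

    record: UORF
    element: str  # uAUG | uStop | uKozak
    codon_index: int | None = None  # 0..2 along the transcript strand
    kozak_rel: int | None = None


class UORFCatalog:
    """All discovered uORFs plus unique uAUG/uStop genomic codon sets.

    ``dedupe='by-genomic-position'`` collapses identical codons shared by
    isoforms (the genome-wide counting mode); ``'per-transcript'`` keeps
    one entry per isoform (the screen's bookkeeping mode).
    """

    def __init__(
        self,
        records: Sequence[UORF],
        policy: KozakPolicy | None = None,
        dedupe: str = "by-genomic-position",
    ) -> None:
        if dedupe not in ("by-genomic-position", "per-transcript"):
            raise ValueError(f"unknown dedupe mode {dedupe!r}")
        self.records = list(records)
        self.policy = policy or KozakPolicy()
        self.dedupe = dedupe

    @property
    def contigs(self) -> set[str]:
        return {r.contig for r in self.records}

    def unique_uaug_keys(self) -> set[tuple]:
        return {r.uaug_key for r in self.records}

    def unique_ustop_keys(self) -> set[tuple]:
        return {r.ustop_key for r in self.records if r.ustop_key is not None}

    def n_uaug(self) -> int:
        if self.dedupe == "per-transcript":
            return len(self.records)
        return len(self.unique_uaug_keys())

    def n_ustop(self) -> int:
        if self.dedupe == "per-transcript":
            return len({(r.transcript_id, r.ustop_offset)
                        for r in self.records if r.ustop_offset is not None})
        return len(self.unique_ustop_keys())

    def position_index(
        self, kozak_window: bool = False
    ) -> dict[tuple[str, int], list[CatalogHit]]:
        """Map (contig, genomic position) -> catalog hits at that base."""
        index: dict[tuple[str, int], list[CatalogHit]] = {}
        for r in self.records:
            for k, g in enumerate(r.start_positions):
                index.setdefault((r.contig, g), []).append(
                    CatalogHit(record=r, element="uAUG", codon_index=k)
                )
            if r.stop_positions is not None:
                for k, g in enumerate(r.stop_positions):
                    index.setdefault((r.contig, g), []).append(
                        CatalogHit(record=r, element="uStop", codon_index=k)
                    )
            if kozak_window:
                for rel, g in r.kozak_genomic.items():
                    index.setdefault((r.contig, g), []).append(
                        CatalogHit(record=r, element="uKozak", kozak_rel=rel)
                    )
        return index

    # -- serialization ------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "transcript_id": r.transcript_id,
                    "gene": r.gene_symbol,
                    "contig": r.contig,
                    "strand": r.strand,
                    "uaug_offset": r.uaug_offset,
                    "ustop_offset": "" if r.ustop_offset is None else r.ustop_offset,
                    "cds_overlapping": r.cds_overlapping,
                    "length_nt": "" if r.length_nt is None else r.length_nt,
                    "stop_codon": r.stop_codon or "",
                    "kozak_window": r.kozak.window,
                    "kozak_core_matches": r.kozak.core_matches,
                    "kozak_strength": r.kozak.strength,
                    "shared_stop_group": r.shared_stop_group or "",
                    "start_positions": ";".join(map(str, r.start_positions)),
                    "stop_positions": ";".join(map(str, r.stop_positions or ())),
                    "kozak_genomic": "|".join(
                        f"{rel}:{g}" for rel, g in sorted(r.kozak_genomic.items())
                    ),
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"#{line}\n")
            self.to_dataframe().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, policy: KozakPolicy | None = None,
                 dedupe: str = "by-genomic-position") -> "UORFCatalog":
        df = pd.read_csv(path, sep="\t", comment="#",
                         dtype={"contig": str}, keep_default_na=False)
        records = []
        for row in df.itertuples(index=False):
            start_positions = tuple(int(x) for x in str(row.start_positions).split(";"))
            stop_positions = (
                tuple(int(x) for x in str(row.stop_positions).split(";"))
                if str(row.stop_positions) else None
            )
            kozak_genomic = {}
            if str(row.kozak_genomic):
                for item in str(row.kozak_genomic).split("|"):
                    rel, g = item.split(":")
                    kozak_genomic[int(rel)] = int(g)
            ustop_offset = int(row.ustop_offset) if str(row.ustop_offset) else None
            uaug_offset = int(row.uaug_offset)
            span_end = (
                stop_positions if stop_positions is not None else start_positions
            )
            records.append(
                UORF(
                    transcript_id=row.transcript_id,
                    gene_symbol=row.gene,
                    contig=row.contig,
                    strand=row.strand,
                    uaug_offset=uaug_offset,
                    ustop_offset=ustop_offset,
                    cds_overlapping=bool(row.cds_overlapping),
                    length_nt=int(row.length_nt) if str(row.length_nt) else None,
                    stop_codon=row.stop_codon or None,
                    start_positions=start_positions,
                    stop_positions=stop_positions,
                    start_blocks=tuple(positions_to_blocks(start_positions)),
                    stop_blocks=(
                        tuple(positions_to_blocks(stop_positions))
                        if stop_positions is not None else None
                    ),
                    span_blocks=(),  # full span not serialized per-base
                    kozak=KozakContext(
                        window=row.kozak_window,
                        core_matches=int(row.kozak_core_matches),
                        strength=row.kozak_strength,
                    ),
                    kozak_genomic=kozak_genomic,
                    shared_stop_group=row.shared_stop_group or None,
                )
            )
        return cls(records, policy=policy, dedupe=dedupe)

    # -- BED output ---------------------------------------------------------

    def uaug_bed_features(self) -> list[BedFeature]:
        seen = set()
        feats = []
        for r in self.records:
            key = r.uaug_key
            if self.dedupe == "by-genomic-position" and key in seen:
                continue
            seen.add(key)
            feats.append(
                BedFeature(
                    contig=r.contig,
                    name=f"{r.transcript_id}|uAUG|{r.uaug_offset}",
                    strand=r.strand,
                    blocks=list(r.start_blocks),
                )
            )
        return feats

    def ustop_bed_features(self) -> list[BedFeature]:
        seen = set()
        feats = []
        for r in self.records:
            key = r.ustop_key
            if key is None:
                continue
            if self.dedupe == "by-genomic-position" and key in seen:
                continue
            seen.add(key)
            feats.append(
                BedFeature(
                    contig=r.contig,
                    name=f"{r.transcript_id}|uStop|{r.ustop_offset}",
                    strand=r.strand,
                    blocks=list(r.stop_blocks),
                )
            )
        return feats

    def uorf_bed_features(self) -> list[BedFeature]:
        feats = []
        for r in self.records:
            feats.append(
                BedFeature(
                    contig=r.contig,
                    name=f"{r.transcript_id}|uORF|{r.uaug_offset}",
                    strand=r.strand,
                    blocks=list(r.span_blocks),
                )
            )
        return feats

    def write_bed(self, prefix: str | Path, header_lines: Sequence[str] = ()) -> None:
        prefix = str(prefix)
        write_bed(self.uorf_bed_features(), prefix + ".uorfs.bed",
                  flavor="bed12-uorfs", header_lines=header_lines)
        write_bed(self.uaug_bed_features(), prefix + ".uaug.bed",
                  flavor="bed6-codons", header_lines=header_lines)
        write_bed(self.ustop_bed_features(), prefix + ".ustop.bed",
                  flavor="bed6-codons", header_lines=header_lines)


def codon_keys_from_bed(path: str | Path) -> set[tuple]:
    """Unique (contig, strand, blocks) codon keys from a BED file written by
    :meth:`UORFCatalog.write_bed` — used to round-trip codon sets."""
    return {
        (f.contig, f.strand, tuple(f.blocks)) for f in read_bed(path)
    }


def annotate_genome(
    models: Iterable[TranscriptModel],
    genome: GenomeSequence,
    policy: KozakPolicy | None = None,
    dedupe: str = "by-genomic-position",
) -> UORFCatalog:
    """Run the full discovery over a transcript set: keep coding models,
    extract each leader, scan for uORFs and assemble the catalog."""
    policy = policy or KozakPolicy()
    records: list[UORF] = []
    for model in filter_coding(models):
        leader = extract_leader(model, genome)
        records.extend(scan_uorfs(leader, policy))
    catalog = UORFCatalog(records, policy=policy, dedupe=dedupe)
    logger.info(
        "annotate_genome: %d uORFs, %d unique uAUG codons, %d unique uStop codons",
        len(records), len(catalog.unique_uaug_keys()), len(catalog.unique_ustop_keys()),
    )
    return catalog
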