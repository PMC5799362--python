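"""Readers and writers for the standard formats the pipeline touches.

Covers FASTA genomes, UCSC refGene-style transcript tables, BED6/BED12
feature output, VCF variant input/output and per-site base-count tables.

Coordinate conventions
----------------------
All *internal* coordinates are 0-based, half-open, exactly as in BED.
Conversion to and from 1-based conventions happens only at the VCF and
base-count-file boundaries and nowhere else.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Characters accepted in genome sequence after uppercasing.
VALID_BASES = frozenset("ACGTN")

BASE_COUNT_COLUMNS = ("sample", "contig", "pos", "ref", "A", "C", "G", "T", "DEL")

REFGENE_COLUMNS = (
    "name", "chrom", "strand", "txStart", "txEnd", "cdsStart", "cdsEnd",
    "exonCount", "exonStarts", "exonEnds", "score", "name2",
    "cdsStartStat", "cdsEndStat", "exonFrames",
)


class FormatError(ValueError):
    """A file violates the expected on-disk format."""


class FastaFormatError(FormatError):
    pass


class TableFormatError(FormatError):
    pass


class RangeError(ValueError):
    """A requested interval falls outside the contig it addresses."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def positions_to_blocks(positions: Sequence[int]) -> list[tuple[int, int]]:
    """Collapse per-base genomic positions (transcript order, ascending or
    descending within exon runs) into sorted, half-open genomic intervals.

    Consecutive runs (step +1 or -1) become one block; the result is sorted
    by genomic start, which is the BED block convention.
    """
    if len(positions) == 0:
        return []
    blocks: list[tuple[int, int]] = []
    run_start = prev = positions[0]
    direction = 0
    for p in positions[1:]:
        step = p - prev
        if step in (1, -1) and (direction == 0 or step == direction):
            direction = step
            prev = p
            continue
        blocks.append((min(run_start, prev), max(run_start, prev) + 1))
        run_start = prev = p
        direction = 0
    blocks.append((min(run_start, prev), max(run_start, prev) + 1))
    return sorted(blocks)


# ---------------------------------------------------------------------------
# Genome sequence


@dataclass
class GenomeSequence:
    """An in-memory genome: contig name -> uppercase DNA string over ACGTN."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        normalized = {}
        for name, seq in self.contigs.items():
            seq = seq.upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise FastaFormatError(
                    f"contig {name!r}: invalid characters {sorted(bad)}"
                )
            normalized[name] = seq
        self.contigs = normalized

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of ``[start, end)`` on *contig*; reverse complemented when
        ``strand == '-'``."""
        if contig not in self.contigs:
            raise KeyError(f"unknown contig {contig!r}")
        seq = self.contigs[contig]
        if not (0 <= start <= end <= len(seq)):
            raise RangeError(
                f"interval [{start}, {end}) outside contig {contig!r} "
                f"of length {len(seq)}"
            )
        sub = seq[start:end]
        return reverse_complement(sub) if strand == "-" else sub

    def base(self, contig: str, pos: int, strand: str = "+") -> str:
        return self.fetch(contig, pos, pos + 1, strand)


def read_fasta(path: str | Path) -> GenomeSequence:
    """Parse a FASTA file into a :class:`GenomeSequence`.

    Sequence is uppercased (soft-masked lowercase is preserved as uppercase).
    Duplicate headers and non-IUPAC characters are rejected with the
    offending line number.
    """
    contigs: dict[str, list[str]] = {}
    current: list[str] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise FastaFormatError(f"{path}: line {lineno}: empty FASTA header")
                if name in contigs:
                    raise FastaFormatError(
                        f"{path}: line {lineno}: duplicate contig {name!r}"
                    )
                current = contigs.setdefault(name, [])
            else:
                if current is None:
                    raise FastaFormatError(
                        f"{path}: line {lineno}: sequence before first header"
                    )
                chunk = line.upper()
                bad = set(chunk) - VALID_BASES
                if bad:
                    raise FastaFormatError(
                        f"{path}: line {lineno}: invalid characters {sorted(bad)}"
                    )
                current.append(chunk)
    return GenomeSequence({name: "".join(parts) for name, parts in contigs.items()})


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Transcript models (refGene table)


@dataclass
class TranscriptModel:
    """One transcript's exon structure, strand and CDS span, genomic coords.

    ``cds_start_genomic == cds_end_genomic`` marks a non-coding transcript.
    Exons are 0-based half-open genomic intervals in ascending genomic order
    regardless of strand, as in the UCSC tables.
    """

    transcript_id: str
    gene_symbol: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start_genomic: int
    cds_end_genomic: int

    @property
    def is_coding(self) -> bool:
        return self.cds_start_genomic < self.cds_end_genomic

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        for (s1, e1), (s2, e2) in itertools.pairwise(self.exons):
            if not (s1 < e1 <= s2 < e2):
                raise ValueError(
                    f"{self.transcript_id}: exons not sorted/non-overlapping"
                )
        if self.exons[-1][0] >= self.exons[-1][1]:
            raise ValueError(f"{self.transcript_id}: empty exon")
        if self.cds_start_genomic > self.cds_end_genomic:
            raise ValueError(f"{self.transcript_id}: cdsStart > cdsEnd")
        if self.is_coding:
            for bound in (self.cds_start_genomic, self.cds_end_genomic - 1):
                if not any(s <= bound < e for s, e in self.exons):
                    raise ValueError(
                        f"{self.transcript_id}: CDS boundary {bound} outside exons"
                    )


def _parse_exon_list(text: str) -> list[int]:
    return [int(x) for x in text.strip().rstrip(",").split(",") if x != ""]


def parse_transcript_table(
    path: str | Path, dialect: str = "auto"
) -> list[TranscriptModel]:
    """Parse a UCSC refGene-style tab table into :class:`TranscriptModel`s.

    ``dialect`` is ``refgene-with-bin`` (16 columns, leading ``bin``),
    ``refgene-no-bin`` (15 columns) or ``auto`` (detected from the column
    count). Minus-strand transcripts keep genomic-ascending exon order.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    ncols = df.shape[1]
    if dialect == "auto":
        if ncols >= 16:
            dialect = "refgene-with-bin"
        elif ncols == 15:
            dialect = "refgene-no-bin"
        else:
            raise TableFormatError(
                f"{path}: {ncols} columns; expected 15 (no bin) or 16 (with bin)"
            )
    offset = 1 if dialect == "refgene-with-bin" else 0
    if ncols < offset + 11:
        raise TableFormatError(f"{path}: too few columns ({ncols}) for {dialect}")

    models = []
    for idx, row in enumerate(df.itertuples(index=False)):
        vals = list(row)
        try:
            name = vals[offset + 0]
            chrom = vals[offset + 1]
            strand = vals[offset + 2]
            cds_start = int(vals[offset + 5])
            cds_end = int(vals[offset + 6])
            exon_count = int(vals[offset + 7])
            starts = _parse_exon_list(vals[offset + 8])
            ends = _parse_exon_list(vals[offset + 9])
            name2 = vals[offset + 11] if ncols > offset + 11 else name
        except (TypeError, ValueError) as exc:
            raise TableFormatError(f"{path}: row {idx}: {exc}") from exc
        if len(starts) != exon_count or len(ends) != exon_count:
            raise TableFormatError(
                f"{path}: row {idx}: exonCount {exon_count} does not match "
                f"exonStarts/exonEnds lengths {len(starts)}/{len(ends)}"
            )
        if cds_start > cds_end:
            raise TableFormatError(f"{path}: row {idx}: cdsStart > cdsEnd")
        model = TranscriptModel(
            transcript_id=name,
            gene_symbol=name2 if isinstance(name2, str) else name,
            contig=chrom,
            strand=strand,
            exons=list(zip(starts, ends)),
            cds_start_genomic=cds_start,
            cds_end_genomic=cds_end,
        )
        try:
            model.validate()
        except ValueError as exc:
            raise TableFormatError(f"{path}: row {idx}: {exc}") from exc
        models.append(model)
    return models


def write_transcript_table(
    models: Iterable[TranscriptModel],
    path: str | Path,
    dialect: str = "refgene-no-bin",
    header_lines: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"#{line}\n")
        for m in models:
            starts = ",".join(str(s) for s, _ in m.exons) + ","
            ends = ",".join(str(e) for _, e in m.exons) + ","
            frames = ",".join("-1" for _ in m.exons) + ","
            fields = [
                m.transcript_id, m.contig, m.strand,
                str(m.tx_start), str(m.tx_end),
                str(m.cds_start_genomic), str(m.cds_end_genomic),
                str(len(m.exons)), starts, ends,
                "0", m.gene_symbol, "unk", "unk", frames,
            ]
            if dialect == "refgene-with-bin":
                fields.insert(0, "0")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# BED


@dataclass
class BedFeature:
    """A (possibly multi-block) feature on one contig, BED coordinates."""

    contig: str
    name: str
    strand: str
    blocks: list[tuple[int, int]]
    score: int = 0

    @property
    def chrom_start(self) -> int:
        return self.blocks[0][0]

    @property
    def chrom_end(self) -> int:
        return self.blocks[-1][1]

    def validate(self) -> None:
        if not self.blocks:
            raise ValueError(f"{self.name}: no blocks")
        for (s1, e1), (s2, e2) in itertools.pairwise(self.blocks):
            if not (s1 < e1 <= s2 < e2):
                raise ValueError(f"{self.name}: blocks not sorted/non-overlapping")
        if self.blocks[-1][0] >= self.blocks[-1][1]:
            raise ValueError(f"{self.name}: empty block")


def write_bed(
    features: Iterable[BedFeature],
    path: str | Path,
    flavor: str = "bed12-uorfs",
    genome: GenomeSequence | None = None,
    header_lines: Sequence[str] = (),
) -> None:
    """Write features as BED.

    ``bed12-uorfs`` always emits 12 columns. ``bed6-codons`` emits 6 columns
    for single-block records; codons split across an intron fall back to
    BED12 so their block structure is preserved.
    """
    if flavor not in ("bed6-codons", "bed12-uorfs"):
        raise ValueError(f"unknown BED flavor {flavor!r}")
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"#{line}\n")
        for f in features:
            f.validate()
            if genome is not None:
                if f.contig not in genome:
                    raise RangeError(f"{f.name}: unknown contig {f.contig!r}")
                if f.chrom_end > genome.length(f.contig) or f.chrom_start < 0:
                    raise RangeError(f"{f.name}: block outside contig {f.contig!r}")
            base = [f.contig, str(f.chrom_start), str(f.chrom_end), f.name,
                    str(f.score), f.strand]
            if flavor == "bed6-codons" and len(f.blocks) == 1:
                fh.write("\t".join(base) + "\n")
            else:
                sizes = ",".join(str(e - s) for s, e in f.blocks) + ","
                starts = ",".join(str(s - f.chrom_start) for s, e in f.blocks) + ","
                fh.write("\t".join(base + [
                    str(f.chrom_start), str(f.chrom_end), "0",
                    str(len(f.blocks)), sizes, starts,
                ]) + "\n")


def read_bed(path: str | Path) -> list[BedFeature]:
    """Read BED6/BED12 lines back into :class:`BedFeature` records."""
    feats = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}: line {lineno}: fewer than 6 BED columns")
            contig, start, end, name, score, strand = parts[:6]
            start, end = int(start), int(end)
            if len(parts) >= 12:
                sizes = _parse_exon_list(parts[10])
                offsets = _parse_exon_list(parts[11])
                blocks = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            else:
                blocks = [(start, end)]
            feats.append(BedFeature(contig, name, strand, blocks, int(float(score))))
    return feats


# ---------------------------------------------------------------------------
# Variants (VCF)


@dataclass
class VariantRecord:
    """One alternate allele at one site, alleles on the genomic plus strand.

    ``pos`` is internal 0-based. Records wider than one base on either
    allele are accepted but flagged complex; downstream consequence calls
    report them as ``complex`` rather than silently dropping them.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    sample_pair_id: str = ""
    caller_id: str = ""
    callers: tuple[str, ...] = ()

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_complex(self) -> bool:
        return not self.is_snv

    def key(self) -> tuple[str, int, str, str, str]:
        return (self.contig, self.pos, self.ref, self.alt, self.sample_pair_id)


def read_vcf(
    path: str | Path,
    sample_pair_id: str | None = None,
    caller_id: str = "",
) -> list[VariantRecord]:
    """Read a VCF into :class:`VariantRecord`s.

    Positions are converted 1-based -> internal 0-based and multi-allelic
    records are split into one record per alternate allele. A sample-pair
    id may come from the ``SP`` INFO field or be supplied explicitly.
    """
    from cyvcf2 import VCF

    records = []
    vcf = VCF(str(path))
    try:
        for v in vcf:
            sp = sample_pair_id
            if sp is None:
                info_sp = v.INFO.get("SP")
                sp = str(info_sp) if info_sp is not None else ""
            for alt in v.ALT:
                records.append(
                    VariantRecord(
                        contig=v.CHROM,
                        pos=v.start,
                        ref=v.REF,
                        alt=alt,
                        sample_pair_id=sp,
                        caller_id=caller_id,
                    )
                )
    finally:
        vcf.close()
    return records


def write_vcf(
    records: Iterable[VariantRecord],
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
    header_lines: Sequence[str] = (),
) -> None:
    """Write a minimal, valid VCF 4.2 file (plus-strand alleles, 1-based).

    The sample-pair id travels in the ``SP`` INFO field so that a single
    file can hold a cohort.
    """
    recs = sorted(records, key=lambda r: (r.contig, r.pos, r.alt))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for line in header_lines:
            fh.write(f"##{line}\n")
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=SP,Number=1,Type=String,Description="Sample pair id">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in recs:
            info = f"SP={r.sample_pair_id}" if r.sample_pair_id else "."
            fh.write(
                f"{r.contig}\t{r.pos + 1}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}\n"
            )


def read_known_sites(path: str | Path) -> dict[tuple[str, int], set[str] | None]:
    """Load a known-polymorphism catalog from VCF (allele-aware) or BED
    (position-only; the allele set is ``None``, meaning "any allele")."""
    path = Path(path)
    known: dict[tuple[str, int], set[str] | None] = {}
    if path.suffix.lower() in (".vcf",):
        for rec in read_vcf(path):
            alts = known.setdefault((rec.contig, rec.pos), set())
            if alts is not None:
                alts.add(rec.alt)
    else:
        for feat in read_bed(path):
            for s, e in feat.blocks:
                for pos in range(s, e):
                    known[(feat.contig, pos)] = None
    return known


# ---------------------------------------------------------------------------
# Base counts


@dataclass
class SiteBaseCount:
    """Per-site, per-sample base tallies from the amplicon pileup."""

    sample_id: str
    contig: str
    pos: int  # internal 0-based
    ref_base: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.ref_base not in "ACGT":
            raise ValueError(
                f"{self.sample_id} {self.contig}:{self.pos}: "
                f"ref base {self.ref_base!r} not in A/C/G/T"
            )
        for base in ("A", "C", "G", "T", "DEL"):
            self.counts.setdefault(base, 0)
            if self.counts[base] < 0:
                raise ValueError(
                    f"{self.sample_id} {self.contig}:{self.pos}: negative count"
                )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def nonref_total(self) -> int:
        return self.total - self.counts[self.ref_base]


def read_base_counts(path: str | Path) -> list[SiteBaseCount]:
    """Read the base-count TSV. Positions are 1-based in the file and
    converted to internal 0-based."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample": str, "contig": str})
    missing = set(BASE_COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    sites = []
    for row in df.itertuples(index=False):
        sites.append(
            SiteBaseCount(
                sample_id=row.sample,
                contig=row.contig,
                pos=int(row.pos) - 1,
                ref_base=str(row.ref),
                counts={b: int(getattr(row, b)) for b in ("A", "C", "G", "T", "DEL")},
            )
        )
    return sites


def write_base_counts(
    sites: Iterable[SiteBaseCount],
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"#{line}\n")
        fh.write("\t".join(BASE_COUNT_COLUMNS) + "\n")
        for s in sites:
            fh.write(
                "\t".join(
                    [s.sample_id, s.contig, str(s.pos + 1), s.ref_base]
                    + [str(s.counts[b]) for b in ("A", "C", "G", "T", "DEL")]
                )
                + "\n"
            )
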