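"""Seeded generators for every input the pipeline consumes.

The generator emulates the study data the pipeline was built for: a small
genome carrying multi-exon transcripts on both strands with planted uORFs
(plain, in-frame pairs sharing one termination codon, CDS-overlapping,
intron-split initiation codons), somatic point variants deleting uAUG or
uStop codons or altering the Kozak window, per-caller VCFs with
configurable sensitivities, and amplicon-style base-count tables with a
log-normal per-site efficiency (reproducing the coverage skew of pooled
PCR amplicons), tumor purity and sequencing-error noise.

Every planted feature is recorded in a :class:`TruthManifest` so each
pipeline stage can be tested against ground truth without any download.
A single global seed fans out to per-stage child seeds derived by stable
hashing of the stage name, so partial re-runs are reproducible and
identical seeds produce byte-identical output files.

Construction guarantees the manifest is *exact*: background sequence is
scrubbed of stray AUGs and of in-frame stops inside planted uORFs by
substituting C (which occurs in neither AUG nor any stop codon, so a
substitution can never create a new start or stop), and a final
independent re-scan asserts that what was planted is exactly what is
discoverable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_io import (
    GenomeSequence,
    SiteBaseCount,
    TranscriptModel,
    VariantRecord,
    complement_base,
    positions_to_blocks,
    write_base_counts,
    write_fasta,
    write_transcript_table,
    write_vcf,
)

STOPS = ("TAA", "TAG", "TGA")
BASES = ("A", "C", "G", "T")
PURINES = {"A", "G"}


class GenerationError(RuntimeError):
    """A requested synthetic feature set is infeasible."""


def child_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed (< 2**31) derived from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


# ---------------------------------------------------------------------------
# Truth manifest


@dataclass
class TruthManifest:
    """Ground truth for one synthetic dataset; serializes to a single JSON."""

    seed: int
    genome_params: dict = field(default_factory=dict)
    contig_lengths: dict = field(default_factory=dict)
    transcripts: list = field(default_factory=list)
    variants: list = field(default_factory=list)
    base_count_params: dict = field(default_factory=dict)

    def all_uorfs(self):
        for t in self.transcripts:
            for u in t["uorfs"]:
                yield t, u

    def uorf_truth_set(self) -> set[tuple]:
        """Comparable per-isoform truth: one tuple per planted uORF."""
        out = set()
        for t, u in self.all_uorfs():
            out.add(
                (
                    t["transcript_id"],
                    u["uaug_offset"],
                    u["ustop_offset"],
                    u["cds_overlapping"],
                    tuple(u["start_positions"]),
                    tuple(u["stop_positions"]) if u["stop_positions"] else None,
                    u["kozak_strength"],
                    u["shared_stop_group"],
                )
            )
        return out

    def element_positions(self) -> set[tuple[str, int]]:
        """Every genomic base belonging to a planted codon or Kozak window."""
        out = set()
        for t, u in self.all_uorfs():
            contig = t["contig"]
            for p in u["start_positions"]:
                out.add((contig, p))
            for p in u["stop_positions"] or ():
                out.add((contig, p))
            for p in u["kozak_genomic"].values():
                out.add((contig, p))
        return out

    def codon_positions(self) -> set[tuple[str, int]]:
        out = set()
        for t, u in self.all_uorfs():
            for p in u["start_positions"]:
                out.add((t["contig"], p))
            for p in u["stop_positions"] or ():
                out.add((t["contig"], p))
        return out

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            data = json.load(fh)
        # JSON turns the int keys of kozak_genomic into strings
        for t in data["transcripts"]:
            for u in t["uorfs"]:
                u["kozak_genomic"] = {int(k): v for k, v in u["kozak_genomic"].items()}
        return cls(**data)


# ---------------------------------------------------------------------------
# Genome


def make_genome(
    seed: int,
    n_contigs: int = 2,
    lengths: Sequence[int] | None = None,
    gc: float = 0.45,
    names: Sequence[str] | None = None,
) -> GenomeSequence:
    """Random genome with the requested GC content, reproducible under seed."""
    if lengths is None:
        lengths = [30_000] * n_contigs
    if len(lengths) != n_contigs:
        raise ValueError("lengths must have n_contigs entries")
    if any(l < 1000 for l in lengths):
        raise ValueError("contig lengths must be >= 1000")
    if names is None:
        names = [f"chrS{i + 1}" for i in range(n_contigs)]
    rng = np.random.default_rng(child_seed(seed, "genome"))
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    contigs = {
        name: "".join(rng.choice(BASES, size=length, p=p))
        for name, length in zip(names, lengths)
    }
    return GenomeSequence(contigs)


# ---------------------------------------------------------------------------
# Transcripts with planted uORFs


def _scrub_to_c(arr: list[str], pos: int) -> None:
    arr[pos] = "C"


def _plan_uorf_placement(
    rng: np.random.Generator,
    tls_len: int,
    span_len: int,
    taken: list[tuple[int, int]],
    lo: int = 0,
    hi: int | None = None,
    attempts: int = 200,
) -> int | None:
    hi = tls_len - span_len if hi is None else min(hi, tls_len - span_len)
    if hi < lo:
        return None
    for _ in range(attempts):
        start = int(rng.integers(lo, hi + 1))
        span = (start, start + span_len)
        if all(span[1] <= s or span[0] >= e for s, e in taken):
            taken.append(span)
            return start
    return None


def _kozak_truth(arr: Sequence[str], uaug: int, tls_len: int) -> tuple[str, str]:
    """Realized Kozak window/strength of a planted uAUG (purine rule).

    Kept local so the manifest does not depend on the discovery module.
    """
    chars = []
    for rel in (-6, -5, -4, -3, -2, -1):
        idx = uaug + rel
        chars.append(arr[idx] if idx >= 0 else ".")
    chars.append(arr[uaug + 3])  # +4: next spliced base (CDS base 1 at the boundary)
    window = (
        "".join(c.lower() if c != "." else "." for c in chars[0:3])
        + (chars[3].upper() if chars[3] != "." else ".")
        + "".join(c.lower() if c != "." else "." for c in chars[4:6])
        + "ATG"
        + (chars[6].upper() if chars[6] != "." else ".")
    )
    minus3, plus4 = chars[3], chars[6]
    if minus3 not in BASES or plus4 not in BASES:
        strength = "undetermined"
    else:
        n = (minus3 in PURINES) + (plus4 in PURINES)
        strength = {2: "strong", 1: "intermediate", 0: "weak"}[n]
    return window, strength


def make_transcripts(
    genome: GenomeSequence,
    seed: int,
    n_coding: int = 40,
    n_noncoding: int = 10,
    tls_length_range: tuple[int, int] = (50, 500),
    exon_count_range: tuple[int, int] = (1, 4),
    minus_strand_fraction: float = 0.5,
    uorf_prevalence: float = 0.55,
    n_shared_stop_pairs: int = 2,
    n_overlapping: int = 2,
    n_split_codon: int = 2,
    intergenic_gap: int = 300,
) -> tuple[GenomeSequence, list[TranscriptModel], TruthManifest]:
    """Plant transcripts (and their uORFs) into a genome.

    Returns the rewritten genome, the transcript models and the truth
    manifest. ``uorf_prevalence`` is the fraction of ordinary coding
    transcripts carrying at least one uORF (the human-leader prevalence
    the generator emulates by default); the three ``n_*`` feature counts
    force transcripts hosting a shared-stop in-frame uAUG pair, a
    CDS-overlapping uORF and an intron-split uAUG, respectively.
    """
    rng = np.random.default_rng(child_seed(seed, "transcripts"))
    if n_shared_stop_pairs + n_overlapping + n_split_codon > n_coding:
        raise GenerationError("more special uORF features requested than transcripts")

    roles = (
        ["shared_stop_pair"] * n_shared_stop_pairs
        + ["cds_overlapping"] * n_overlapping
        + ["split_codon"] * n_split_codon
    )
    for _ in range(n_coding - len(roles)):
        roles.append("plain" if rng.random() < uorf_prevalence else "no_uorf")
    roles += ["noncoding"] * n_noncoding
    rng.shuffle(roles)

    arrays = {name: bytearray(seq, "ascii") for name, seq in genome.contigs.items()}
    cursors = {name: 50 for name in arrays}
    contig_names = list(arrays)

    models: list[TranscriptModel] = []
    manifest = TruthManifest(
        seed=seed,
        contig_lengths={n: len(a) for n, a in arrays.items()},
    )

    n_c = n_n = 0
    for role in roles:
        if role == "noncoding":
            n_n += 1
            tid, gene = f"NC{n_n:03d}", f"NCGENE{n_n:03d}"
        else:
            n_c += 1
            tid, gene = f"TX{n_c:03d}", f"GENE{n_c:03d}"
        strand = "-" if rng.random() < minus_strand_fraction else "+"

        lo, hi = tls_length_range
        if role in ("shared_stop_pair", "cds_overlapping", "split_codon"):
            lo = max(lo, 60)
        tls_len = int(rng.integers(lo, hi + 1))
        n_cds_codons = int(rng.integers(20, 61))
        cds_len = 3 * n_cds_codons
        utr3_len = int(rng.integers(30, 101))
        spliced_len = tls_len + cds_len + utr3_len

        p = [0.275, 0.225, 0.225, 0.275]
        arr = list(rng.choice(BASES, size=spliced_len, p=p))

        # background TLS must contain no AUG before planting
        for i in range(0, tls_len - 2):
            if arr[i] == "A" and arr[i + 1] == "T" and arr[i + 2] == "G":
                _scrub_to_c(arr, i + 1)

        # ----- plan and plant uORFs -----
        planted: list[dict] = []
        taken: list[tuple[int, int]] = []
        if role in ("plain", "split_codon"):
            n_uorfs = 1 if role == "split_codon" else int(rng.integers(1, 3))
            for k in range(n_uorfs):
                n_codons = int(rng.integers(2, 8))
                span = 3 * n_codons
                start_lo = 5 if role == "split_codon" else 0
                uaug = _plan_uorf_placement(rng, tls_len, span, taken, lo=start_lo)
                if uaug is None:
                    if k == 0:
                        raise GenerationError(f"{tid}: TLS too short for uORF")
                    continue
                planted.append({"uaug": uaug, "ustop": uaug + span - 3,
                                "kind": role})
        elif role == "shared_stop_pair":
            d = int(rng.integers(1, 3))
            kc = int(rng.integers(1, 4))
            span = 3 * d + 3 * kc + 3
            uaug = _plan_uorf_placement(rng, tls_len, span, taken)
            if uaug is None:
                raise GenerationError(f"{tid}: TLS too short for shared-stop pair")
            ustop = uaug + span - 3
            planted.append({"uaug": uaug, "ustop": ustop, "kind": "pair_first"})
            planted.append({"uaug": uaug + 3 * d, "ustop": ustop,
                            "kind": "pair_second"})
        elif role == "cds_overlapping":
            uaug = _plan_uorf_placement(
                rng, tls_len, 3, taken, lo=max(0, tls_len - 24), hi=tls_len - 3
            )
            if uaug is None:
                raise GenerationError(f"{tid}: cannot place CDS-overlapping uORF")
            planted.append({"uaug": uaug, "ustop": None, "kind": "cds_overlapping"})

        uaug_offsets = {u["uaug"] for u in planted}
        protected: set[int] = set()
        for u in planted:
            protected.update(range(u["uaug"], u["uaug"] + 3))
            if u["ustop"] is not None:
                protected.update(range(u["ustop"], u["ustop"] + 3))

        for u in planted:
            arr[u["uaug"] : u["uaug"] + 3] = list("ATG")
        stops_by_pos: dict[int, str] = {}
        for u in planted:
            if u["ustop"] is not None and u["ustop"] not in stops_by_pos:
                stops_by_pos[u["ustop"]] = STOPS[int(rng.integers(3))]
        for pos, codon in stops_by_pos.items():
            arr[pos : pos + 3] = list(codon)

        # stray AUGs introduced by planting
        for i in range(0, tls_len - 2):
            if arr[i] == "A" and arr[i + 1] == "T" and arr[i + 2] == "G":
                if i in uaug_offsets:
                    continue
                for j in (i + 1, i, i + 2):
                    if j not in protected:
                        _scrub_to_c(arr, j)
                        break
                else:
                    raise GenerationError(f"{tid}: unscrubable stray AUG at {i}")

        # no in-frame stop may precede the planted one (or, for a
        # CDS-overlapping uORF, occur anywhere downstream in the TLS)
        for u in planted:
            end = u["ustop"] if u["ustop"] is not None else tls_len - 2
            j = u["uaug"] + 3
            while j + 3 <= (u["ustop"] if u["ustop"] is not None else tls_len):
                codon = "".join(arr[j : j + 3])
                if codon in STOPS and j not in stops_by_pos:
                    for jj in (j + 1, j, j + 2):
                        if jj not in protected:
                            _scrub_to_c(arr, jj)
                            break
                    else:
                        raise GenerationError(f"{tid}: unscrubable stray stop at {j}")
                j += 3

        # main CDS
        if role != "noncoding":
            arr[tls_len : tls_len + 3] = list("ATG")
            arr[tls_len + cds_len - 3 : tls_len + cds_len] = list("TAA")

        # ----- defensive re-scan: planted truth must be exactly discoverable
        found = {
            i
            for i in range(0, tls_len - 2)
            if arr[i] == "A" and arr[i + 1] == "T" and arr[i + 2] == "G"
        }
        if found != uaug_offsets:
            raise GenerationError(f"{tid}: planted/observed uAUG sets differ")
        for u in planted:
            j = u["uaug"] + 3
            first_stop = None
            while j + 3 <= tls_len:
                if "".join(arr[j : j + 3]) in STOPS:
                    first_stop = j
                    break
                j += 3
            if first_stop != u["ustop"]:
                raise GenerationError(f"{tid}: planted/observed uStop differ")

        # ----- exon/intron structure -----
        n_exons = int(rng.integers(exon_count_range[0], exon_count_range[1] + 1))
        forced = None
        if role == "split_codon" and planted:
            forced = planted[0]["uaug"] + int(rng.integers(1, 3))
            n_exons = max(n_exons, 2)
        breakpoints: list[int] = []
        if n_exons > 1:
            for _ in range(500):
                cand = set(
                    int(x)
                    for x in rng.integers(5, spliced_len - 5, size=n_exons - 1)
                )
                if forced is not None:
                    cand = set(list(cand)[: n_exons - 2]) | {forced}
                cand = sorted(cand)
                bounds = [0] + cand + [spliced_len]
                if len(cand) == n_exons - 1 and all(
                    b2 - b1 >= 4 for b1, b2 in zip(bounds, bounds[1:])
                ):
                    breakpoints = cand
                    break
            else:
                breakpoints = [forced] if forced is not None else []
        elif forced is not None:
            breakpoints = [forced]
        intron_lengths = [int(rng.integers(60, 201)) for _ in breakpoints]

        # ----- genomic placement -----
        genomic_span = spliced_len + sum(intron_lengths)
        contig = None
        for name in contig_names:
            if cursors[name] + genomic_span + intergenic_gap <= len(arrays[name]):
                contig = name
                break
        if contig is None:
            raise GenerationError(
                f"{tid}: genome too small for remaining transcripts"
            )
        tx_start = cursors[contig]
        cursors[contig] += genomic_span + intergenic_gap

        coords: list[int] = []
        if strand == "+":
            g = tx_start
            bp = dict(zip(breakpoints, intron_lengths))
            for i in range(spliced_len):
                if i in bp:
                    g += bp[i]
                coords.append(g)
                g += 1
        else:
            g = tx_start + genomic_span - 1
            bp = dict(zip(breakpoints, intron_lengths))
            for i in range(spliced_len):
                if i in bp:
                    g -= bp[i]
                coords.append(g)
                g -= 1

        contig_arr = arrays[contig]
        for i, base in enumerate(arr):
            out = base if strand == "+" else complement_base(base)
            contig_arr[coords[i]] = ord(out)

        exons = positions_to_blocks(coords)
        if role == "noncoding":
            cds_start = cds_end = exons[0][0]
        elif strand == "+":
            cds_start = coords[tls_len]
            cds_end = coords[tls_len + cds_len - 1] + 1
        else:
            cds_end = coords[tls_len] + 1
            cds_start = coords[tls_len + cds_len - 1]

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
        models.append(model)

        uorf_entries = []
        for u in planted:
            uaug, ustop = u["uaug"], u["ustop"]
            window, strength = _kozak_truth(arr, uaug, tls_len)
            kozak_genomic = {
                rel: coords[uaug + rel]
                for rel in (-6, -5, -4, -3, -2, -1)
                if uaug + rel >= 0
            }
            kozak_genomic[4] = coords[uaug + 3]
            uorf_entries.append(
                {
                    "uaug_offset": uaug,
                    "ustop_offset": ustop,
                    "cds_overlapping": ustop is None,
                    "length_nt": None if ustop is None else ustop + 3 - uaug,
                    "stop_codon": None if ustop is None else stops_by_pos[ustop],
                    "start_positions": [coords[uaug + k] for k in range(3)],
                    "stop_positions": (
                        None if ustop is None
                        else [coords[ustop + k] for k in range(3)]
                    ),
                    "kozak_window": window,
                    "kozak_strength": strength,
                    "kozak_genomic": kozak_genomic,
                    "shared_stop_group": (
                        None if ustop is None else f"{tid}:stop@{ustop}"
                    ),
                    "kind": u["kind"],
                }
            )
        manifest.transcripts.append(
            {
                "transcript_id": tid,
                "gene": gene,
                "contig": contig,
                "strand": strand,
                "coding": role != "noncoding",
                "tls_length": tls_len if role != "noncoding" else 0,
                "uorfs": uorf_entries if role != "noncoding" else [],
            }
        )

    new_genome = GenomeSequence(
        {name: a.decode("ascii") for name, a in arrays.items()}
    )
    return new_genome, models, manifest


# ---------------------------------------------------------------------------
# Variants


def _strand_of(manifest: TruthManifest, transcript_id: str) -> str:
    for t in manifest.transcripts:
        if t["transcript_id"] == transcript_id:
            return t["strand"]
    raise KeyError(transcript_id)


def plant_variants(
    manifest: TruthManifest,
    genome: GenomeSequence,
    seed: int,
    n_start_loss: int = 22,
    n_stop_loss: int = 31,
    n_kozak: int = 1,
    n_stop_retained: int = 0,
    n_background: int = 0,
    n_samples: int = 30,
    sample_prefix: str = "S",
) -> list[VariantRecord]:
    """Plant somatic single-nucleotide variants on the manifest's uORFs.

    Start-loss variants substitute one AUG base (any single substitution
    destroys the AUG and is by construction near-cognate); stop-loss
    variants choose a sense substitution, stop-retained decoys a
    stop-to-stop substitution; Kozak variants hit the -6..-1 window at
    positions free of other codons; background variants avoid every
    catalog footprint. Alleles are emitted on the genomic plus strand,
    positions are distinct (non-recurrent), and each variant belongs to
    one of ``n_samples`` tumor/normal sample pairs.
    """
    rng = np.random.default_rng(child_seed(seed, "variants"))
    samples = [f"{sample_prefix}{i + 1:03d}" for i in range(n_samples)]

    uorfs = [(t, u) for t, u in manifest.all_uorfs()]
    stopped = [(t, u) for t, u in uorfs if u["ustop_offset"] is not None]
    codon_positions = manifest.codon_positions()
    element_positions = manifest.element_positions()
    used: set[tuple[str, int]] = set()

    def _pick(cands: list, n: int, label: str) -> list:
        if len(cands) < n:
            raise GenerationError(
                f"cannot plant {n} {label} variants: only {len(cands)} hosts"
            )
        order = rng.permutation(len(cands))
        return [cands[i] for i in order[:n]]

    variants: list[VariantRecord] = []

    def _emit(contig, strand, pos, ref_tx, alt_tx, element, classification, tid):
        ref_plus = ref_tx if strand == "+" else complement_base(ref_tx)
        alt_plus = alt_tx if strand == "+" else complement_base(alt_tx)
        observed = genome.base(contig, pos)
        if observed != ref_plus:
            raise GenerationError(
                f"internal inconsistency at {contig}:{pos}: genome {observed!r} "
                f"vs manifest {ref_plus!r}"
            )
        sample = samples[int(rng.integers(n_samples))]
        used.add((contig, pos))
        variants.append(
            VariantRecord(contig=contig, pos=pos, ref=ref_plus, alt=alt_plus,
                          sample_pair_id=sample)
        )
        manifest.variants.append(
            {
                "contig": contig, "pos": pos, "ref": ref_plus, "alt": alt_plus,
                "sample_pair_id": sample, "element": element,
                "classification": classification, "transcript_id": tid,
            }
        )

    # start-loss
    for t, u in _pick(uorfs, n_start_loss, "start-loss"):
        for _ in range(20):
            k = int(rng.integers(3))
            pos = u["start_positions"][k]
            if (t["contig"], pos) not in used:
                break
        else:
            raise GenerationError("could not find unused start-codon base")
        ref_tx = "ATG"[k]
        alt_tx = str(rng.choice([b for b in BASES if b != ref_tx]))
        _emit(t["contig"], t["strand"], pos, ref_tx, alt_tx,
              "uAUG", "loss_of_uAUG", t["transcript_id"])

    # stop-loss (and stop-retained decoys) on distinct stopped uORFs
    stop_hosts = _pick(stopped, n_stop_loss + n_stop_retained, "stop-affecting")
    for which, (t, u) in enumerate(stop_hosts):
        retained = which >= n_stop_loss
        codon = u["stop_codon"]
        subs = [
            (k, b)
            for k in range(3)
            for b in BASES
            if b != codon[k]
            and ((codon[:k] + b + codon[k + 1 :]) in STOPS) == retained
            and (t["contig"], u["stop_positions"][k]) not in used
        ]
        if not subs:
            raise GenerationError(f"no usable stop substitution on {codon}")
        k, alt_tx = subs[int(rng.integers(len(subs)))]
        _emit(t["contig"], t["strand"], u["stop_positions"][k], codon[k], alt_tx,
              "uStop", "stop_retained" if retained else "loss_of_uStop",
              t["transcript_id"])

    # Kozak window variants: upstream positions only, clear of any codon
    kozak_cands = []
    kozak_cand_positions: set[tuple[str, int]] = set()
    for t, u in uorfs:
        for rel, pos in u["kozak_genomic"].items():
            if rel == 4:
                continue
            key = (t["contig"], pos)
            if key in codon_positions or key in used or key in kozak_cand_positions:
                continue
            kozak_cand_positions.add(key)
            kozak_cands.append((t, u, rel, pos))
    for t, u, rel, pos in _pick(kozak_cands, n_kozak, "Kozak"):
        if (t["contig"], pos) in used:
            continue
        widx = {-6: 0, -5: 1, -4: 2, -3: 3, -2: 4, -1: 5}[rel]
        ref_tx = u["kozak_window"][widx].upper()
        alt_tx = str(rng.choice([b for b in BASES if b != ref_tx]))
        _emit(t["contig"], t["strand"], pos, ref_tx, alt_tx,
              "uKozak", "kozak_alteration", t["transcript_id"])

    # background variants clear of every catalog footprint
    contig_names = list(genome.contigs)
    for _ in range(n_background):
        for _ in range(1000):
            contig = contig_names[int(rng.integers(len(contig_names)))]
            pos = int(rng.integers(genome.length(contig)))
            if (contig, pos) in element_positions or (contig, pos) in used:
                continue
            ref = genome.base(contig, pos)
            if ref == "N":
                continue
            alt = str(rng.choice([b for b in BASES if b != ref]))
            sample = samples[int(rng.integers(n_samples))]
            used.add((contig, pos))
            variants.append(
                VariantRecord(contig=contig, pos=pos, ref=ref, alt=alt,
                              sample_pair_id=sample)
            )
            manifest.variants.append(
                {"contig": contig, "pos": pos, "ref": ref, "alt": alt,
                 "sample_pair_id": sample, "element": None,
                 "classification": "none", "transcript_id": None}
            )
            break
        else:
            raise GenerationError("could not place background variant")

    return variants


def emit_caller_vcfs(
    variants: Sequence[VariantRecord],
    seed: int,
    caller_sensitivities: Mapping[str, float],
    genome: GenomeSequence | None = None,
    n_false_positives: int = 0,
    avoid_positions: Iterable[tuple[str, int]] = (),
    out_dir: str | Path | None = None,
) -> dict[str, list[VariantRecord]]:
    """Per-pseudo-caller variant lists (optionally written as VCFs).

    Each caller reports every true variant independently with its
    sensitivity and adds ``n_false_positives`` random calls outside the
    truth set (``genome`` required for their reference alleles).
    """
    truth_positions = {(v.contig, v.pos) for v in variants} | set(avoid_positions)
    samples = sorted({v.sample_pair_id for v in variants}) or ["S001"]
    out: dict[str, list[VariantRecord]] = {}
    for caller, sens in caller_sensitivities.items():
        if not (0.0 <= sens <= 1.0):
            raise ValueError(f"sensitivity for {caller!r} must be in [0, 1]")
        rng = np.random.default_rng(child_seed(seed, f"caller:{caller}"))
        calls = [
            VariantRecord(contig=v.contig, pos=v.pos, ref=v.ref, alt=v.alt,
                          sample_pair_id=v.sample_pair_id, caller_id=caller)
            for v in variants
            if rng.random() < sens
        ]
        if n_false_positives:
            if genome is None:
                raise ValueError("genome required to draw false positives")
            contig_names = list(genome.contigs)
            placed = 0
            while placed < n_false_positives:
                contig = contig_names[int(rng.integers(len(contig_names)))]
                pos = int(rng.integers(genome.length(contig)))
                if (contig, pos) in truth_positions:
                    continue
                ref = genome.base(contig, pos)
                if ref == "N":
                    continue
                alt = str(rng.choice([b for b in BASES if b != ref]))
                calls.append(
                    VariantRecord(
                        contig=contig, pos=pos, ref=ref, alt=alt,
                        sample_pair_id=samples[int(rng.integers(len(samples)))],
                        caller_id=caller,
                    )
                )
                placed += 1
        out[caller] = sorted(calls, key=lambda r: r.key())
        if out_dir is not None:
            lengths = (
                {n: genome.length(n) for n in genome.contigs} if genome else None
            )
            write_vcf(out[caller], Path(out_dir) / f"caller_{caller}.vcf",
                      contig_lengths=lengths)
    return out


# ---------------------------------------------------------------------------
# Base counts


def simulate_base_counts(
    manifest: TruthManifest,
    genome: GenomeSequence,
    seed: int,
    samples: Sequence[str] | None = None,
    mean_depth: float = 103.0,
    depth_sigma: float = 1.5,
    purity: float = 0.5,
    error_rate: float = 0.005,
    zygosity: str = "het",
) -> tuple[list[tuple[str, str, int]], list[SiteBaseCount]]:
    """Amplicon-style base counts over every planted uORF element base.

    Per-site amplification efficiency is log-normal(-sigma^2/2, sigma)
    (mean 1), shared by all samples of a site — the screen's coverage skew
    came from site-specific PCR efficiency. ``depth_sigma = 0`` gives the
    exact ``mean_depth`` in every cell. At a cell carrying a planted
    variant the alternate allele is drawn with probability
    ``purity/2 * (1 - e) + e/3`` for a heterozygous variant (``purity``
    for homozygous); all other cells carry error-only alternates at
    ``e/3`` per base.
    """
    if not (0.0 < purity <= 1.0):
        raise ValueError("purity must be in (0, 1]")
    if zygosity not in ("het", "hom"):
        raise ValueError("zygosity must be 'het' or 'hom'")
    rng = np.random.default_rng(child_seed(seed, "base_counts"))

    design: list[tuple[str, str, int]] = []
    seen_positions: set[tuple[str, int]] = set()
    for t, u in manifest.all_uorfs():
        contig = t["contig"]
        groups = [("uAUG", u["start_positions"])]
        if u["stop_positions"]:
            groups.append(("uStop", u["stop_positions"]))
        groups.append(("uKozak", sorted(u["kozak_genomic"].values())))
        for element, positions in groups:
            for k, pos in enumerate(positions):
                if (contig, pos) in seen_positions:
                    continue
                seen_positions.add((contig, pos))
                site_id = f"{t['transcript_id']}:{element}:{u['uaug_offset']}:{k}"
                design.append((site_id, contig, pos))

    if samples is None:
        samples = sorted({v["sample_pair_id"] for v in manifest.variants}) or ["S001"]

    variant_map = {
        (v["sample_pair_id"], v["contig"], v["pos"]): v["alt"]
        for v in manifest.variants
    }
    vaf = purity / 2 if zygosity == "het" else purity

    counts: list[SiteBaseCount] = []
    for site_id, contig, pos in design:
        eff = rng.lognormal(-depth_sigma**2 / 2, depth_sigma) if depth_sigma > 0 else 1.0
        ref = genome.base(contig, pos)
        for sample in samples:
            depth = (
                int(rng.poisson(mean_depth * eff))
                if depth_sigma > 0
                else int(round(mean_depth))
            )
            alt = variant_map.get((sample, contig, pos))
            probs = dict.fromkeys(BASES, error_rate / 3)
            if alt is not None:
                p_alt = vaf * (1 - error_rate) + error_rate / 3
                probs[alt] = p_alt
                probs[ref] = 1.0 - p_alt - 2 * error_rate / 3
            else:
                probs[ref] = 1.0 - error_rate
            draw = rng.multinomial(depth, [probs[b] for b in BASES])
            tallies = {b: int(c) for b, c in zip(BASES, draw)}
            tallies["DEL"] = 0
            counts.append(
                SiteBaseCount(sample_id=sample, contig=contig, pos=pos,
                              ref_base=ref, counts=tallies)
            )

    manifest.base_count_params = {
        "mean_depth": mean_depth, "depth_sigma": depth_sigma,
        "purity": purity, "error_rate": error_rate, "zygosity": zygosity,
        "samples": list(samples),
    }
    return design, counts


# ---------------------------------------------------------------------------
# One-call cohort driver


def simulate_cohort(
    seed: int,
    out_dir: str | Path | None = None,
    n_contigs: int = 3,
    contig_length: int = 60_000,
    gc: float = 0.45,
    n_coding: int = 60,
    n_noncoding: int = 10,
    n_start_loss: int = 22,
    n_stop_loss: int = 31,
    n_kozak: int = 1,
    n_background: int = 0,
    caller_sensitivities: Mapping[str, float] | None = None,
    mean_depth: float = 103.0,
    depth_sigma: float = 1.5,
    purity: float = 0.5,
    error_rate: float = 0.005,
    uorf_prevalence: float = 1.0,
) -> dict:
    """Generate a complete synthetic study (genome, transcripts, variants,
    caller VCFs, base counts) and optionally write every file.

    Returns a dict with the in-memory objects; with ``out_dir`` set, the
    standard-format files (FASTA, refGene table, truth JSON, VCFs,
    base-count TSV, design TSV) are written there too.
    """
    if caller_sensitivities is None:
        caller_sensitivities = {
            "sniper": 1.0, "varscan": 1.0, "mutect2": 1.0, "muse": 1.0
        }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    genome0 = make_genome(seed, n_contigs=n_contigs,
                          lengths=[contig_length] * n_contigs, gc=gc)
    genome, models, manifest = make_transcripts(
        genome0, seed, n_coding=n_coding, n_noncoding=n_noncoding,
        uorf_prevalence=uorf_prevalence,
    )
    variants = plant_variants(
        manifest, genome, seed,
        n_start_loss=n_start_loss, n_stop_loss=n_stop_loss,
        n_kozak=n_kozak, n_background=n_background,
    )
    caller_sets = emit_caller_vcfs(
        variants, seed, caller_sensitivities, genome=genome,
        out_dir=out_dir,
    )
    design, counts = simulate_base_counts(
        manifest, genome, seed,
        mean_depth=mean_depth, depth_sigma=depth_sigma,
        purity=purity, error_rate=error_rate,
    )

    if out_dir is not None:
        write_fasta(genome, out_dir / "genome.fa")
        write_transcript_table(models, out_dir / "refgene.txt")
        lengths = {n: genome.length(n) for n in genome.contigs}
        write_vcf(variants, out_dir / "variants.vcf", contig_lengths=lengths)
        write_base_counts(counts, out_dir / "counts.tsv")
        with open(out_dir / "design.tsv", "w") as fh:
            fh.write("site_id\tcontig\tpos\n")
            for site_id, contig, pos in design:
                fh.write(f"{site_id}\t{contig}\t{pos + 1}\n")
        manifest.to_json(out_dir / "truth.json")

    return {
        "genome": genome,
        "models": models,
        "manifest": manifest,
        "variants": variants,
        "caller_sets": caller_sets,
        "design": design,
        "counts": counts,
    }
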