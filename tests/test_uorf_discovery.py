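"""Leader extraction, uORF scanning, Kozak classification, catalogs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uorfscan.genome_io import GenomeSequence, TranscriptModel, reverse_complement
from uorfscan.uorf_discovery import (
    KozakPolicy,
    ModelInconsistencyError,
    UORFCatalog,
    annotate_genome,
    codon_keys_from_bed,
    extract_leader,
    filter_coding,
    kozak_context,
    scan_uorfs,
)

from conftest import make_leader, naive_uorf_scan, plant_transcript


def _coding(tid="T", cds=(40, 100)):
    return TranscriptModel(tid, tid, "c1", "+", [(10, 150)], cds[0], cds[1])


def _noncoding(tid="N"):
    return TranscriptModel(tid, tid, "c1", "+", [(10, 150)], 10, 10)


class TestFilterCoding:
    def test_direct_filter(self):
        kept = filter_coding([_coding("a"), _noncoding("n"), _coding("b")])
        assert [m.transcript_id for m in kept] == ["a", "b"]

    def test_all_noncoding_warns(self, caplog):
        with caplog.at_level("WARNING"):
            assert filter_coding([_noncoding()]) == []
        assert "no coding transcripts" in caplog.text


class TestExtractLeader:
    def test_single_exon_plus_identity(self):
        genome, model, coords = plant_transcript("ACGTAA", "ATGCCCTAA")
        leader = extract_leader(model, genome)
        assert leader.sequence == "ACGTAA"
        assert list(leader.coord_map) == coords[:6]
        assert leader.cds_first_base == "A"

    def test_two_exon_minus_per_base_oracle(self):
        tls = "ACGTACGGTTAC"
        genome, model, coords = plant_transcript(
            tls, "ATGAAATAA", strand="-", introns={5: 70}
        )
        leader = extract_leader(model, genome)
        assert leader.sequence == tls
        # per-base oracle: each leader base is the complement of the
        # plus-strand genome base at its mapped coordinate
        for i, g in enumerate(leader.coord_map):
            assert leader.sequence[i] == reverse_complement(
                genome.fetch(model.contig, g, g + 1)
            )
        # descending map on the minus strand
        assert all(a > b for a, b in zip(leader.coord_map, leader.coord_map[1:]))

    def test_intron_absent_from_leader(self):
        tls = "AAACCCGGGTTT"
        genome, model, _ = plant_transcript(tls, "ATGTAA", introns={6: 80})
        leader = extract_leader(model, genome)
        assert len(leader.sequence) == len(tls)
        assert leader.sequence == tls
        assert len(model.exons) == 2

    def test_empty_leader_allowed(self):
        genome, model, _ = plant_transcript("", "ATGCCCTAA")
        assert extract_leader(model, genome).sequence == ""

    def test_cds_start_outside_exons_fails(self):
        genome = GenomeSequence({"c1": "A" * 200})
        model = TranscriptModel("T", "T", "c1", "+", [(10, 40), (100, 150)], 60, 120)
        with pytest.raises(ModelInconsistencyError, match="CDS start"):
            extract_leader(model, genome)


class TestScanUorfs:
    def test_minimal_uorf(self):
        (u,) = scan_uorfs(make_leader("ATGTAA"))
        assert (u.uaug_offset, u.ustop_offset, u.length_nt) == (0, 3, 6)
        assert not u.cds_overlapping

    def test_shared_stop_counts(self):
        uorfs = scan_uorfs(make_leader("ATGATGTGA"))
        assert [(u.uaug_offset, u.ustop_offset) for u in uorfs] == [(0, 6), (3, 6)]
        assert len({u.shared_stop_group for u in uorfs}) == 1
        catalog = UORFCatalog(uorfs)
        assert len(catalog.unique_ustop_keys()) == 1 < len(catalog.unique_uaug_keys())

    def test_cds_overlapping_flagged_and_off_ustop_catalog(self):
        (u,) = scan_uorfs(make_leader("CATGCC"))
        assert u.cds_overlapping and u.ustop_offset is None
        catalog = UORFCatalog([u])
        assert catalog.unique_ustop_keys() == set()
        assert len(catalog.unique_uaug_keys()) == 1

    def test_codon_with_n_never_matches(self):
        # TAN is not a stop; ATG holding an N is not a start
        (u,) = scan_uorfs(make_leader("ATGTANTAA"))
        assert u.ustop_offset == 6
        assert scan_uorfs(make_leader("ATNGTAA")) == []

    def test_oracle_equivalence_on_random_leaders(self):
        rng = np.random.default_rng(123)
        for _ in range(120):
            n = int(rng.integers(0, 301))
            gc = rng.uniform(0.3, 0.7)
            p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
            seq = "".join(rng.choice(list("ACGT"), size=n, p=p))
            got = [(u.uaug_offset, u.ustop_offset) for u in scan_uorfs(make_leader(seq))]
            assert got == naive_uorf_scan(seq)

    @given(st.text(alphabet="ACGT", min_size=1, max_size=120))
    @settings(max_examples=60, deadline=None)
    def test_truncation_never_creates_new_uorfs(self, seq):
        # dropping the 5'-most base leaves only suffix-uORFs of the original
        full = {(u.uaug_offset, u.ustop_offset) for u in scan_uorfs(make_leader(seq))}
        trunc = scan_uorfs(make_leader(seq[1:]))
        shifted = {
            (u.uaug_offset + 1, None if u.ustop_offset is None else u.ustop_offset + 1)
            for u in trunc
        }
        assert shifted <= full

    @given(st.text(alphabet="ACGT", min_size=0, max_size=150))
    @settings(max_examples=60, deadline=None)
    def test_never_more_unique_stops_than_starts(self, seq):
        catalog = UORFCatalog(scan_uorfs(make_leader(seq)))
        assert len(catalog.unique_ustop_keys()) <= len(catalog.unique_uaug_keys())


class TestKozak:
    def test_intermediate_context(self):
        # -3 = T (no match), +4 = A (purine match) -> one core match
        leader = make_leader("TTGTGTATGA" + "CC")
        kz = kozak_context(leader, 6)
        assert kz.window == "ttgTgtATGA"
        assert (kz.core_matches, kz.strength) == (1, "intermediate")

    def test_optimal_context_is_strong(self):
        leader = make_leader("GCCGCCATGG")
        kz = kozak_context(leader, 6)
        assert kz.window == "gccGccATGG"
        assert (kz.core_matches, kz.strength) == (2, "strong")

    def test_weak_context(self):
        kz = kozak_context(make_leader("TCCTCCATGT"), 6)
        assert (kz.core_matches, kz.strength) == (0, "weak")

    def test_truncated_upstream_is_undetermined(self):
        kz = kozak_context(make_leader("CATGTAAGGG"), 1)
        assert kz.strength == "undetermined"
        assert kz.window.startswith(".....")

    def test_plus4_from_cds_when_aug_abuts_cds(self):
        leader = make_leader("GCCGCCATG", cds_first_base="G")
        kz = kozak_context(leader, 6)
        assert kz.window.endswith("ATGG")
        assert kz.strength == "strong"

    def test_exact_g_policy_demotes_a(self):
        policy = KozakPolicy(match_rule_minus3="exact-G", match_rule_plus4="exact-G")
        kz = kozak_context(make_leader("GCCACCATGA"), 6, policy)
        assert (kz.core_matches, kz.strength) == (0, "weak")


class TestCatalog:
    def test_isoform_dedupe_by_genomic_position(self):
        genome, m1, _ = plant_transcript("CCATGTAACC", "ATGAAATAA", tid="I1")
        _, m2, _ = plant_transcript("CCATGTAACC", "ATGAAATAA", tid="I2")
        by_pos = annotate_genome([m1, m2], genome, dedupe="by-genomic-position")
        per_tx = annotate_genome([m1, m2], genome, dedupe="per-transcript")
        assert len(by_pos.records) == 2  # records always per isoform
        assert by_pos.n_uaug() == 1 and by_pos.n_ustop() == 1
        assert per_tx.n_uaug() == 2 and per_tx.n_ustop() == 2

    def test_bed_roundtrip_preserves_codon_sets(self, tmp_path, small_cohort):
        catalog = annotate_genome(small_cohort["models"], small_cohort["genome"])
        catalog.write_bed(tmp_path / "cat")
        assert codon_keys_from_bed(tmp_path / "cat.uaug.bed") == catalog.unique_uaug_keys()
        assert codon_keys_from_bed(tmp_path / "cat.ustop.bed") == catalog.unique_ustop_keys()

    def test_catalog_tsv_roundtrip(self, tmp_path, small_cohort):
        catalog = annotate_genome(small_cohort["models"], small_cohort["genome"])
        catalog.write_tsv(tmp_path / "cat.tsv")
        back = UORFCatalog.read_tsv(tmp_path / "cat.tsv")
        key = lambda r: (r.transcript_id, r.uaug_offset)
        for a, b in zip(sorted(catalog.records, key=key), sorted(back.records, key=key)):
            assert (a.start_positions, a.stop_positions, a.kozak, a.shared_stop_group) \
                == (b.start_positions, b.stop_positions, b.kozak, b.shared_stop_group)


def _resplice(genome, contig, strand, blocks):
    s = "".join(genome.fetch(contig, a, b) for a, b in blocks)
    return s if strand == "+" else reverse_complement(s)


class TestProjectionRoundTrip:
    def test_discovered_codons_resplice_to_their_strings(self, small_cohort):
        """Every genomic codon projection, re-fetched and re-spliced on the
        transcript strand, must reproduce ATG or the recorded stop codon —
        including minus-strand and intron-split codons."""
        genome = small_cohort["genome"]
        catalog = annotate_genome(small_cohort["models"], genome)
        seen_split = seen_minus = False
        for r in catalog.records:
            seen_split = seen_split or len(r.start_blocks) > 1
            seen_minus = seen_minus or r.strand == "-"
            assert _resplice(genome, r.contig, r.strand, r.start_blocks) == "ATG"
            if r.stop_blocks is not None:
                assert _resplice(genome, r.contig, r.strand, r.stop_blocks) == r.stop_codon
        assert seen_minus  # both strands exercised

    def test_intron_split_codon_respliced(self):
        # force a split uAUG explicitly: intron inside the ATG
        genome, model, _ = plant_transcript("CCATGTAACC", "ATGAAATAA",
                                            introns={3: 90})
        catalog = annotate_genome([model], genome)
        (r,) = catalog.records
        assert len(r.start_blocks) == 2
        assert _resplice(genome, r.contig, r.strand, r.start_blocks) == "ATG"
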