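"""Consensus filtering, coverage gating, consequence classification."""

import itertools

import pytest

from uorfscan.genome_io import SiteBaseCount, VariantRecord, complement_base, read_vcf
from uorfscan.uorf_discovery import STOP_CODONS, annotate_genome
from uorfscan.variant_annotation import (
    AssemblyMismatchError,
    ReferenceMismatchError,
    classify_effect,
    consensus,
    coverage_gate,
    subset_to_catalog,
    tabulate_effects,
)
from uorfscan.synthetic_data import emit_caller_vcfs

from conftest import plant_transcript

BASES = "ACGT"


def catalog_for(tls, cds="ATGAAATAA", strand="+", tid="T1"):
    genome, model, _ = plant_transcript(tls, cds, strand=strand, tid=tid)
    return genome, annotate_genome([model], genome, dedupe="per-transcript")


class TestSubset:
    def test_codon_containment(self):
        genome, catalog = catalog_for("CCATGTAACC")
        (r,) = catalog.records
        v = VariantRecord("c1", r.start_positions[1], "T", "C")
        pairs = subset_to_catalog([v], catalog)
        assert len(pairs) == 1 and pairs[0][1].element == "uAUG"

    def test_outside_codon_dropped_without_kozak_window(self):
        genome, catalog = catalog_for("CCATGTAACC")
        (r,) = catalog.records
        v = VariantRecord("c1", r.start_positions[0] - 1, "C", "A")
        assert subset_to_catalog([v], catalog, kozak_window=False) == []
        assert subset_to_catalog([v], catalog, kozak_window=True)

    def test_shared_codon_yields_one_pairing_per_isoform(self):
        genome, m1, _ = plant_transcript("CCATGTAACC", "ATGAAATAA", tid="I1")
        _, m2, _ = plant_transcript("CCATGTAACC", "ATGAAATAA", tid="I2")
        catalog = annotate_genome([m1, m2], genome, dedupe="per-transcript")
        pos = catalog.records[0].start_positions[0]
        pairs = subset_to_catalog([VariantRecord("c1", pos, "A", "G")], catalog)
        assert sorted(h.record.transcript_id for _, h in pairs) == ["I1", "I2"]

    def test_assembly_mismatch_fails_loud(self):
        genome, catalog = catalog_for("CCATGTAACC")
        with pytest.raises(AssemblyMismatchError):
            subset_to_catalog([VariantRecord("chrOther", 5, "A", "G")], catalog)


class TestConsensus:
    def _sets(self):
        v = lambda pos, sp="P1": VariantRecord("c1", pos, "A", "G", sample_pair_id=sp)
        return {
            "c1": [v(1), v(2), v(3)],
            "c2": [v(1), v(2)],
            "c3": [v(1), v(2)],
            "c4": [v(1)],
        }

    def test_all_caller_default(self):
        kept = consensus(self._sets())
        assert [r.pos for r in kept] == [1]
        assert kept[0].callers == ("c1", "c2", "c3", "c4")

    def test_threshold(self):
        assert [r.pos for r in consensus(self._sets(), required=3)] == [1, 2]

    def test_required_one_is_union(self):
        assert [r.pos for r in consensus(self._sets(), required=1)] == [1, 2, 3]

    def test_monotone_in_required(self):
        sizes = [len(consensus(self._sets(), required=k)) for k in (1, 2, 3, 4)]
        assert sizes == sorted(sizes, reverse=True)

    def test_enumeration_oracle_on_emitted_vcfs(self, tmp_path):
        """Consensus over four pseudo-caller VCFs with mixed sensitivities
        equals direct enumeration of the emitted files."""
        truth = [
            VariantRecord("c1", p, "A", "G", sample_pair_id=f"P{p % 7}")
            for p in range(0, 2000, 10)
        ]
        sens = {"a": 0.95, "b": 0.9, "c": 0.8, "d": 0.7}
        emit_caller_vcfs(truth, seed=5, caller_sensitivities=sens,
                         out_dir=tmp_path)
        sets = {
            name: read_vcf(tmp_path / f"caller_{name}.vcf", caller_id=name)
            for name in sens
        }
        kept = consensus(sets)
        keys = [set(r.key() for r in recs) for recs in sets.values()]
        expected = set.intersection(*keys)
        assert {r.key() for r in kept} == expected
        assert 0 < len(kept) < len(truth)


class TestCoverageGate:
    def _counts(self, total):
        return {("c1", 100): SiteBaseCount("x", "c1", 100, "A", {"A": total})}

    def test_and_semantics(self):
        v = VariantRecord("c1", 100, "A", "G")
        assert coverage_gate(v, self._counts(12), self._counts(10)) == (True, "pass")
        passed, reason = coverage_gate(v, self._counts(12), self._counts(9))
        assert not passed and "normal" in reason

    def test_uncovered(self):
        v = VariantRecord("c1", 500, "A", "G")
        assert coverage_gate(v, self._counts(12), self._counts(12)) == (
            False, "uncovered")


class TestClassifyEffect:
    @pytest.mark.parametrize(
        "codon_pos,ref,alt,expected_codon",
        [(0, "A", "G", "GTG"), (1, "T", "C", "ACG"), (2, "G", "A", "ATA")],
    )
    def test_uaug_substitutions(self, codon_pos, ref, alt, expected_codon):
        genome, catalog = catalog_for("CCCATGTAACC")
        (r,) = catalog.records
        v = VariantRecord("c1", r.start_positions[codon_pos], ref, alt)
        (pair,) = [p for p in subset_to_catalog([v], catalog)
                   if p[1].element == "uAUG"]
        e = classify_effect(v, pair[1], genome=genome)
        assert (e.classification, e.alt_codon) == ("loss_of_uAUG", expected_codon)
        assert e.near_cognate

    def test_exhaustive_codon_substitution_matrix(self):
        """All 9 ATG substitutions lose the start (always near-cognate);
        per stop codon, stop->stop substitutions retain and stop->sense
        substitutions lose the stop (4 and 23 over the three stops)."""
        retained = lost = 0
        for stop in sorted(STOP_CODONS):
            tls = "CC" + "ATG" + "GAC" + stop + "CC"
            genome, catalog = catalog_for(tls)
            (r,) = catalog.records
            assert r.stop_codon == stop
            for k, alt_tx in itertools.product(range(3), BASES):
                if alt_tx == "ATG"[k]:
                    continue
                v = VariantRecord("c1", r.start_positions[k], "ATG"[k], alt_tx)
                (h,) = [h for _, h in subset_to_catalog([v], catalog)
                        if h.element == "uAUG"]
                e = classify_effect(v, h, genome=genome)
                assert e.classification == "loss_of_uAUG" and e.near_cognate
            for k, alt_tx in itertools.product(range(3), BASES):
                if alt_tx == stop[k]:
                    continue
                v = VariantRecord("c1", r.stop_positions[k], stop[k], alt_tx)
                (h,) = [h for _, h in subset_to_catalog([v], catalog)
                        if h.element == "uStop"]
                e = classify_effect(v, h, genome=genome)
                if e.alt_codon in STOP_CODONS:
                    assert e.classification == "stop_retained"
                    retained += 1
                else:
                    assert e.classification == "loss_of_uStop"
                    lost += 1
        assert (retained, lost) == (4, 23)

    @pytest.mark.parametrize("ref,alt,expected",
                             [("TAA", "TAG", "stop_retained"),
                              ("TGA", "TGG", "loss_of_uStop")])
    def test_stop_examples(self, ref, alt, expected):
        tls = "CC" + "ATGGAC" + ref + "CC"
        genome, catalog = catalog_for(tls)
        (r,) = catalog.records
        k = next(i for i in range(3) if ref[i] != alt[i])
        v = VariantRecord("c1", r.stop_positions[k], ref[k], alt[k])
        (h,) = [h for _, h in subset_to_catalog([v], catalog)
                if h.element == "uStop"]
        assert classify_effect(v, h, genome=genome).classification == expected

    def test_kozak_minus1_substitution_keeps_strength(self):
        # context ttgTggATGA -> ttgTgtATGA: intermediate before and after
        genome, catalog = catalog_for("TTGTGGATGA" + "CC")
        (r,) = catalog.records
        assert r.kozak.window == "ttgTggATGA"
        pos = r.kozak_genomic[-1]
        v = VariantRecord("c1", pos, "G", "T")
        (h,) = [h for _, h in subset_to_catalog([v], catalog, kozak_window=True)
                if h.element == "uKozak" and h.kozak_rel == -1]
        e = classify_effect(v, h, genome=genome)
        assert e.classification == "kozak_alteration"
        assert e.kozak_before == e.kozak_after == "intermediate"

    def test_kozak_core_change_shifts_strength(self):
        genome, catalog = catalog_for("GCCGCCATGG")
        (r,) = catalog.records
        pos = r.kozak_genomic[-3]
        v = VariantRecord("c1", pos, "G", "T")
        (h,) = [h for _, h in subset_to_catalog([v], catalog, kozak_window=True)
                if h.element == "uKozak" and h.kozak_rel == -3]
        e = classify_effect(v, h, genome=genome)
        assert (e.kozak_before, e.kozak_after) == ("strong", "intermediate")

    def test_minus_strand_matches_mirrored_plus_construction(self):
        tls, cds = "CCCATGTAACC", "ATGAAATAA"
        effects = {}
        for strand in "+-":
            genome, model, _ = plant_transcript(tls, cds, strand=strand)
            catalog = annotate_genome([model], genome)
            (r,) = catalog.records
            ref_tx, alt_tx = "T", "C"  # ATG -> ACG on the transcript strand
            ref = ref_tx if strand == "+" else complement_base(ref_tx)
            alt = alt_tx if strand == "+" else complement_base(alt_tx)
            v = VariantRecord("c1", r.start_positions[1], ref, alt)
            (h,) = [h for _, h in subset_to_catalog([v], catalog)
                    if h.element == "uAUG"]
            e = classify_effect(v, h, genome=genome)
            effects[strand] = (e.classification, e.alt_codon, e.near_cognate)
        assert effects["+"] == effects["-"] == ("loss_of_uAUG", "ACG", True)

    def test_reference_mismatch_fails_loud(self):
        genome, catalog = catalog_for("CCATGTAACC")
        (r,) = catalog.records
        v = VariantRecord("c1", r.start_positions[0], "C", "G")  # wrong ref
        (h,) = [h for _, h in subset_to_catalog([v], catalog)
                if h.element == "uAUG"]
        with pytest.raises(ReferenceMismatchError):
            classify_effect(v, h, genome=genome)

    def test_complex_variant_reported_not_dropped(self):
        genome, catalog = catalog_for("CCATGTAACC")
        (r,) = catalog.records
        v = VariantRecord("c1", r.start_positions[0], "AT", "A")
        (h,) = [h for _, h in subset_to_catalog([v], catalog)
                if h.element == "uAUG"]
        assert classify_effect(v, h, genome=genome).classification == "complex"


class TestTabulate:
    def test_empty_summary(self):
        summary = tabulate_effects([])
        assert summary["n_effects"] == summary["n_variants"] == 0
        assert summary["by_classification"] == {}

    def test_recurrence_and_known_partition(self):
        genome, catalog = catalog_for("CCATGTAACC")
        (r,) = catalog.records
        pos = r.start_positions[0]
        effects = []
        for sample in ("P1", "P2"):
            v = VariantRecord("c1", pos, "A", "G", sample_pair_id=sample)
            (h,) = [h for _, h in subset_to_catalog([v], catalog)
                    if h.element == "uAUG"]
            effects.append(classify_effect(v, h, genome=genome))
        summary = tabulate_effects(effects, known_sites={("c1", pos): {"G"}})
        assert summary["n_recurrent"] == 1
        assert summary["n_known"] == 1 and summary["n_novel"] == 0
        assert summary["variants_by_classification"] == {"loss_of_uAUG": 1}
        assert summary["by_classification"] == {"loss_of_uAUG": 2}
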