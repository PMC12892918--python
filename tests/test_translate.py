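"""Event application, variant translation, digestion and self subtraction."""
from __future__ import annotations

import numpy as np
import pytest

from spliceneo import synthdata as sd
from spliceneo import translate as tr
from spliceneo.models import SpliceEvent, TranscriptModel, VariantProtein

from _oracles import (oracle_revcomp, oracle_splice, oracle_translate,
                      oracle_windows)


def _toy_gene(strand="+"):
    """Three-exon toy: ATG-exon 'ATGAAA', cassette 'GGG', final 'TTTTAG'."""
    sense = "NN" + "ATGAAA" + "gtag" + "GGG" + "gtag" + "TTTTAG" + "NN"
    sense = sense.upper().replace("N", "C")
    exons = [(2, 8), (12, 15), (19, 25)]
    if strand == "-":
        L = len(sense)
        chrom = oracle_revcomp(sense)
        exons = sorted((L - e, L - s) for s, e in exons)
        cds = (L - 25, L - 2)
    else:
        chrom = sense
        cds = (2, 25)
    t = TranscriptModel(
        transcript_id="t1", gene_id="g1", chrom="c1", strand=strand,
        exons=tuple(exons), cds_start=cds[0], cds_end=cds[1],
    )
    ex_sorted = sorted(exons)
    ev = SpliceEvent(
        event_id="e1", event_type="SE", gene_id="g1", chrom="c1", strand=strand,
        exon=ex_sorted[1], upstream=ex_sorted[0], downstream=ex_sorted[2],
    )
    return {"c1": chrom}, t, ev


class TestApplyEvent:
    def test_se_plus_strand_concatenation(self):
        genome, t, ev = _toy_gene("+")
        pair = tr.apply_event(ev, t, genome)
        assert pair.inclusion_mrna == "ATGAAAGGGTTTTAG"
        assert pair.exclusion_mrna == "ATGAAATTTTAG"

    def test_minus_strand_equals_reverse_complement_construction(self):
        genome_p, tp, evp = _toy_gene("+")
        genome_m, tm, evm = _toy_gene("-")
        pp = tr.apply_event(evp, tp, genome_p)
        pm = tr.apply_event(evm, tm, genome_m)
        assert pm.inclusion_mrna == pp.inclusion_mrna
        assert pm.exclusion_mrna == pp.exclusion_mrna

    def test_ri_length_conservation(self):
        cfg = sd.SimulationConfig(seed=5, n_genes=4, n_events=4, fraction_ri=1.0,
                                  n_planted_binders=0, n_planted_ms_exclusive=0)
        genome, transcripts, _, events = sd.simulate_annotation(cfg)
        for ev, t in zip(events, transcripts):
            pair = tr.apply_event(ev, t, genome)
            intron_len = ev.exon[1] - ev.exon[0]
            assert len(pair.inclusion_mrna) == len(pair.exclusion_mrna) + intron_len

    def test_unrepresentable_event_raises(self):
        genome, t, ev = _toy_gene("+")
        bad = SpliceEvent(
            event_id="x", event_type="SE", gene_id="g1", chrom="c1", strand="+",
            exon=(1, 2), upstream=ev.upstream, downstream=ev.downstream,
        )
        with pytest.raises(tr.EventNotRepresentable):
            tr.apply_event(bad, t, genome)


class TestTranslateVariant:
    def test_in_frame_exclusion(self):
        genome, t, ev = _toy_gene("+")
        vp, ref = tr.translate_variant(ev, t, genome, variant_form="exclusion")
        assert vp.sequence == "MKF"
        assert vp.frame_status == "in_frame"
        assert ref == "MKGF"

    def test_frameshift_cassette(self):
        # cassette of length 4: exclusion stays reference, inclusion-gain would
        # shift; here the cassette is in the reference, so skipping length-4 shifts
        sense = "CC" + "ATGAAA" + "GTAG" + "GGGA" + "GTAG" + "TTTGCTTAAGTTAAC" + "CC"
        exons = ((2, 8), (12, 16), (20, 35))
        t = TranscriptModel(
            transcript_id="t1", gene_id="g1", chrom="c1", strand="+",
            exons=exons, cds_start=2, cds_end=35,
        )
        ev = SpliceEvent(
            event_id="e1", event_type="SE", gene_id="g1", chrom="c1", strand="+",
            exon=exons[1], upstream=exons[0], downstream=exons[2],
        )
        genome = {"c1": sense}
        vp, ref = tr.translate_variant(ev, t, genome, variant_form="exclusion")
        assert vp.frame_status == "frameshift"
        # oracle: splice and translate the exclusion form by hand
        excl = oracle_splice(sense, [exons[0], exons[2]], "+")
        assert vp.sequence == oracle_translate(excl, 0)
        # downstream of the junction the residues differ from reference
        lo, hi = vp.novel_region
        assert hi == len(vp.sequence) and hi > lo

    def test_utr_event_has_empty_novel_region(self):
        # cassette entirely in the 3' UTR: exclusion protein equals reference
        sense = "CC" + "ATGAAATAA" + "CCC" + "GTAG" + "GGG" + "GTAG" + "TTTTTT" + "CC"
        exons = ((2, 14), (18, 21), (25, 31))
        t = TranscriptModel(
            transcript_id="t1", gene_id="g1", chrom="c1", strand="+",
            exons=exons, cds_start=2, cds_end=11,
        )
        ev = SpliceEvent(
            event_id="e1", event_type="SE", gene_id="g1", chrom="c1", strand="+",
            exon=exons[1], upstream=exons[0], downstream=exons[2],
        )
        vp, ref = tr.translate_variant(ev, t, {"c1": sense}, variant_form="exclusion")
        assert vp.sequence == ref == "MK"
        assert not vp.has_novelty
        assert tr.digest_kmers(vp) == []

    def test_frameshift_flag_matches_length_rule_on_generated_events(self):
        cfg = sd.SimulationConfig(seed=6, n_genes=20, n_events=20,
                                  fraction_differential=1.0,
                                  n_planted_binders=0, n_planted_ms_exclusive=0)
        truth = sd.simulate_truth(cfg)
        by_gene = {}
        for t in truth.transcripts:
            by_gene.setdefault(t.gene_id, []).append(t)
        for ev in truth.events:
            t = by_gene[ev.gene_id][0]
            vp, _ = tr.translate_variant(ev, t, truth.genome, variant_form="exclusion")
            cassette_len = ev.exon[1] - ev.exon[0]
            expected = "frameshift" if cassette_len % 3 else "in_frame"
            assert vp.frame_status == expected

    def test_in_frame_round_trip(self):
        """Re-inserting the cassette reproduces the reference protein exactly."""
        genome, t, ev = _toy_gene("+")
        vp_inc, ref = tr.translate_variant(ev, t, genome, variant_form="inclusion")
        assert vp_inc.sequence == ref


class TestDigestAndSelf:
    def _vp(self, seq, lo, hi, junction=None, frame="in_frame"):
        return VariantProtein(
            event_id="e", transcript_id="t", sequence=seq,
            frame_status=frame, junction_residue=junction if junction is not None else lo,
            novel_region=(lo, hi),
        )

    def test_single_novel_residue_window_count(self):
        seq = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL"  # 30-mer
        j = 15
        vp = self._vp(seq, j, j + 1, junction=j)
        recs = tr.digest_kmers(vp, (9, 9))
        # 9 distinct windows overlap position 15 for k=9 (starts 7..15)
        assert len(recs) == 9
        assert all(r.spans_junction for r in recs)

    def test_counts_match_window_oracle_for_frameshift_tail(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=40))
        vp = self._vp(seq, 20, 40, junction=20, frame="frameshift")
        got = {r.sequence for r in tr.digest_kmers(vp, (8, 11))}
        assert got == oracle_windows(seq, 20, 40, 8, 11)

    def test_empty_novel_region_emits_nothing(self):
        vp = self._vp("ACDEFGHIKLMNP", 5, 5)
        assert tr.digest_kmers(vp) == []

    def test_short_protein_emits_nothing(self):
        vp = self._vp("ACDEFGH", 0, 7)
        assert tr.digest_kmers(vp) == []

    def test_nonstandard_residues_excluded(self):
        vp = self._vp("ACDEFGHXKLMNP", 0, 13)
        assert all("X" not in r.sequence for r in tr.digest_kmers(vp))

    def test_filter_self_exact_substring(self):
        proteome = {"p1": "MKLVACDEFGHIKW"}
        vp = self._vp("ACDEFGHIKLMNPQR", 0, 15)
        kmers = tr.digest_kmers(vp, (9, 9))
        novel, hits = tr.filter_self(kmers, proteome)
        assert {h.sequence for h in hits} == {"ACDEFGHIK"}
        assert all(h.self_hit for h in hits)
        assert all(not n.self_hit for n in novel)

    def test_dedup_and_order_invariance(self, small_truth):
        from spliceneo.pipeline import collect_neopeptides
        from spliceneo.events import apply_filters, test_all_events as run_differential_tests

        counts = sd.simulate_junction_counts(small_truth)
        tested, _ = run_differential_tests(small_truth.events, counts)
        filtered = apply_filters(tested, counts, small_truth.tpm)
        fwd, _ = collect_neopeptides(filtered, small_truth, (8, 11))
        rev, _ = collect_neopeptides(filtered[::-1], small_truth, (8, 11))
        assert sorted(r.sequence for r in fwd) == sorted(r.sequence for r in rev)
        assert len({r.sequence for r in fwd}) == len(fwd)

    def test_novel_region_emission_converges_with_full_protein_emission(self, small_truth):
        """After self subtraction, digesting only the novel region equals
        digesting the entire variant protein (the proteome removes the rest)."""
        by_gene = {}
        for t in small_truth.transcripts:
            by_gene.setdefault(t.gene_id, []).append(t)
        checked = 0
        for ev in small_truth.events:
            truth = small_truth.event_truth[ev.event_id]
            if not truth["differential"]:
                continue
            t = tr.select_transcript(ev, by_gene[ev.gene_id])
            vp, _ = tr.translate_variant(ev, t, small_truth.genome,
                                         variant_form=truth["variant_form"])
            if not vp.has_novelty:
                continue
            novel_only, _ = tr.filter_self(tr.digest_kmers(vp), small_truth.proteome)
            full = VariantProtein(
                event_id=vp.event_id, transcript_id=vp.transcript_id,
                sequence=vp.sequence, frame_status=vp.frame_status,
                junction_residue=vp.junction_residue,
                novel_region=(0, len(vp.sequence)),
            )
            full_novel, _ = tr.filter_self(tr.digest_kmers(full), small_truth.proteome)
            assert {r.sequence for r in novel_only} == {r.sequence for r in full_novel}
            checked += 1
        assert checked >= 3
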