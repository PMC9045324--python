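"""Anchor finding, synteny chaining, event classification and SNP calling."""

import numpy as np
import pytest

from linrep.compare import (
    SnpCall,
    call_snps,
    chain_blocks,
    classify_events,
    classify_snp_effect,
    export_dotplot,
    find_anchors,
)
from linrep.io import FeatureRecord, reverse_complement
from linrep.simulate import PlannedEvent, apply_events, generate_replicon, sample_events


def pipeline(a, b, **kw):
    anchors = find_anchors(a, b, k=kw.pop("k", 21))
    return chain_blocks(anchors, a, b, **kw)


class TestFindAnchors:
    def test_identity_single_forward_anchor(self, small_replicon):
        a = small_replicon.sequence[:3000]
        anchors = find_anchors(a, a, k=21)
        assert len(anchors) == 1
        an = anchors[0]
        assert (an.pos_a, an.pos_b, an.length, an.orientation) == (0, 0, 3000, "forward")

    def test_reverse_complement_single_reverse_anchor(self, small_replicon):
        a = small_replicon.sequence[:3000]
        b = reverse_complement(a)
        anchors = find_anchors(a, b, k=21)
        assert len(anchors) == 1
        an = anchors[0]
        assert an.orientation == "reverse"
        assert (an.pos_a, an.pos_b, an.length) == (0, 0, 3000)
        assert a[an.pos_a: an.pos_a + an.length] == reverse_complement(
            b[an.pos_b: an.pos_b + an.length]
        )

    def test_inversion_fixture_layout(self, small_replicon):
        a = small_replicon.sequence[:10_000]
        b = a[:4000] + reverse_complement(a[4000:7000]) + a[7000:]
        anchors = find_anchors(a, b, k=21)
        orientations = [an.orientation for an in anchors]
        assert orientations.count("reverse") == 1
        rev = next(an for an in anchors if an.orientation == "reverse")
        assert abs(rev.pos_a - 4000) <= 21 and abs(rev.length - 3000) <= 42

    def test_k_larger_than_sequence_raises(self):
        with pytest.raises(ValueError):
            find_anchors("ACGT", "ACGT", k=10)

    def test_repeated_kmers_yield_no_anchor(self):
        a = "ACGT" * 50
        assert find_anchors(a, a, k=8) == []


class TestChainBlocks:
    def test_identity_one_block_identity_one(self, small_replicon):
        a = small_replicon.sequence
        blocks = pipeline(a, a)
        assert len(blocks) == 1
        blk = blocks[0]
        assert (blk.a_start, blk.a_end, blk.b_start, blk.b_end) == (0, len(a), 0, len(a))
        assert blk.identity == 1.0

    def test_insertion_splits_into_two_blocks(self, small_replicon):
        a = small_replicon.sequence
        der, _ = apply_events(
            generate_replicon(len(a), 0.72, 11, "fix30k"),
            [PlannedEvent("insertion", 15_000, length=6708)],
            seed=5,
        )
        blocks = pipeline(a, der.sequence)
        assert len(blocks) == 2
        gap_b = blocks[1].b_start - blocks[0].b_end
        gap_a = blocks[1].a_start - blocks[0].a_end
        assert gap_b - gap_a == 6708

    def test_inversion_fixture_three_blocks_middle_reverse(self, small_replicon):
        a = small_replicon.sequence[:10_000]
        b = a[:4000] + reverse_complement(a[4000:7000]) + a[7000:]
        blocks = pipeline(a, b)
        assert [blk.orientation for blk in blocks] == ["forward", "reverse", "forward"]


class TestClassifyEvents:
    def test_self_comparison_no_events_no_snps(self, small_replicon):
        a = small_replicon.sequence
        blocks = pipeline(a, a)
        assert classify_events(blocks, a, a) == []
        assert call_snps(blocks, a, a) == []

    def test_small_insertion_worked_example(self, rng):
        # b = a with "CCC" inserted after base 5 (1-based); scaled-down k
        a = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 60)])
        b = a[:5] + "CCC" + a[5:]
        blocks = pipeline(a, b, k=8, min_block=4, indel_cap=2)
        events = classify_events(blocks, a, b, min_event=3)
        assert len(events) == 1
        ev = events[0]
        assert ev.type == "insertion"
        assert ev.a_locus == 5 and ev.length == 3
        assert ev.b_interval == (6, 8)  # first inserted base is b position 6

    def test_insertion_deletion_inversion_translocation_roundtrip(self):
        recovered = 0
        for run in range(12):
            rng = np.random.default_rng(400 + run)
            ref = generate_replicon(30_000, 0.72, 500 + run, "ref")
            planned = sample_events(30_000, rng, n_events=2)
            derived, truth = apply_events(ref, planned, seed=600 + run)
            a, b = ref.sequence, derived.sequence
            events = classify_events(pipeline(a, b), a, b)
            ok = len(events) == len(truth.events) and all(
                any(
                    e.type == t.type and abs(e.a_locus - t.a_locus) <= 21
                    for e in events
                )
                for t in truth.events
            )
            recovered += ok
        assert recovered == 12

    def test_donor_copy_insertion_is_a_duplication(self):
        ref = generate_replicon(50_000, 0.72, 31, "r")
        der, _ = apply_events(
            ref,
            [PlannedEvent("insertion", 30_000, length=2000, donor_interval=(10_000, 12_000))],
        )
        events = classify_events(pipeline(ref.sequence, der.sequence), ref.sequence, der.sequence)
        assert [e.type for e in events] == ["duplication"]
        assert abs(events[0].a_locus - 10_001) <= 21

    def test_swapping_sequences_mirrors_indels_fixes_inversions(self):
        ref = generate_replicon(40_000, 0.72, 41, "r")
        der, _ = apply_events(
            ref,
            [
                PlannedEvent("insertion", 10_000, length=1500),
                PlannedEvent("inversion", 25_000, length=2000),
            ],
            seed=42,
        )
        a, b = ref.sequence, der.sequence
        ab = classify_events(pipeline(a, b), a, b)
        ba = classify_events(pipeline(b, a), b, a)
        assert sorted(e.type for e in ab) == ["insertion", "inversion"]
        assert sorted(e.type for e in ba) == ["deletion", "inversion"]
        ins = next(e for e in ab if e.type == "insertion")
        dele = next(e for e in ba if e.type == "deletion")
        assert abs(dele.a_locus - ins.b_interval[0]) <= 21

    def test_alignment_audit_covers_both_sequences(self):
        ref = generate_replicon(30_000, 0.72, 61, "r")
        rng = np.random.default_rng(62)
        derived, _ = apply_events(ref, sample_events(30_000, rng, n_events=2), seed=63)
        a, b = ref.sequence, derived.sequence
        blocks = pipeline(a, b)
        events = classify_events(blocks, a, b)
        covered_a = sum(bl.a_span for bl in blocks) + sum(
            e.length for e in events if e.type == "deletion"
        )
        covered_b = sum(bl.b_span for bl in blocks) + sum(
            e.length for e in events if e.type in ("insertion", "duplication")
        )
        assert covered_a >= 0.99 * len(a)
        assert covered_b >= 0.99 * len(b)


class TestCallSnps:
    def test_single_substitution_recovered(self, small_replicon):
        a = small_replicon.sequence
        der, truth = apply_events(
            generate_replicon(len(a), 0.72, 11, "fix30k"),
            [PlannedEvent("substitution", 12_345)],
            seed=9,
        )
        calls = call_snps(pipeline(a, der.sequence), a, der.sequence)
        assert len(calls) == 1
        pos, pos_b, ref_b, alt_b = truth.substitutions[0]
        assert (calls[0].pos_a, calls[0].ref_base, calls[0].alt_base) == (pos, ref_b, alt_b)
        assert calls[0].pos_b == pos_b

    def test_planted_substitutions_and_indels_recovered_exactly(self):
        ref = generate_replicon(60_000, 0.72, 13, "p")
        rng = np.random.default_rng(14)
        pos = np.sort(rng.choice(np.arange(3000, 57_000), size=8, replace=False))
        events = [PlannedEvent("substitution", int(p)) for p in pos[:6]] + [
            PlannedEvent("deletion", int(p), length=1) for p in pos[6:]
        ]
        derived, truth = apply_events(ref, events, seed=15)
        calls = call_snps(
            pipeline(ref.sequence, derived.sequence), ref.sequence, derived.sequence
        )
        subs = {(c.pos_a, c.ref_base, c.alt_base) for c in calls if not c.is_indel}
        assert subs == {(p, r, x) for p, _pb, r, x in truth.substitutions}
        indels = sorted(c.pos_a for c in calls if c.is_indel)
        assert indels == sorted(e.a_locus for e in truth.events)


class TestSnpEffect:
    # CDS on + strand from 11..22 (1-based): codons GCT ATG TAA would stop;
    # use GCT GAT GGT CAT -> Ala Asp Gly His
    SEQ = "A" * 10 + "GCTGATGGTCAT" + "A" * 10
    CDS = [FeatureRecord("r", 11, 22, "+", "CDS", "some protein", "other")]

    def test_synonymous_third_position(self):
        call = SnpCall(pos_a=13, pos_b=13, ref_base="T", alt_base="C")  # GCT->GCC
        assert classify_snp_effect(call, self.CDS, self.SEQ) == "synonymous"

    def test_missense(self):
        call = SnpCall(pos_a=14, pos_b=14, ref_base="G", alt_base="C")  # GAT->CAT
        assert classify_snp_effect(call, self.CDS, self.SEQ) == "missense"

    def test_nonsense(self):
        # GAT -> TAT? no; make TAA: position 14 G->T, 15 A->A.. use GGT codon:
        # codon 3 GGT at 17..19; G->T at 17 gives TGT (Cys) missense;
        # TAT..; simplest: codon 2 GAT: G->T -> TAT (Tyr) missense. Use TAA:
        # mutate codon2 to TAA needs 2 changes; instead codon GAT pos16 T->A
        # gives GAA (Glu). For a stop, mutate codon4 CAT pos20 C->T -> TAT no.
        # Codon GGT pos18 G->A -> GAT no. Use dedicated sequence with TGG:
        seq = "A" * 10 + "GCTTGGCAT" + "A" * 10
        cds = [FeatureRecord("r", 11, 19, "+", "CDS", "p", "other")]
        call = SnpCall(pos_a=16, pos_b=16, ref_base="G", alt_base="A")  # TGG->TGA
        assert classify_snp_effect(call, cds, seq) == "nonsense"

    def test_minus_strand_synonymous(self):
        # CDS on - strand: top-strand 11..19 AGCCATAGC; coding = revcomp =
        # GCT ATG GCT.  Third codon GCT: wobble base is top-strand pos 11.
        seq = "A" * 10 + "AGCCATAGC" + "A" * 10
        cds = [FeatureRecord("r", 11, 19, "-", "CDS", "p", "other")]
        call = SnpCall(pos_a=11, pos_b=11, ref_base="A", alt_base="G")  # GCT->GCC
        assert classify_snp_effect(call, cds, seq) == "synonymous"

    def test_frameshift_and_inframe_indels(self):
        one = SnpCall(pos_a=14, pos_b=13, ref_base="G", alt_base="-")
        three = SnpCall(pos_a=14, pos_b=13, ref_base="GAT", alt_base="-")
        assert classify_snp_effect(one, self.CDS, self.SEQ) == "frameshift"
        assert classify_snp_effect(three, self.CDS, self.SEQ) == "indel_inframe"

    def test_intergenic(self):
        call = SnpCall(pos_a=3, pos_b=3, ref_base="A", alt_base="G")
        assert classify_snp_effect(call, self.CDS, self.SEQ) == "intergenic"

    def test_cds_length_not_multiple_of_three_warns(self):
        cds = [FeatureRecord("r", 11, 21, "+", "CDS", "p", "other")]
        call = SnpCall(pos_a=13, pos_b=13, ref_base="T", alt_base="C")
        with pytest.warns(UserWarning, match="divisible by 3"):
            classify_snp_effect(call, cds, self.SEQ)


class TestDotplot:
    def test_identity_single_diagonal(self, tmp_path, small_replicon):
        a = small_replicon.sequence[:2000]
        df = export_dotplot(find_anchors(a, a, k=21), tmp_path / "dots.tsv")
        assert len(df) == 1
        assert df.iloc[0].pos_a == df.iloc[0].pos_b == 1
        assert df.iloc[0].orientation == "forward"

    def test_inversion_antidiagonal_rows(self, tmp_path, small_replicon):
        a = small_replicon.sequence[:6000]
        b = a[:2000] + reverse_complement(a[2000:4000]) + a[4000:]
        df = export_dotplot(find_anchors(a, b, k=21), tmp_path / "dots.tsv")
        assert (df.orientation == "reverse").sum() == 1

    def test_empty_anchor_list_writes_header_only(self, tmp_path):
        out = tmp_path / "dots.tsv"
        df = export_dotplot([], out)
        assert df.empty
        lines = out.read_text().strip().splitlines()
        assert lines[0].startswith("#") and "pos_a" in lines[1]
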