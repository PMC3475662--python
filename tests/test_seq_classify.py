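"""Sequence diffing, micro-homology and mutation-taxonomy classification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from forkslip.seq_classify import (
    Context,
    MutationKind,
    SequenceInputError,
    classify_mutation,
    consensus_call,
    diff_single_event,
    microhomology,
    reconstruct_mutant,
    revcomp,
    spectrum_table,
    substitution_class,
    verify_reversion,
)
from forkslip.synthetic import EventSpec, plant_event

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


# ---------------------------------------------------------------------------
# oracles


def brute_force_mh(ref, anchor, size):
    """Longest match of ref[anchor..] with ref[anchor+size..], scanned
    position by position."""
    i0, m = anchor - 1, 0
    while i0 + size + m < len(ref) and ref[i0 + m] == ref[i0 + size + m]:
        m += 1
    return m


def indel_decompositions(ref, mut):
    """Every (prefix_len, segment) reproducing mut from ref by a single
    insertion or deletion, by exhaustive scan."""
    placements = []
    if len(mut) > len(ref):
        d = len(mut) - len(ref)
        for p in range(len(ref) + 1):
            if mut[:p] == ref[:p] and mut[p + d :] == ref[p:]:
                placements.append((p, mut[p : p + d]))
    elif len(ref) > len(mut):
        d = len(ref) - len(mut)
        for p in range(len(mut) + 1):
            if mut[:p] == ref[:p] and mut[p:] == ref[p + d :]:
                placements.append((p, ref[p : p + d]))
    return placements


# ---------------------------------------------------------------------------


class TestDiff:
    def test_identity(self):
        assert diff_single_event("ACGT", "ACGT").type == "none"

    def test_single_substitution(self):
        ev = diff_single_event("ACGTACGT", "ACCTACGT")
        assert (ev.type, ev.anchor, ev.ref_seg, ev.alt_seg) == (
            "substitution", 3, "G", "C",
        )

    def test_clean_deletion_left_aligned(self):
        ev = diff_single_event("AAACCCGGG", "AAAGGG")
        assert (ev.type, ev.anchor, ev.ref_seg) == ("deletion", 4, "CCC")

    def test_deletion_in_repeat_left_aligned(self):
        # deleting any single C of the run gives the same mutant; the
        # canonical anchor is the 5'-most
        ev = diff_single_event("AACCCCG", "AACCCG")
        assert (ev.type, ev.anchor, ev.ref_seg) == ("deletion", 3, "C")

    def test_multi_mismatch_is_complex(self):
        assert diff_single_event("ACGTAC", "AGGTAG").type == "complex"

    def test_non_acgt_rejected_with_positions(self):
        with pytest.raises(SequenceInputError, match=r"\[3\]"):
            diff_single_event("ACNT", "ACGT")

    @given(dna, st.integers(0, 199), st.integers(1, 30))
    def test_indel_anchor_is_leftmost_decomposition(self, ref, pos, d):
        pos = pos % len(ref)
        mut = ref[:pos] + ref[pos + d :]  # deletion of up to d nt
        if mut == ref or not mut:
            return
        ev = diff_single_event(ref, mut)
        placements = indel_decompositions(ref, mut)
        assert ev.type == "deletion"
        assert ev.anchor - 1 == min(p for p, _ in placements)
        assert (ev.anchor - 1, ev.ref_seg) in placements


class TestMicrohomology:
    def test_homopolymer_run(self):
        assert microhomology("AAAAA", 1, 1) == (4, (1, 5))

    def test_planted_motif_pair(self):
        # 5-nt motif at offsets q and q+20
        rng = np.random.default_rng(5)
        motif = "GATCC"
        ref = "".join(rng.choice(list("ACGT"), 60))
        ref = ref[:10] + motif + ref[15:30] + motif + ref[35:]
        # guard the construction: maximal match exactly 5
        if brute_force_mh(ref, 11, 20) == 5 and ref[9] != ref[29]:
            mh, placement = microhomology(ref, 11, 20)
            assert mh == 5
            assert placement == (11, 16)

    def test_not_left_aligned_rejected(self):
        with pytest.raises(ValueError, match="left-aligned"):
            microhomology("AAAAA", 2, 1)

    @given(dna, st.integers(1, 60), st.integers(1, 30))
    def test_matches_brute_force(self, ref, anchor, size):
        anchor = 1 + (anchor % len(ref))
        if anchor + size > len(ref) + 1:
            return
        if anchor > 1 and ref[anchor - 2] == ref[anchor + size - 2]:
            return
        mh, placement = microhomology(ref, anchor, size)
        assert mh == brute_force_mh(ref, anchor, size)
        assert placement == (anchor, anchor + mh)
        assert placement[1] - placement[0] == mh


class TestSubstitutionClass:
    @pytest.mark.parametrize(
        "pair,expected",
        [
            (("G", "A"), "GC->AT"),
            (("C", "T"), "GC->AT"),
            (("A", "G"), "AT->GC"),
            (("T", "C"), "AT->GC"),
            (("G", "T"), "GC->TA"),
            (("C", "A"), "GC->TA"),
            (("G", "C"), "GC->CG"),
            (("C", "G"), "GC->CG"),
            (("A", "C"), "AT->CG"),
            (("T", "G"), "AT->CG"),
            (("A", "T"), "AT->TA"),
            (("T", "A"), "AT->TA"),
        ],
    )
    def test_all_twelve_changes(self, pair, expected):
        assert substitution_class(*pair) == expected

    def test_strand_symmetry(self):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for b1 in "ACGT":
            for b2 in "ACGT":
                if b1 != b2:
                    assert substitution_class(b1, b2) == substitution_class(
                        comp[b1], comp[b2]
                    )

    def test_equal_bases_rejected(self):
        with pytest.raises(SequenceInputError):
            substitution_class("A", "A")


class TestClassify:
    def test_planted_duplication_20nt_mh5(self):
        # reference with a 5-nt motif repeated at spacing 20; the slippage
        # duplication copies the 20-nt inter-repeat unit
        rng = np.random.default_rng(11)
        while True:
            ref = "".join(rng.choice(list("ACGT"), 80))
            q0 = 30
            ref = ref[:q0 + 20] + ref[q0:q0 + 5] + ref[q0 + 25:]
            if (
                brute_force_mh(ref, q0 + 1, 20) == 5
                and ref[q0 - 1] != ref[q0 + 19]
            ):
                break
        mut = ref[: q0 + 20] + ref[q0:]
        rec = classify_mutation(ref, mut)
        assert rec.kind is MutationKind.DUPLICATION
        assert (rec.size, rec.mh_len) == (20, 5)
        assert rec.pos == q0 + 1
        assert rec.placement_range == (q0 + 1, q0 + 6)

    def test_planted_deletion_22nt_mh4(self):
        rng = np.random.default_rng(13)
        while True:
            ref = "".join(rng.choice(list("ACGT"), 80))
            q0 = 25
            ref = ref[:q0 + 22] + ref[q0:q0 + 4] + ref[q0 + 26:]
            if (
                brute_force_mh(ref, q0 + 1, 22) == 4
                and ref[q0 - 1] != ref[q0 + 21]
            ):
                break
        mut = ref[:q0] + ref[q0 + 22 :]
        rec = classify_mutation(ref, mut)
        assert rec.kind is MutationKind.DELETION
        assert (rec.size, rec.mh_len) == (22, 4)
        assert rec.pos == q0 + 1

    def test_frameshift_contexts(self):
        ref = "ACGGTACTA"
        # deletion of one G in the GG run
        rec = classify_mutation(ref, "ACGTACTA")
        assert rec.kind is MutationKind.FRAMESHIFT_DEL
        assert rec.context is Context.HOMO_RUN
        # deletion of the isolated T at pos 5
        rec = classify_mutation(ref, "ACGGACTA")
        assert rec.kind is MutationKind.FRAMESHIFT_DEL
        assert rec.context is Context.MONO
        # insertion extending the GG run
        rec = classify_mutation(ref, "ACGGGTACTA")
        assert rec.kind is MutationKind.FRAMESHIFT_INS
        assert rec.context is Context.HOMO_RUN
        # non-templated single-base insertion
        rec = classify_mutation(ref, "ACGGTAGCTA")
        assert rec.kind is MutationKind.FRAMESHIFT_INS
        assert rec.context is Context.MONO

    def test_non_tandem_insertion_is_complex(self):
        ref = "ACGTACGTACGTACGT"
        mut = ref[:8] + "TTAGG" + ref[8:]
        if ref[8:13] != "TTAGG":
            rec = classify_mutation(ref, mut)
            assert rec.kind is MutationKind.COMPLEX

    def test_canonicalization_same_record_for_equivalent_placements(self):
        # deleting either CG unit of a CGCG repeat yields the same mutant
        ref = "TTACGCGAA"
        mut1 = ref[:3] + ref[5:]   # remove first CG
        mut2 = ref[:5] + ref[7:]   # remove second CG
        assert mut1 == mut2
        rec = classify_mutation(ref, mut1)
        assert rec.pos == 4  # left-most placement
        assert rec.mh_len == 2
        assert rec.placement_range == (4, 6)

    def test_roundtrip_of_planted_events(self, reference):
        """Events planted by the generator are recovered exactly
        (kind, size, micro-homology) with the truth anchor inside the
        reported placement range."""
        ref, _ = reference
        rng = np.random.default_rng(17)
        kinds = [
            "GC->AT", "AT->GC", "GC->TA", "GC->CG", "AT->CG", "AT->TA",
            "fs_plus_homo", "fs_plus_mono", "fs_minus_homo", "fs_minus_mono",
            "deletions", "duplications",
        ]
        kind_map = {
            "fs_plus_homo": MutationKind.FRAMESHIFT_INS,
            "fs_plus_mono": MutationKind.FRAMESHIFT_INS,
            "fs_minus_homo": MutationKind.FRAMESHIFT_DEL,
            "fs_minus_mono": MutationKind.FRAMESHIFT_DEL,
            "deletions": MutationKind.DELETION,
            "duplications": MutationKind.DUPLICATION,
        }
        for i in range(300):
            kind = kinds[i % len(kinds)]
            mut, truth = plant_event(ref, EventSpec(kind), rng)
            rec = classify_mutation(ref, mut)
            assert rec.size == truth.true_size
            assert rec.mh_len == truth.true_mh, (kind, truth)
            if kind in kind_map:
                assert rec.kind is kind_map[kind]
                assert (
                    rec.placement_range[0]
                    <= truth.true_pos
                    <= rec.placement_range[1]
                )
            else:
                assert rec.kind is MutationKind.SUBSTITUTION
                assert rec.sub_class == kind
                assert rec.pos == truth.true_pos
            # reconstructing from the record reproduces the mutant
            assert reconstruct_mutant(ref, rec) == mut


class TestConsensusAndSpectrum:
    def test_consensus_identical_and_disjoint(self):
        ref = "ACGTACGTAA"
        r1 = classify_mutation(ref, "ACCTACGTAA")
        r2 = classify_mutation(ref, "ACGTACTTAA")
        assert consensus_call([r1, r2], [r1, r2]) == [r1, r2]
        assert consensus_call([r1], [r2]) == []
        assert consensus_call([r1, r2], [r2]) == [r2]

    def test_consensus_maps_reverse_strand_records(self):
        ref = "TTACGCGAATCGGAT"
        mut = ref[:3] + ref[5:]
        fwd = classify_mutation(ref, mut)
        rev = classify_mutation(revcomp(ref), revcomp(mut))
        assert consensus_call([fwd], [rev], ref=ref) == [fwd]

    def test_spectrum_counts_and_permutation_invariance(self):
        ref = "ACGGTACTAACGGTACTA"
        muts = ["CCGGTACTAACGGTACTA", "ACGTACTAACGGTACTA", "ACGGTACTAACGGTACTT"]
        records = [classify_mutation(ref, m) for m in muts]
        t1 = spectrum_table(records, "s", "ON")
        t2 = spectrum_table(records[::-1], "s", "ON")
        assert t1.counts == t2.counts
        assert t1.total == 3

    def test_empty_spectrum(self):
        assert spectrum_table([], "s", "ON").total == 0

    def test_spectrum_strand_symmetry(self, reference):
        """Substitution-class counts are identical when every (ref, mut)
        pair is reverse complemented."""
        ref, _ = reference
        rng = np.random.default_rng(23)
        muts = [
            plant_event(ref, EventSpec(k), rng)[0]
            for k in ("GC->AT", "AT->GC", "GC->TA", "GC->CG", "AT->CG", "AT->TA")
            for _ in range(5)
        ]
        fwd = spectrum_table([classify_mutation(ref, m) for m in muts], "s", "ON")
        rc = spectrum_table(
            [classify_mutation(revcomp(ref), revcomp(m)) for m in muts], "s", "ON"
        )
        for cls in ("GC->AT", "AT->GC", "GC->TA", "GC->CG", "AT->CG", "AT->TA"):
            assert fwd.counts[cls] == rc.counts[cls]


class TestReversion:
    def test_wild_type_revertant(self, reference):
        ref, _ = reference
        allele, _ = plant_event(ref, EventSpec("duplications"), np.random.default_rng(1))
        assert verify_reversion(ref, allele, ref)
        assert not verify_reversion(ref, allele, allele)

    def test_constructed_reversion_of_duplication(self, reference):
        ref, _ = reference
        allele, truth = plant_event(
            ref, EventSpec("duplications", size=20), np.random.default_rng(2)
        )
        rec = classify_mutation(ref, allele)
        # delete the duplicated copy from the allele
        i0 = rec.pos - 1
        revertant = allele[:i0] + allele[i0 + rec.size :]
        assert verify_reversion(ref, allele, revertant)
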