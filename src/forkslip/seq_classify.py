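"""Mutation classification against a reference ORF.

A mutant allele is compared with the reference coding sequence and reduced
to a single canonical event: a base substitution, a +/-1 frameshift, a
deletion or tandem duplication of two or more nucleotides, or a complex
change.  Indels are left-aligned (5'-most equivalent placement on the
forward strand of the reference) and annotated with the length of the
flanking direct repeat (micro-homology), the signature of replication
slippage: when nascent strands dissociate from the template and re-anneal
at a nearby short repeat, the intervening segment is deleted or duplicated
and the mediating repeat flanks the event.

Coordinates are 1-based and inclusive on the reference forward strand.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "MutationKind",
    "Context",
    "RawEvent",
    "MutationRecord",
    "SpectrumTable",
    "SequenceInputError",
    "SUBSTITUTION_CLASSES",
    "SPECTRUM_CATEGORIES",
    "revcomp",
    "diff_single_event",
    "microhomology",
    "substitution_class",
    "classify_mutation",
    "reconstruct_mutant",
    "map_to_forward",
    "consensus_call",
    "spectrum_table",
    "verify_reversion",
]

NUCLEOTIDES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SequenceInputError(ValueError):
    """Raised for sequences outside the A/C/G/T alphabet or empty input."""


class MutationKind(str, Enum):
    SUBSTITUTION = "substitution"
    FRAMESHIFT_INS = "frameshift_ins"
    FRAMESHIFT_DEL = "frameshift_del"
    DELETION = "deletion"
    DUPLICATION = "duplication"
    COMPLEX = "complex"


class Context(str, Enum):
    """Sequence context of a +/-1 frameshift.

    HOMO_RUN: the indel sits in a reference run of >= 2 identical bases
    (homo-nucleotide slippage); MONO: an isolated base; NA: not a
    frameshift.
    """

    HOMO_RUN = "homo_run"
    MONO = "mono"
    NA = "n_a"


#: Strand-agnostic base-pair substitution classes.  The first two are
#: transitions, the remaining four transversions.
SUBSTITUTION_CLASSES = (
    "GC->AT",
    "AT->GC",
    "GC->TA",
    "GC->CG",
    "AT->CG",
    "AT->TA",
)

#: Category keys of a mutation spectrum table.
SPECTRUM_CATEGORIES = SUBSTITUTION_CLASSES + (
    "fs_plus_homo",
    "fs_plus_mono",
    "fs_minus_homo",
    "fs_minus_mono",
    "deletions",
    "duplications",
    "complex",
)


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_sequence(seq: str, name: str) -> str:
    if not seq:
        raise SequenceInputError(f"{name}: empty sequence")
    seq = seq.upper()
    bad = [i + 1 for i, ch in enumerate(seq) if ch not in NUCLEOTIDES]
    if bad:
        raise SequenceInputError(
            f"{name}: non-ACGT characters at positions {bad[:20]}"
        )
    return seq


@dataclass(frozen=True)
class RawEvent:
    """Minimal description of the difference between two sequences.

    ``type`` is one of ``substitution``, ``insertion``, ``deletion``,
    ``none`` or ``complex``.  ``anchor`` is the 1-based, left-aligned
    position on the reference: for a substitution the changed base, for a
    deletion the first deleted base, for an insertion the reference base
    before which the segment is inserted.
    """

    type: str
    anchor: int
    ref_seg: str
    alt_seg: str


@dataclass(frozen=True)
class MutationRecord:
    """One classified sequence change in reference coordinates."""

    kind: MutationKind
    pos: int
    ref_seg: str
    alt_seg: str
    size: int
    mh_len: int
    placement_range: tuple[int, int]
    context: Context = Context.NA
    sub_class: str = "n/a"

    @property
    def key(self) -> tuple:
        return (self.kind, self.pos, self.ref_seg, self.alt_seg)


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _common_suffix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[len(a) - 1 - i] == b[len(b) - 1 - i]:
        i += 1
    return i


def diff_single_event(ref: str, mut: str) -> RawEvent:
    """Reduce a (reference, mutant) pair to one raw event.

    Equal-length sequences with a single mismatch give a substitution; a
    pure length difference whose middle segment is empty on the shorter
    side gives an insertion or deletion anchored at the left-most
    equivalent placement; identical sequences give ``none``; anything
    else is ``complex``.
    """
    ref = _validate_sequence(ref, "ref")
    mut = _validate_sequence(mut, "mut")
    if ref == mut:
        return RawEvent("none", 0, "", "")

    p = _common_prefix_len(ref, mut)
    s = _common_suffix_len(ref, mut)
    min_len = min(len(ref), len(mut))
    # p and s may overlap when the event sits inside a repeat; the set of
    # equivalent placements corresponds to prefix lengths in
    # [max(0, min_len - s), min(p, min_len)].
    s = min(s, min_len)
    left = max(min_len - s, 0)

    if len(ref) == len(mut):
        if p + s == len(ref) - 1:
            return RawEvent("substitution", p + 1, ref[p], mut[p])
        return RawEvent("complex", p + 1, ref[p : len(ref) - s], mut[p : len(mut) - s])

    d = abs(len(ref) - len(mut))
    if p + s >= min_len:  # pure indel
        if len(mut) > len(ref):
            return RawEvent("insertion", left + 1, "", mut[left : left + d])
        return RawEvent("deletion", left + 1, ref[left : left + d], "")
    return RawEvent("complex", p + 1, ref[p : len(ref) - s], mut[p : len(mut) - s])


def microhomology(ref: str, anchor: int, size: int) -> tuple[int, tuple[int, int]]:
    """Flanking direct-repeat length for an indel spanning ``size`` nt.

    ``anchor`` is the 1-based, left-aligned start of the affected
    reference segment.  Returns ``(mh_len, placement_range)`` where
    ``mh_len`` is the longest ``m`` with
    ``ref[anchor .. anchor+m-1] == ref[anchor+size .. anchor+size+m-1]``
    and ``placement_range`` is the inclusive interval
    ``[anchor, anchor + mh_len]`` of equivalent left anchors.
    """
    ref = _validate_sequence(ref, "ref")
    if not 1 <= anchor or anchor + size > len(ref) + 1:
        raise ValueError(f"anchor {anchor} with size {size} out of bounds")
    if anchor > 1 and ref[anchor - 2] == ref[anchor + size - 2]:
        raise ValueError(
            f"anchor {anchor} is not left-aligned: the event can shift left"
        )
    i0 = anchor - 1
    m = 0
    n = len(ref)
    while i0 + size + m < n and ref[i0 + m] == ref[i0 + size + m]:
        m += 1
    return m, (anchor, anchor + m)


_PURINE_ANCHOR = {"C": True, "T": True}


def substitution_class(ref_base: str, alt_base: str) -> str:
    """Strand-agnostic base-pair class of a substitution, e.g. ``GC->AT``.

    The class of ``b1 -> b2`` equals the class of
    ``complement(b1) -> complement(b2)``.
    """
    ref_base = ref_base.upper()
    alt_base = alt_base.upper()
    if ref_base not in NUCLEOTIDES or alt_base not in NUCLEOTIDES:
        raise SequenceInputError(f"invalid bases {ref_base!r}->{alt_base!r}")
    if ref_base == alt_base:
        raise SequenceInputError("substitution requires two different bases")
    if ref_base in _PURINE_ANCHOR:  # normalise to the G/A-containing strand
        ref_base = ref_base.translate(_COMPLEMENT)
        alt_base = alt_base.translate(_COMPLEMENT)
    return {
        ("G", "A"): "GC->AT",
        ("A", "G"): "AT->GC",
        ("G", "T"): "GC->TA",
        ("G", "C"): "GC->CG",
        ("A", "C"): "AT->CG",
        ("A", "T"): "AT->TA",
    }[(ref_base, alt_base)]


def classify_mutation(ref: str, mut: str) -> MutationRecord:
    """Classify a mutant allele into the mutation taxonomy.

    Size-1 indels are frameshifts (homo-nucleotide context when they sit
    in a reference run of >= 2 identical bases); indels of >= 2 nt are
    deletions or, for insertions that tandemly copy the adjacent
    reference segment, duplications.  Non-tandem multi-base insertions
    and multi-mismatch changes are complex.
    """
    raw = diff_single_event(ref, mut)
    ref = ref.upper()

    if raw.type == "none":
        raise SequenceInputError("sequences are identical: no event to classify")

    if raw.type == "substitution":
        return MutationRecord(
            kind=MutationKind.SUBSTITUTION,
            pos=raw.anchor,
            ref_seg=raw.ref_seg,
            alt_seg=raw.alt_seg,
            size=1,
            mh_len=0,
            placement_range=(raw.anchor, raw.anchor),
            context=Context.NA,
            sub_class=substitution_class(raw.ref_seg, raw.alt_seg),
        )

    if raw.type == "complex":
        return MutationRecord(
            kind=MutationKind.COMPLEX,
            pos=raw.anchor,
            ref_seg=raw.ref_seg,
            alt_seg=raw.alt_seg,
            size=max(len(raw.ref_seg), len(raw.alt_seg)),
            mh_len=0,
            placement_range=(raw.anchor, raw.anchor),
        )

    d = max(len(raw.ref_seg), len(raw.alt_seg))
    i0 = raw.anchor - 1

    if raw.type == "deletion":
        mh, placement = microhomology(ref, raw.anchor, d)
        if d == 1:
            context = Context.HOMO_RUN if mh >= 1 else Context.MONO
            kind = MutationKind.FRAMESHIFT_DEL
        else:
            context = Context.NA
            kind = MutationKind.DELETION
        return MutationRecord(
            kind=kind,
            pos=raw.anchor,
            ref_seg=raw.ref_seg,
            alt_seg="",
            size=d,
            mh_len=mh,
            placement_range=placement,
            context=context,
        )

    # insertion
    tandem = ref[i0 : i0 + d] == raw.alt_seg
    if tandem:
        # For a tandem copy the flanking repeat is measured on the
        # reference frame; the left-aligned insertion anchor satisfies the
        # left-alignment contract of `microhomology` because the base
        # preceding the anchor differs from the last inserted base.
        mh, placement = microhomology(ref, raw.anchor, d)
    else:
        mh, placement = 0, (raw.anchor, raw.anchor)
    if d == 1:
        context = Context.HOMO_RUN if (tandem and mh >= 1) else Context.MONO
        kind = MutationKind.FRAMESHIFT_INS
    elif tandem:
        context = Context.NA
        kind = MutationKind.DUPLICATION
    else:
        context = Context.NA
        kind = MutationKind.COMPLEX
    return MutationRecord(
        kind=kind,
        pos=raw.anchor,
        ref_seg="",
        alt_seg=raw.alt_seg,
        size=d,
        mh_len=mh,
        placement_range=placement,
        context=context,
    )


def reconstruct_mutant(ref: str, record: MutationRecord) -> str:
    """Apply a classified event to the reference and return the mutant."""
    ref = _validate_sequence(ref, "ref")
    i0 = record.pos - 1
    if record.kind is MutationKind.SUBSTITUTION:
        return ref[:i0] + record.alt_seg + ref[i0 + 1 :]
    if record.kind in (MutationKind.DELETION, MutationKind.FRAMESHIFT_DEL):
        return ref[:i0] + ref[i0 + record.size :]
    if record.kind in (MutationKind.DUPLICATION, MutationKind.FRAMESHIFT_INS):
        return ref[:i0] + record.alt_seg + ref[i0:]
    # complex: replace the differing middle segment
    return ref[:i0] + record.alt_seg + ref[i0 + len(record.ref_seg) :]


def map_to_forward(record: MutationRecord, ref: str) -> MutationRecord:
    """Re-express a record classified against revcomp(ref) in forward
    coordinates, re-canonicalising the placement."""
    mut_rc = reconstruct_mutant(revcomp(ref), record)
    return classify_mutation(ref, revcomp(mut_rc))


def consensus_call(
    diffs_forward: Iterable[MutationRecord],
    diffs_reverse: Iterable[MutationRecord],
    ref: Optional[str] = None,
) -> list[MutationRecord]:
    """Keep only mutations confirmed on both sequencing strands.

    ``diffs_reverse`` may be classified against the reverse complement of
    the reference; pass ``ref`` to map them to forward coordinates before
    intersecting on (kind, position, segments).
    """
    forward = list(diffs_forward)
    if ref is not None:
        reverse = [map_to_forward(r, ref) for r in diffs_reverse]
    else:
        reverse = list(diffs_reverse)
    reverse_keys = {r.key for r in reverse}
    return [r for r in forward if r.key in reverse_keys]


@dataclass
class SpectrumTable:
    """Per-category event counts for one strain and barrier condition."""

    strain_id: str
    condition: str
    counts: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def fractions(self) -> dict[str, float]:
        total = self.total
        if total == 0:
            raise ValueError("empty spectrum has no fractions")
        return {c: self.counts.get(c, 0) / total for c in SPECTRUM_CATEGORIES}


def _category(record: MutationRecord) -> str:
    if record.kind is MutationKind.SUBSTITUTION:
        return record.sub_class
    if record.kind is MutationKind.FRAMESHIFT_INS:
        return "fs_plus_homo" if record.context is Context.HOMO_RUN else "fs_plus_mono"
    if record.kind is MutationKind.FRAMESHIFT_DEL:
        return "fs_minus_homo" if record.context is Context.HOMO_RUN else "fs_minus_mono"
    if record.kind is MutationKind.DELETION:
        return "deletions"
    if record.kind is MutationKind.DUPLICATION:
        return "duplications"
    return "complex"


def spectrum_table(
    records: Iterable[MutationRecord], strain_id: str, condition: str
) -> SpectrumTable:
    """Tabulate classified events into a mutation-spectrum table."""
    table = SpectrumTable(strain_id=strain_id, condition=str(condition))
    for record in records:
        table.counts[_category(record)] += 1
    return table


def verify_reversion(wild_ref: str, allele_seq: str, revertant_seq: str) -> bool:
    """True iff a revertant restored the exact wild-type sequence.

    Used in reverse-mutation assays: a slippage-derived duplication
    allele reverts to functionality only by precise loss of the
    duplicated segment, which this check makes explicit by requiring
    base identity over the full ORF.
    """
    wild_ref = _validate_sequence(wild_ref, "wild_ref")
    allele_seq = _validate_sequence(allele_seq, "allele_seq")
    revertant_seq = _validate_sequence(revertant_seq, "revertant_seq")
    if allele_seq == wild_ref:
        raise SequenceInputError("allele does not differ from the wild-type ORF")
    return revertant_seq == wild_ref
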