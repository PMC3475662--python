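"""Colony-level event calling from PCR amplification patterns.

Each selected colony is scored with three PCRs: the target locus
(*ura4*), an essential control locus (*rng3*) that must always amplify,
and the predicted translocation junction.  Loss of the target locus with
an intact control is a genomic deletion; a junction product is a
translocation; an amplifiable target is routed to sequencing for point
mutation classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .seq_classify import SequenceInputError, _validate_sequence, revcomp

__all__ = [
    "ColonyAssay",
    "EventClass",
    "AmbiguousPrimerError",
    "classify_colony",
    "predict_amplicon",
]

MIN_PRIMER_LENGTH = 15


class EventClass(str, Enum):
    DELETION = "deletion"
    TRANSLOCATION = "translocation"
    POINT_MUTATION_CANDIDATE = "point_mutation_candidate"
    INVALID = "invalid"


class AmbiguousPrimerError(ValueError):
    """A primer has more than one exact site on the template."""


@dataclass
class ColonyAssay:
    """PCR amplification flags (and optional sequence) for one colony."""

    colony_id: str
    ura4_amplified: bool
    rng3_amplified: bool
    tl_junction_amplified: bool
    ura4_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ura4_sequence is not None and not self.ura4_amplified:
            raise ValueError(
                f"colony {self.colony_id}: a ura4 sequence implies ura4 amplified"
            )


def classify_colony(assay: ColonyAssay) -> EventClass:
    """Call the event class of a colony from its amplification pattern.

    The control locus must amplify for the assay to be interpretable.  A
    translocation junction takes precedence over target-locus loss
    because the junction implies loss of the target in this construct.
    """
    if not assay.rng3_amplified:
        return EventClass.INVALID
    if assay.tl_junction_amplified:
        return EventClass.TRANSLOCATION
    if not assay.ura4_amplified:
        return EventClass.DELETION
    return EventClass.POINT_MUTATION_CANDIDATE


def _find_all(template: str, probe: str) -> list[int]:
    sites = []
    start = 0
    while True:
        i = template.find(probe, start)
        if i < 0:
            return sites
        sites.append(i)
        start = i + 1  # overlapping matches count as distinct sites


def predict_amplicon(template: str, fwd_primer: str, rev_primer: str) -> Optional[int]:
    """Predicted PCR product size in bp, or None when no product forms.

    Primer annealing is exact-match: the forward primer must occur on
    the given strand and the reverse primer on the opposite strand, in
    convergent orientation.  The product runs from the forward primer's
    5' end to the reverse primer's 5' end inclusive, so an insertion
    strictly between the primer sites lengthens the product by its size
    and a deletion overlapping a site abolishes the product.
    """
    template = _validate_sequence(template, "template")
    fwd_primer = _validate_sequence(fwd_primer, "fwd_primer")
    rev_primer = _validate_sequence(rev_primer, "rev_primer")
    if len(fwd_primer) < MIN_PRIMER_LENGTH or len(rev_primer) < MIN_PRIMER_LENGTH:
        raise SequenceInputError(
            f"primers must be >= {MIN_PRIMER_LENGTH} nt for unambiguous annealing"
        )

    fwd_sites = _find_all(template, fwd_primer)
    rev_sites = _find_all(template, revcomp(rev_primer))
    if len(fwd_sites) > 1:
        raise AmbiguousPrimerError(f"forward primer has {len(fwd_sites)} sites")
    if len(rev_sites) > 1:
        raise AmbiguousPrimerError(f"reverse primer has {len(rev_sites)} sites")
    if not fwd_sites or not rev_sites:
        return None

    i = fwd_sites[0]
    j = rev_sites[0]
    if j < i:  # divergent orientation: no exponential product
        return None
    return j + len(rev_primer) - i
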