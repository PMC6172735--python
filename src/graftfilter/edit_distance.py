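"""Edit-distance scoring of read bundles against one reference.

The edit distance of a mapped read is the sum of its soft-clipped bases and
inserted bases (both from the CIGAR string) and its NM tag value. For a read
pair the two mate distances are averaged; an unmapped mate contributes a
fixed penalty instead (default 8). Scores are exact half-integers
(:class:`fractions.Fraction`), never rounded, so downstream tie detection is
exact.

Note on NM: the SAM specification defines NM as mismatches plus inserted and
deleted bases, so the sum above counts inserted bases twice with a
spec-conforming aligner. That literal sum is the default here because it is
the published definition; ``nm_decompose=True`` subtracts CIGAR I and D bases
from NM first, yielding soft clips + insertions + mismatches only.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

from .alignment_io import AlignmentInputError, AlignmentRecord, ReadBundle, cigar_components

__all__ = ["EditDistanceScore", "record_edit_distance", "bundle_edit_distance"]


@dataclass(frozen=True)
class EditDistanceScore:
    """Edit distance of one read or read pair against one reference.

    ``value`` is an integer for single-end reads and a half-integer for pair
    averages. A bundle with no mapping at all has *no* score (``None`` at the
    call site), never a score of 0.
    """

    value: Fraction
    basis: str  # "single" | "paired"
    mate1_ed: Optional[int] = None
    mate2_ed: Optional[int] = None
    penalized_mates: int = 0

    def __post_init__(self) -> None:
        if self.basis not in ("single", "paired"):
            raise ValueError(f"invalid basis {self.basis!r}")


def record_edit_distance(record: AlignmentRecord, *, nm_decompose: bool = False) -> int:
    """Edit distance of one mapped primary record: soft clips + insertions + NM.

    With ``nm_decompose`` the CIGAR's inserted and deleted bases are removed
    from NM before summing (for aligners whose NM follows the SAM spec).
    Deletions and skipped regions (N) never contribute on their own, which is
    what keeps the score meaningful for spliced RNA alignments.
    """
    if record.is_unmapped or record.cigar is None:
        raise AlignmentInputError(
            f"edit distance of unmapped record {record.query_name!r} is undefined"
        )
    if record.nm is None:
        raise AlignmentInputError(
            f"mapped record {record.query_name!r} lacks the NM tag; "
            "edit-distance classification is undefined without it"
        )
    comps = cigar_components(record.cigar)
    nm = record.nm
    if nm_decompose:
        nm = max(0, nm - comps.inserted_bases - comps.deleted_bases)
    return comps.softclip_bases + comps.inserted_bases + nm


def bundle_edit_distance(
    bundle: ReadBundle,
    unmapped_penalty: int = 8,
    *,
    nm_decompose: bool = False,
) -> Optional[EditDistanceScore]:
    """Score one bundle against the reference its records were aligned to.

    Only primary alignments are consulted. Single-end: the primary's record
    edit distance, or no score if unmapped. Paired-end: the mean of the two
    mate distances, an unmapped (or never-output) mate counting as
    ``unmapped_penalty``; no score if neither mate maps. Mate order does not
    affect the value.
    """
    m1, m2 = bundle.primary_mate1, bundle.primary_mate2
    if m1 is None and m2 is None:
        raise AlignmentInputError(
            f"bundle {bundle.query_name!r} has no primary alignments"
        )

    paired = any(r.is_paired for r in bundle.primaries)
    if not paired:
        rec = m1 if m1 is not None else m2
        if rec.is_unmapped:
            return None
        return EditDistanceScore(
            value=Fraction(record_edit_distance(rec, nm_decompose=nm_decompose)),
            basis="single",
            mate1_ed=record_edit_distance(rec, nm_decompose=nm_decompose),
        )

    def mate_ed(rec: Optional[AlignmentRecord]) -> Optional[int]:
        # a mate absent from the BAM is indistinguishable from an unmapped one
        if rec is None or rec.is_unmapped:
            return None
        return record_edit_distance(rec, nm_decompose=nm_decompose)

    ed1, ed2 = mate_ed(m1), mate_ed(m2)
    if ed1 is None and ed2 is None:
        return None
    penalized = (ed1 is None) + (ed2 is None)
    eff1 = unmapped_penalty if ed1 is None else ed1
    eff2 = unmapped_penalty if ed2 is None else ed2
    return EditDistanceScore(
        value=Fraction(eff1 + eff2, 2),
        basis="paired",
        mate1_ed=ed1,
        mate2_ed=ed2,
        penalized_mates=penalized,
    )
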