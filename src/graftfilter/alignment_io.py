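"""SAM/BAM input, query-name collation, and output writing.

Records are carried as thin wrappers around :class:`pysam.AlignedSegment` so
that every per-record field round-trips untouched: classification needs only
the query name, flags, CIGAR and the NM tag, and everything else is opaque
payload. Input order is never assumed — :func:`collate_by_name` buffers
records until the stream ends, with a fast path for name-grouped input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pysam

__all__ = [
    "AlignmentInputError",
    "AlignmentRecord",
    "ReadBundle",
    "CigarSummary",
    "read_alignments",
    "collate_by_name",
    "cigar_components",
    "write_alignments",
]


class AlignmentInputError(ValueError):
    """Malformed or unusable alignment input (missing tags, duplicate primaries...)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AlignmentRecord:
    """One SAM/BAM line with the fields classification needs, plus the raw segment."""

    query_name: str
    is_paired: bool
    is_first_mate: bool
    is_unmapped: bool
    is_secondary: bool
    is_supplementary: bool
    reference_name: Optional[str]
    position: Optional[int]  # 1-based leftmost, SAM convention
    mapq: int
    cigar: Optional[str]
    nm: Optional[int]
    segment: pysam.AlignedSegment  # opaque payload; rewritten bit-identically

    @property
    def is_primary(self) -> bool:
        return not (self.is_secondary or self.is_supplementary)

    @classmethod
    def from_segment(cls, seg: pysam.AlignedSegment) -> "AlignmentRecord":
        nm = seg.get_tag("NM") if seg.has_tag("NM") else None
        return cls(
            query_name=seg.query_name,
            is_paired=seg.is_paired,
            is_first_mate=(not seg.is_paired) or seg.is_read1,
            is_unmapped=seg.is_unmapped,
            is_secondary=seg.is_secondary,
            is_supplementary=seg.is_supplementary,
            reference_name=None if seg.is_unmapped else seg.reference_name,
            position=None if seg.is_unmapped else seg.reference_start + 1,
            mapq=seg.mapping_quality,
            cigar=None if seg.is_unmapped else seg.cigarstring,
            nm=int(nm) if nm is not None else None,
            segment=seg,
        )


@dataclass
class ReadBundle:
    """All records sharing one query name in one BAM: the unit of classification.

    ``primary_mate1`` holds the single-end primary for unpaired data.
    Supplementary (chimeric) records ride along in ``secondaries``: like
    secondary alignments, they follow the fate of their primary.
    """

    query_name: str
    primary_mate1: Optional[AlignmentRecord] = None
    primary_mate2: Optional[AlignmentRecord] = None
    secondaries: list[AlignmentRecord] = field(default_factory=list)

    def add(self, record: AlignmentRecord) -> None:
        if record.query_name != self.query_name:
            raise AlignmentInputError(
                f"record {record.query_name!r} added to bundle {self.query_name!r}"
            )
        if not record.is_primary:
            self.secondaries.append(record)
            return
        slot = "primary_mate1" if record.is_first_mate else "primary_mate2"
        if getattr(self, slot) is not None:
            raise AlignmentInputError(
                f"duplicate primary alignment for {record.query_name!r} "
                f"(mate {1 if record.is_first_mate else 2})"
            )
        setattr(self, slot, record)

    @property
    def primaries(self) -> list[AlignmentRecord]:
        return [r for r in (self.primary_mate1, self.primary_mate2) if r is not None]

    @property
    def records(self) -> list[AlignmentRecord]:
        return self.primaries + self.secondaries

    def any_primary_mapped(self) -> bool:
        return any(not r.is_unmapped for r in self.primaries)


@dataclass(frozen=True)
class CigarSummary:
    """Per-operation-class base counts of one CIGAR string.

    Hard clips (H) and padding (P) contribute to no field: hard-clipped bases
    are absent from the record.
    """

    softclip_bases: int
    inserted_bases: int
    deleted_bases: int
    skipped_bases: int
    aligned_bases: int

    @property
    def query_consumed(self) -> int:
        return self.softclip_bases + self.inserted_bases + self.aligned_bases


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def cigar_components(cigar: str) -> CigarSummary:
    """Decompose a SAM CIGAR string into per-class base counts."""
    consumed = 0
    counts = {"S": 0, "I": 0, "D": 0, "N": 0, "M": 0}
    for m in _CIGAR_RE.finditer(cigar):
        n, op = int(m.group(1)), m.group(2)
        consumed += m.end() - m.start()
        if op in "M=X":
            counts["M"] += n
        elif op in counts:
            counts[op] += n
        # H and P contribute nothing
    if consumed != len(cigar) or not cigar:
        raise AlignmentInputError(f"unparseable CIGAR string: {cigar!r}")
    return CigarSummary(
        softclip_bases=counts["S"],
        inserted_bases=counts["I"],
        deleted_bases=counts["D"],
        skipped_bases=counts["N"],
        aligned_bases=counts["M"],
    )


def read_alignments(path: str):
    """Open a SAM/BAM file; return ``(header, record_iterator)``.

    The iterator yields :class:`AlignmentRecord` in file order. Errors carry
    the file path and the record index at which they occurred.
    """
    try:
        af = pysam.AlignmentFile(path, check_sq=False)
        header = af.header
    except (OSError, ValueError) as exc:
        raise AlignmentInputError(f"cannot read alignments from {path!r}: {exc}") from exc

    def _iter() -> Iterator[AlignmentRecord]:
        try:
            for i, seg in enumerate(af):
                try:
                    yield AlignmentRecord.from_segment(seg)
                except Exception as exc:
                    raise AlignmentInputError(
                        f"{path!r}: malformed record at index {i}: {exc}"
                    ) from exc
        finally:
            af.close()

    return header, _iter()


def collate_by_name(
    records: Iterable[AlignmentRecord], *, assume_name_grouped: bool = False
) -> Iterator[ReadBundle]:
    """Group a record stream into one :class:`ReadBundle` per query name.

    Input order is arbitrary: incomplete bundles are buffered in memory keyed
    by query name and emitted, in first-seen order, when the stream ends.
    With ``assume_name_grouped=True`` (records of each name adjacent, e.g.
    ``samtools collate`` output) each bundle is emitted as soon as the name
    changes, keeping memory flat.
    """
    if assume_name_grouped:
        current: Optional[ReadBundle] = None
        for rec in records:
            if current is None or rec.query_name != current.query_name:
                if current is not None:
                    yield current
                current = ReadBundle(query_name=rec.query_name)
            current.add(rec)
        if current is not None:
            yield current
        return

    buffer: dict[str, ReadBundle] = {}
    for rec in records:
        bundle = buffer.get(rec.query_name)
        if bundle is None:
            bundle = buffer[rec.query_name] = ReadBundle(query_name=rec.query_name)
        bundle.add(rec)
    yield from buffer.values()


def _unique_pg_id(existing: list[dict], base: str) -> str:
    ids = {pg.get("ID") for pg in existing}
    if base not in ids:
        return base
    k = 1
    while f"{base}.{k}" in ids:
        k += 1
    return f"{base}.{k}"


def write_alignments(
    path: str,
    header,
    records: Iterable[AlignmentRecord],
    program_entry: str = "",
) -> int:
    """Write records to ``path`` (BAM, or SAM if the path ends in ``.sam``).

    The input header is preserved with one @PG line appended (ID/PN/VN/CL).
    Returns the number of records written.
    """
    from . import __version__

    hdr = header.to_dict() if hasattr(header, "to_dict") else dict(header)
    pgs = list(hdr.get("PG", []))
    entry = {
        "ID": _unique_pg_id(pgs, "graftfilter"),
        "PN": "graftfilter",
        "VN": __version__,
    }
    if program_entry:
        entry["CL"] = program_entry
    if pgs and "ID" in pgs[-1]:
        entry["PP"] = pgs[-1]["ID"]
    hdr["PG"] = pgs + [entry]

    mode = "w" if str(path).endswith(".sam") else "wb"
    count = 0
    try:
        out = pysam.AlignmentFile(path, mode, header=hdr)
    except (OSError, ValueError) as exc:
        raise AlignmentInputError(f"cannot write alignments to {path!r}: {exc}") from exc
    with out:
        for rec in records:
            out.write(rec.segment)
            count += 1
    return count
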