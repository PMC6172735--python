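"""Shared fixtures: in-memory SAM record construction and tiny file writers.

All alignment fixtures are built programmatically; nothing binary is stored.
"""

from __future__ import annotations

import pysam
import pytest

from graftfilter.alignment_io import AlignmentRecord

HEADER_DICT = {"HD": {"VN": "1.6", "SO": "unknown"}, "SQ": [{"SN": "ref", "LN": 100_000}]}
HEADER = pysam.AlignmentHeader.from_dict(HEADER_DICT)

FLAG_PAIRED = 0x1
FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_MATE1 = 0x40
FLAG_MATE2 = 0x80
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


def make_segment(
    name: str,
    flag: int = 0,
    pos: int = 100,
    cigar: str | None = "100M",
    nm: int | None = 0,
    mapq: int = 60,
    read_length: int = 100,
) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(HEADER)
    seg.query_name = name
    seg.flag = flag
    if flag & FLAG_UNMAPPED:
        seg.reference_id = -1
        seg.reference_start = -1
        seg.query_sequence = "A" * read_length
        seg.mapping_quality = 0
    else:
        seg.reference_id = 0
        seg.reference_start = pos
        seg.query_sequence = "A" * read_length
        seg.cigarstring = cigar
        seg.mapping_quality = mapq
        if nm is not None:
            seg.set_tag("NM", nm)
    return seg


def make_record(*args, **kwargs) -> AlignmentRecord:
    return AlignmentRecord.from_segment(make_segment(*args, **kwargs))


def write_sam(path, segments, header=None) -> str:
    with pysam.AlignmentFile(
        str(path), "w" if str(path).endswith(".sam") else "wb",
        header=header or HEADER,
    ) as out:
        for seg in segments:
            out.write(seg)
    return str(path)


def paired_segments(
    name: str,
    nm1: int | None = 0,
    nm2: int | None = 0,
    cigar1: str = "100M",
    cigar2: str = "100M",
    mapped1: bool = True,
    mapped2: bool = True,
):
    """A mate pair; nm=None or mapped=False makes that mate unmapped."""
    segs = []
    for mate_flag, nm, cigar, mapped in (
        (FLAG_MATE1, nm1, cigar1, mapped1),
        (FLAG_MATE2, nm2, cigar2, mapped2),
    ):
        flag = FLAG_PAIRED | mate_flag
        if not mapped or nm is None:
            flag |= FLAG_UNMAPPED
            segs.append(make_segment(name, flag))
        else:
            segs.append(make_segment(name, flag, cigar=cigar, nm=nm))
    return segs


@pytest.fixture()
def tmp_sam(tmp_path):
    def _write(name, segments, header=None):
        return write_sam(tmp_path / name, segments, header)

    return _write
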