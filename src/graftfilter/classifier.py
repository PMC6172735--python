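"""Species classification of one read (pair) from its two per-reference scores.

Two modes:

* ``edit_distance`` — the reference with the lower edit distance wins; a read
  mapping to only one reference belongs to that species; equal distances are
  a TIE and the read is written to neither output. A would-be graft call
  whose score exceeds ``max_edit_distance`` becomes CAP_EXCEEDED and is kept
  out of the graft output (the cap protects the graft product; host-side
  calls are not capped, and capped reads are reported separately so the
  cap's effect is auditable).
* ``strict`` — the conservative baseline: any primary mate mapping to the
  host reference makes the whole read (pair) HOST, regardless of distances.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .alignment_io import AlignmentInputError, ReadBundle
from .edit_distance import EditDistanceScore

__all__ = ["Label", "FilterParams", "ClassificationLabel", "classify_scores", "classify_strict"]


class Label(str, enum.Enum):
    GRAFT = "GRAFT"
    HOST = "HOST"
    TIE = "TIE"
    NEITHER = "NEITHER"
    CAP_EXCEEDED = "CAP_EXCEEDED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class FilterParams:
    """Tunable filter parameters.

    ``max_edit_distance`` caps the graft-side score (``None`` disables the
    cap); ``unmapped_penalty`` is the per-mate score substituted for an
    unmapped mate of a pair.
    """

    max_edit_distance: Optional[int] = 4
    unmapped_penalty: int = 8
    mode: str = "edit_distance"  # "edit_distance" | "strict"
    emit_host_output: bool = False
    nm_decompose: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("edit_distance", "strict"):
            raise ValueError(f"invalid mode {self.mode!r}")
        if self.max_edit_distance is not None and self.max_edit_distance < 0:
            raise ValueError("max_edit_distance must be nonnegative")
        if self.unmapped_penalty < 0:
            raise ValueError("unmapped_penalty must be nonnegative")


@dataclass(frozen=True)
class ClassificationLabel:
    label: Label
    graft_score: Optional[EditDistanceScore] = None
    host_score: Optional[EditDistanceScore] = None


def classify_scores(
    graft: Optional[EditDistanceScore],
    host: Optional[EditDistanceScore],
    params: FilterParams,
) -> ClassificationLabel:
    """Classify one read (pair) from its graft-side and host-side scores.

    ``None`` means no mapping to that reference at all. Total over valid
    inputs; never raises.
    """

    def capped(label: Label) -> Label:
        if (
            label is Label.GRAFT
            and params.max_edit_distance is not None
            and graft.value > params.max_edit_distance
        ):
            return Label.CAP_EXCEEDED
        return label

    if graft is None and host is None:
        label = Label.NEITHER
    elif host is None:
        label = capped(Label.GRAFT)
    elif graft is None:
        label = Label.HOST
    elif graft.value < host.value:
        label = capped(Label.GRAFT)
    elif host.value < graft.value:
        label = Label.HOST
    else:
        label = Label.TIE
    return ClassificationLabel(label=label, graft_score=graft, host_score=host)


def classify_strict(
    graft_bundle: Optional[ReadBundle],
    host_bundle: Optional[ReadBundle],
) -> ClassificationLabel:
    """Strict baseline: HOST if any primary mate maps to the host reference.

    Else GRAFT if any primary mate maps to the graft reference, else NEITHER.
    Distances are ignored entirely.
    """
    if graft_bundle is None and host_bundle is None:
        raise AlignmentInputError("read name present in neither input")
    if host_bundle is not None and host_bundle.any_primary_mapped():
        return ClassificationLabel(label=Label.HOST)
    if graft_bundle is not None and graft_bundle.any_primary_mapped():
        return ClassificationLabel(label=Label.GRAFT)
    return ClassificationLabel(label=Label.NEITHER)
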