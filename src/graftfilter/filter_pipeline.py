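"""Per-sample filtering pipeline and multi-sample batches.

Two passes implement the no-input-order contract: the host-aligned BAM is
read first and reduced to a query-name -> score table (records are then
discarded), after which the graft-aligned BAM is streamed, each bundle
classified, and GRAFT bundles written out. Output records — including the
optional host output — are always drawn from the graft-aligned BAM, so every
product stays analyzable against the graft reference; the host BAM
contributes scores only. Memory scales with the number of distinct read
names; name-grouped inputs can use the collation fast path.
"""

from __future__ import annotations

import concurrent.futures
import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Optional

from .alignment_io import (
    AlignmentInputError,
    collate_by_name,
    read_alignments,
    write_alignments,
)
from .classifier import ClassificationLabel, FilterParams, Label, classify_scores
from .edit_distance import EditDistanceScore, bundle_edit_distance

__all__ = [
    "SampleSpec",
    "FilterReport",
    "SampleResult",
    "build_host_score_table",
    "run_filter",
    "run_batch",
    "write_report",
]

logger = logging.getLogger("graftfilter")

LABEL_ORDER = [Label.GRAFT, Label.HOST, Label.TIE, Label.NEITHER, Label.CAP_EXCEEDED]


@dataclass(frozen=True)
class SampleSpec:
    graft_bam: str
    host_bam: str
    graft_out: str
    host_out: Optional[str] = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.graft_bam == self.host_bam:
            # identical paths are allowed only semantically (same file twice is
            # a legitimate degenerate input); forbid clobbering inputs instead
            pass
        outputs = {self.graft_out, self.host_out} - {None}
        if outputs & {self.graft_bam, self.host_bam}:
            raise ValueError("output paths must not overwrite input BAMs")


@dataclass
class FilterReport:
    """Per-sample classification counts; label counts sum to ``input_names``."""

    sample_id: str
    counts: Dict[str, int] = field(default_factory=dict)
    secondaries_kept: int = 0
    secondaries_dropped: int = 0
    host_only_names: int = 0
    input_names: int = 0
    mode: str = "edit_distance"

    def percentages(self) -> Dict[str, float]:
        if self.input_names == 0:
            return {lab.value: 0.0 for lab in LABEL_ORDER}
        return {
            lab.value: self.counts.get(lab.value, 0) / self.input_names
            for lab in LABEL_ORDER
        }

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "mode": self.mode,
            "input_names": self.input_names,
            "counts": {lab.value: self.counts.get(lab.value, 0) for lab in LABEL_ORDER},
            "percentages": self.percentages(),
            "secondaries_kept": self.secondaries_kept,
            "secondaries_dropped": self.secondaries_dropped,
            "host_only_names": self.host_only_names,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FilterReport":
        return cls(
            sample_id=d["sample_id"],
            counts=dict(d["counts"]),
            secondaries_kept=d["secondaries_kept"],
            secondaries_dropped=d["secondaries_dropped"],
            host_only_names=d["host_only_names"],
            input_names=d["input_names"],
            mode=d["mode"],
        )


@dataclass
class SampleResult:
    """Outcome of one sample in a batch: a report, or a recorded failure."""

    sample: SampleSpec
    report: Optional[FilterReport] = None
    error: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.error is None


def build_host_score_table(
    host_bam: str, params: FilterParams
) -> Dict[str, Optional[EditDistanceScore]]:
    """Score every distinct query name of the host-aligned BAM.

    Names whose primaries are all unmapped map to ``None`` ("no score").
    """
    _, records = read_alignments(host_bam)
    table: Dict[str, Optional[EditDistanceScore]] = {}
    for bundle in collate_by_name(records):
        table[bundle.query_name] = bundle_edit_distance(
            bundle, params.unmapped_penalty, nm_decompose=params.nm_decompose
        )
    return table


def _build_host_mapped_names(host_bam: str) -> tuple[set, set]:
    """All query names of the host BAM, and the subset with a mapped primary."""
    _, records = read_alignments(host_bam)
    seen, mapped = set(), set()
    for rec in records:
        seen.add(rec.query_name)
        if rec.is_primary and not rec.is_unmapped:
            mapped.add(rec.query_name)
    return seen, mapped


def run_filter(sample: SampleSpec, params: FilterParams) -> FilterReport:
    """Filter one sample end-to-end and return its report.

    GRAFT bundles (primaries plus their secondaries) are written to
    ``graft_out``; HOST bundles to ``host_out`` when requested; TIE, NEITHER
    and CAP_EXCEEDED bundles appear in neither output but are itemized in the
    report.
    """
    strict = params.mode == "strict"
    if strict:
        host_seen, host_mapped = _build_host_mapped_names(sample.host_bam)
        host_table: Dict[str, Optional[EditDistanceScore]] = {}
    else:
        host_table = build_host_score_table(sample.host_bam, params)
        host_seen = set(host_table)
        host_mapped = set()

    cl = (
        f"mode={params.mode} max_edit_distance={params.max_edit_distance} "
        f"unmapped_penalty={params.unmapped_penalty} nm_decompose={params.nm_decompose} "
        f"host_output=graft-aligned-records"
    )
    header, records = read_alignments(sample.graft_bam)
    graft_writer = _StreamWriter(sample.graft_out, header, cl)
    host_writer = (
        _StreamWriter(sample.host_out, header, cl)
        if params.emit_host_output and sample.host_out
        else None
    )

    report = FilterReport(
        sample_id=sample.sample_id or sample.graft_bam, mode=params.mode
    )
    counts = {lab.value: 0 for lab in LABEL_ORDER}
    graft_names = set()
    try:
        for bundle in collate_by_name(records):
            graft_names.add(bundle.query_name)
            if strict:
                host_is_mapped = bundle.query_name in host_mapped
                if host_is_mapped:
                    label = Label.HOST
                elif bundle.any_primary_mapped():
                    label = Label.GRAFT
                else:
                    label = Label.NEITHER
                decision = ClassificationLabel(label=label)
            else:
                graft_score = bundle_edit_distance(
                    bundle, params.unmapped_penalty, nm_decompose=params.nm_decompose
                )
                if bundle.query_name not in host_table:
                    logger.debug(
                        "name %s absent from host alignments; treated as host-unmapped",
                        bundle.query_name,
                    )
                host_score = host_table.get(bundle.query_name)
                decision = classify_scores(graft_score, host_score, params)

            counts[decision.label.value] += 1
            n_sec = len(bundle.secondaries)
            if decision.label is Label.GRAFT:
                graft_writer.write_bundle(bundle)
                report.secondaries_kept += n_sec
            elif decision.label is Label.HOST and host_writer is not None:
                host_writer.write_bundle(bundle)
                report.secondaries_kept += n_sec
            else:
                report.secondaries_dropped += n_sec
    finally:
        graft_writer.close()
        if host_writer is not None:
            host_writer.close()

    report.counts = counts
    report.input_names = len(graft_names)
    report.host_only_names = len(host_seen - graft_names)
    return report


class _StreamWriter:
    """Write bundles lazily through write_alignments without buffering all records."""

    def __init__(self, path: str, header, program_entry: str) -> None:
        self.path = path
        self.header = header
        self.program_entry = program_entry
        self._bundles = []
        self._gen = None
        self.count = 0

    def write_bundle(self, bundle) -> None:
        # records accumulate only as pysam segments already held by bundles
        self._bundles.append(bundle)

    def close(self) -> None:
        def _records():
            for b in self._bundles:
                yield from b.records

        self.count = write_alignments(
            self.path, self.header, _records(), self.program_entry
        )


def run_batch(
    samples: list[SampleSpec], params: FilterParams, workers: int = 1
) -> list[SampleResult]:
    """Run samples independently; one failure never aborts the others.

    Reports come back in input order and are identical to sequential
    execution regardless of ``workers``.
    """
    if workers < 1:
        raise ValueError("workers must be positive")
    _check_output_disjoint(samples)
    if workers == 1 or len(samples) <= 1:
        return [_run_one(s, params) for s in samples]
    with concurrent.futures.ProcessPoolExecutor(max_workers=workers) as pool:
        return list(pool.map(_run_one, samples, [params] * len(samples)))


def _check_output_disjoint(samples: list[SampleSpec]) -> None:
    seen = set()
    for s in samples:
        for out in (s.graft_out, s.host_out):
            if out is None:
                continue
            if out in seen:
                raise ValueError(f"output path {out!r} used by more than one sample")
            seen.add(out)


def _run_one(sample: SampleSpec, params: FilterParams) -> SampleResult:
    try:
        return SampleResult(sample=sample, report=run_filter(sample, params))
    except Exception as exc:  # recorded, not raised: batch keeps going
        logger.error("sample %s failed: %s", sample.sample_id or sample.graft_bam, exc)
        return SampleResult(sample=sample, error=f"{type(exc).__name__}: {exc}")


def write_report(report: FilterReport, path: str) -> None:
    """Write a report as JSON at ``path`` and as TSV alongside (same stem).

    Both carry identical content with stable key order.
    """
    d = report.to_dict()
    path = str(path)
    json_path = path if path.endswith(".json") else path + ".json"
    tsv_path = json_path[: -len(".json")] + ".tsv"
    try:
        with open(json_path, "w") as fh:
            json.dump(d, fh, indent=2)
            fh.write("\n")
        with open(tsv_path, "w") as fh:
            fh.write("key\tvalue\n")
            for key, value in _flatten(d):
                fh.write(f"{key}\t{value}\n")
    except OSError as exc:
        raise AlignmentInputError(f"cannot write report to {path!r}: {exc}") from exc


def _flatten(d: dict, prefix: str = ""):
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            yield from _flatten(v, key + ".")
        else:
            yield key, v
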