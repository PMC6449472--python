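"""Short-read and subread quality filters with per-rule accounting.

Illumina pairs are dropped whole when either mate fails a rule; rules are
checked in fixed precedence (N content, then low-quality fraction, then
adapter overlap) so the per-reason counters are reproducible. PCR duplicates
are exact (seq1, seq2) tuple re-occurrences, first occurrence kept. PacBio
subreads are kept when read score >= 0.80 and length >= 500 bp; both rules
are strict "remove if below", so the boundaries are inclusive keeps.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io_formats import SequenceRecord

DROP_REASONS = ("has_n", "lowq", "adapter", "duplicate")


@dataclasses.dataclass
class QcParams:
    max_lowq_frac: float = 0.20
    lowq_phred: int = 20
    adapter_seq: Optional[str] = None
    min_adapter_overlap: int = 10  # exclusive: overlap must exceed this
    max_adapter_mismatch: int = 3
    min_subread_len: int = 500
    min_read_score: float = 0.80

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_lowq_frac <= 1.0:
            raise ValueError("max_lowq_frac must be in [0, 1]")
        if self.min_adapter_overlap < 1:
            raise ValueError("min_adapter_overlap must be >= 1")


@dataclasses.dataclass
class QcReport:
    """Per-reason pair counters plus input/output base totals."""

    counts: Dict[str, int] = dataclasses.field(
        default_factory=lambda: {r: 0 for r in (*DROP_REASONS, "kept")}
    )
    input_pairs: int = 0
    input_bases: int = 0
    output_bases: int = 0

    def check(self) -> None:
        if sum(self.counts.values()) != self.input_pairs:
            raise AssertionError("QC accounting does not reconcile")


def adapter_overlap_len(read: SequenceRecord, adapter: str, max_mismatch: int = 3) -> int:
    """Longest read-suffix / adapter-prefix overlap within the mismatch budget.

    Ungapped (Hamming) comparison; a full internal adapter occurrence counts
    as an overlap of the whole adapter length. Returns 0 when nothing
    qualifies.
    """
    if not adapter:
        raise ValueError("adapter must be nonempty")
    seq = read.sequence
    best = 0
    # suffix-of-read vs prefix-of-adapter, longest first
    for ln in range(min(len(seq), len(adapter)), 0, -1):
        tail = seq[-ln:]
        mism = 0
        for a, b in zip(tail, adapter):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        if mism <= max_mismatch:
            best = ln
            break
    # full internal occurrences
    la = len(adapter)
    if best < la and len(seq) > la:
        for i in range(len(seq) - la):
            mism = 0
            for a, b in zip(seq[i : i + la], adapter):
                if a != b:
                    mism += 1
                    if mism > max_mismatch:
                        break
            if mism <= max_mismatch:
                best = la
                break
    return best


def classify_read(read: SequenceRecord, params: QcParams) -> Optional[str]:
    """None to keep, otherwise the first failing drop reason."""
    if read.quality is None:
        raise ValueError(f"{read.id}: read has no qualities")
    if "N" in read.sequence:
        return "has_n"
    n = len(read.sequence)
    if n and int((read.quality < params.lowq_phred).sum()) / n > params.max_lowq_frac:
        return "lowq"
    if params.adapter_seq:
        ov = adapter_overlap_len(read, params.adapter_seq, params.max_adapter_mismatch)
        if ov > params.min_adapter_overlap:
            return "adapter"
    return None


_PRECEDENCE = {"has_n": 0, "lowq": 1, "adapter": 2}


def filter_pairs(
    pairs: Sequence[Tuple[SequenceRecord, SequenceRecord]], params: QcParams
) -> Tuple[List[Tuple[SequenceRecord, SequenceRecord]], QcReport]:
    """Apply per-read rules at pair level, then exact-duplicate removal.

    A pair is dropped when either mate fails; the recorded reason is the
    highest-precedence failure across the two mates. Duplicate removal runs
    on the survivors: a (seq1, seq2) tuple already emitted drops the pair.
    """
    report = QcReport(input_pairs=len(pairs))
    kept: List[Tuple[SequenceRecord, SequenceRecord]] = []
    seen = set()
    for r1, r2 in pairs:
        report.input_bases += len(r1) + len(r2)
        reasons = [r for r in (classify_read(r1, params), classify_read(r2, params)) if r]
        if reasons:
            report.counts[min(reasons, key=_PRECEDENCE.__getitem__)] += 1
            continue
        key = (r1.sequence, r2.sequence)
        if key in seen:
            report.counts["duplicate"] += 1
            continue
        seen.add(key)
        kept.append((r1, r2))
        report.counts["kept"] += 1
        report.output_bases += len(r1) + len(r2)
    report.check()
    return kept, report


def filter_subreads(
    subreads: Sequence[Tuple[SequenceRecord, float]], params: QcParams
) -> List[Tuple[SequenceRecord, float]]:
    """Keep subreads with score >= min_read_score and length >= min_subread_len."""
    kept = []
    for rec, score in subreads:
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"{rec.id}: read score {score} outside [0, 1]")
        if score >= params.min_read_score and len(rec) >= params.min_subread_len:
            kept.append((rec, score))
    return kept
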