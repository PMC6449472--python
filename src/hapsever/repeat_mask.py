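"""Repeat masking of elementary contigs before allele-sequence detection.

Two desk-scale detectors are provided: interspersed repeats by k-mer
frequency (positions covered by a k-mer whose multiplicity across the contig
set exceeds a threshold), and tandem repeats by a direct periodicity scan
(>=2 adjacent approximate copies of a short pattern). External masks from
homology-based tools are ingested as BED through io_formats and combined
with merge_masks; downstream coverage arithmetic only needs masked spans,
not repeat classification.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from . import _intervals
from ._kmers import kmer_codes, seq_to_codes
from .io_formats import MaskInterval, SequenceRecord


@dataclasses.dataclass
class MaskParams:
    k: int = 15
    freq_threshold: Optional[float] = None  # None: 4x mean k-mer multiplicity
    freq_threshold_factor: float = 4.0
    min_run: int = 50
    tandem_max_period: int = 6
    tandem_min_copies: int = 2
    tandem_max_mismatch_frac: float = 0.1

    def __post_init__(self) -> None:
        for name in ("k", "min_run", "tandem_max_period", "tandem_min_copies"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def mask_by_kmer_frequency(
    contigs: Sequence[SequenceRecord], params: MaskParams = MaskParams()
) -> List[MaskInterval]:
    """Mask runs of high-multiplicity k-mers across the contig set.

    A position is marked when some k-window covering it has multiplicity
    (canonical, across all contigs) above the frequency threshold; marked
    runs of at least `min_run` bp become `interspersed` intervals.
    """
    if not contigs:
        raise ValueError("contig set must be nonempty")
    per_contig: List[Tuple[np.ndarray, np.ndarray]] = []
    chunks = []
    for rec in contigs:
        codes, valid = kmer_codes(seq_to_codes(rec.sequence), params.k, canonical=True)
        per_contig.append((codes, valid))
        chunks.append(codes[valid])
    allk = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)
    if allk.size == 0:
        return []
    uniq, counts = np.unique(allk, return_counts=True)
    threshold = params.freq_threshold
    if threshold is None:
        threshold = params.freq_threshold_factor * (allk.size / uniq.size)
    out: List[MaskInterval] = []
    for rec, (codes, valid) in zip(contigs, per_contig):
        if codes.size == 0:
            continue
        idx = np.searchsorted(uniq, codes)
        idx[idx >= uniq.size] = 0
        mult = np.where(uniq[idx.clip(max=uniq.size - 1)] == codes, counts[idx], 0)
        hot = valid & (mult > threshold)
        if not hot.any():
            continue
        # window i covers [i, i+k): build a coverage diff array
        L = len(rec.sequence)
        diff = np.zeros(L + 1, dtype=np.int32)
        pos = np.flatnonzero(hot)
        np.add.at(diff, pos, 1)
        np.add.at(diff, np.minimum(pos + params.k, L), -1)
        covered = np.cumsum(diff[:-1]) > 0
        for s, e in _bool_runs(covered):
            if e - s >= params.min_run:
                out.append(MaskInterval(rec.id, int(s), int(e), "interspersed"))
    return out


def _bool_runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return list(zip(edges[::2], edges[1::2]))


def find_tandem_repeats(
    contig: SequenceRecord, params: MaskParams = MaskParams()
) -> List[MaskInterval]:
    """Periodicity scan for short tandem arrays.

    For each period p <= tandem_max_period and start position, the pattern is
    the first p bases; the array extends while the mismatch fraction against
    the periodic extension of that pattern stays within
    tandem_max_mismatch_frac. Intervals spanning at least
    tandem_min_copies * p (plus the seed copy implicit in the pattern) are
    kept and unioned.
    """
    seq = contig.sequence
    L = len(seq)
    found: List[Tuple[int, int]] = []
    for p in range(1, params.tandem_max_period + 1):
        min_len = max(2 * p, params.tandem_min_copies * p)
        i = 0
        while i + min_len <= L:
            pattern = seq[i : i + p]
            if "N" in pattern:
                i += 1
                continue
            thr = params.tandem_max_mismatch_frac
            # keep scanning past a transient excursion above the mismatch
            # budget: later matches can dilute it back under (grace window
            # sized so one extra mismatch can be absorbed)
            grace = max(2 * p, int(round(2.0 / thr))) if thr > 0 else 1
            mism = 0
            best_end = i + p
            x = i + p
            while x < L and (x + 1) - best_end <= grace:
                if seq[x] != pattern[(x - i) % p]:
                    mism += 1
                if mism <= thr * (x - i + 1):
                    best_end = x + 1
                x += 1
            if best_end - i >= min_len:
                found.append((i, best_end))
                i = best_end - p + 1
            else:
                i += 1
    if not found:
        return []
    return [
        MaskInterval(contig.id, s, e, "tandem") for s, e in _intervals.merge(found)
    ]


def merge_masks(
    *mask_lists: Iterable[MaskInterval],
    contig_lengths: Optional[Dict[str, int]] = None,
) -> Tuple[List[MaskInterval], Dict[str, int]]:
    """Union all masks per contig into a canonical non-overlapping mask.

    Returns (intervals, report) where report maps each label (and 'total')
    to masked bp. Merged intervals keep their label when a single label
    contributed, otherwise 'merged'.
    """
    by_contig: Dict[str, List[MaskInterval]] = defaultdict(list)
    label_bp: Dict[str, int] = defaultdict(int)
    per_label: Dict[Tuple[str, str], List[Tuple[int, int]]] = defaultdict(list)
    for masks in mask_lists:
        for iv in masks:
            if contig_lengths is not None:
                L = contig_lengths.get(iv.contig_id)
                if L is None:
                    raise ValueError(f"mask on unknown contig {iv.contig_id!r}")
                if iv.end > L:
                    raise ValueError(
                        f"{iv.contig_id}: mask [{iv.start},{iv.end}) exceeds length {L}"
                    )
            by_contig[iv.contig_id].append(iv)
            per_label[(iv.contig_id, iv.label)].append((iv.start, iv.end))
    for (contig, label), ivs in per_label.items():
        label_bp[label] += _intervals.total_length(ivs)
    out: List[MaskInterval] = []
    total = 0
    for contig in sorted(by_contig):
        ivs = by_contig[contig]
        merged = _intervals.merge([(iv.start, iv.end) for iv in ivs])
        for s, e in merged:
            labels = {iv.label for iv in ivs if iv.start < e and iv.end > s}
            label = labels.pop() if len(labels) == 1 else "merged"
            out.append(MaskInterval(contig, s, e, label))
            total += e - s
    report = dict(label_bp)
    report["total"] = total
    return out, report
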