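"""Assembly summary statistics, depth summaries, mapping rates, and
pairwise same-molecule variant comparison.

`compare_sequences` counts single-nucleotide variants and indel events
between two near-identical molecules (e.g. two assemblies of the same
mitochondrion) from a global affine-gap alignment (match +1, mismatch -1,
gap open -2, gap extend -1): mismatch columns are SNVs, and each maximal
run of gap columns is one indel event regardless of its length. The affine
penalty matters — under unit gap costs a multi-base gap can split into
several single-base gaps whenever intervening bases match by chance,
inflating the event count. Circular molecules are first rotated to a shared
anchor k-mer so the linear alignment does not split at an arbitrary origin.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from Bio import Align

from .io_formats import SequenceRecord


@dataclasses.dataclass
class AssemblyStats:
    n_seqs: int
    total_bp: int
    n50_bp: int
    mean_len_bp: float

    @property
    def mean_len_report(self) -> int:
        """Mean length rounded half-even to integer bp (report form)."""
        return round(self.mean_len_bp)


@dataclasses.dataclass
class DepthSummary:
    contig_id: str
    mean_depth: float
    min_depth: int
    max_depth: int


@dataclasses.dataclass
class VariantComparison:
    n_snv: int
    n_indel_events: int


def n50(lengths: Sequence[int]) -> int:
    """Largest L whose cumulative descending sum first reaches half the total."""
    if not len(lengths):
        raise ValueError("n50 of empty length set")
    if min(lengths) <= 0:
        raise ValueError("lengths must be positive")
    total = sum(lengths)
    acc = 0
    for L in sorted(lengths, reverse=True):
        acc += L
        if 2 * acc >= total:
            return L
    raise AssertionError("unreachable")


def summarize(records: Sequence[SequenceRecord]) -> AssemblyStats:
    if not records:
        raise ValueError("cannot summarize an empty sequence set")
    lengths = [len(r) for r in records]
    return AssemblyStats(
        n_seqs=len(lengths),
        total_bp=sum(lengths),
        n50_bp=n50(lengths),
        mean_len_bp=sum(lengths) / len(lengths),
    )


def depth_summary(
    intervals: Iterable[Tuple[str, int, int]], contig_lengths: Dict[str, int]
) -> List[DepthSummary]:
    """Per-base depth statistics from alignment intervals (one per read).

    `intervals` are (contig_id, start, end) triples; a contig with no
    intervals reports 0/0/0. Implemented with a difference array, which the
    tests check against a naive per-base oracle.
    """
    by_contig: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
    for cid, s, e in intervals:
        if cid not in contig_lengths:
            raise ValueError(f"interval on unknown contig {cid!r}")
        if not 0 <= s < e <= contig_lengths[cid]:
            raise ValueError(f"{cid}: interval [{s},{e}) out of bounds")
        by_contig[cid].append((s, e))
    out: List[DepthSummary] = []
    for cid in sorted(contig_lengths):
        L = contig_lengths[cid]
        ivs = by_contig.get(cid, [])
        if not ivs:
            out.append(DepthSummary(cid, 0.0, 0, 0))
            continue
        diff = np.zeros(L + 1, dtype=np.int64)
        for s, e in ivs:
            diff[s] += 1
            diff[e] -= 1
        depth = np.cumsum(diff[:-1])
        out.append(
            DepthSummary(cid, float(depth.mean()), int(depth.min()), int(depth.max()))
        )
    return out


def mapping_rate(
    read_assignments: Dict[str, Set[str]], reference_ids: Iterable[str]
) -> float:
    """Percent of reads with at least one assignment to the reference set."""
    if not read_assignments:
        raise ValueError("no reads")
    refs = set(reference_ids)
    mapped = sum(1 for ctgs in read_assignments.values() if ctgs & refs)
    return round(100.0 * mapped / len(read_assignments), 2)


def _rotate_to_shared_anchor(a: str, b: str, k: int = 21) -> Tuple[str, str]:
    """Rotate two circular sequences so both start at a shared unique k-mer."""
    def unique_kmers(s: str) -> Dict[str, int]:
        pos: Dict[str, int] = {}
        dup = set()
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if km in pos or km in dup:
                dup.add(km)
                pos.pop(km, None)
            else:
                pos[km] = i
        return pos

    ka, kb = unique_kmers(a), unique_kmers(b)
    shared = [km for km in ka if km in kb]
    if not shared:
        raise ValueError("no shared anchor k-mer for circular rotation")
    anchor = min(shared, key=lambda km: ka[km])
    ia, ib = ka[anchor], kb[anchor]
    return a[ia:] + a[:ia], b[ib:] + b[:ib]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


def compare_sequences(
    a: SequenceRecord, b: SequenceRecord, circular: bool = False
) -> VariantComparison:
    """Count SNVs and indel events between two near-identical molecules.

    Quadratic in sequence length: intended for molecule-scale inputs
    (mitochondria, plasmids; tens of kb), not whole assemblies.
    """
    sa, sb = a.sequence, b.sequence
    if not sa or not sb:
        raise ValueError("both sequences must be nonempty")
    if circular:
        sa, sb = _rotate_to_shared_anchor(sa, sb)
    aln = _make_aligner().align(sa, sb)[0]
    blocks_a, blocks_b = aln.aligned
    n_snv = 0
    for (as_, ae), (bs, be) in zip(blocks_a, blocks_b):
        xa = np.frombuffer(sa[as_:ae].encode(), dtype=np.uint8)
        xb = np.frombuffer(sb[bs:be].encode(), dtype=np.uint8)
        n_snv += int((xa != xb).sum())
    # each junction between consecutive aligned blocks is one maximal gap
    # run (leading/trailing overhangs of a global alignment count too)
    n_indel = max(0, len(blocks_a) - 1)
    if len(blocks_a):
        if blocks_a[0][0] > 0 or blocks_b[0][0] > 0:
            n_indel += 1
        if blocks_a[-1][1] < len(sa) or blocks_b[-1][1] < len(sb):
            n_indel += 1
    return VariantComparison(n_snv=n_snv, n_indel_events=n_indel)
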