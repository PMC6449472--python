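"""Allele-sequence (haplotig) detection and contig partitioning.

The procedure separates "elementary contigs" of a heterozygous diploid
assembly into haploid genome contigs (HGCs) and allele sequences (ASs):

1. Self-alignment matches for a contig pair are clustered per strand into
   the maximum-weight colinear chain (weighted longest increasing
   subsequence on both coordinate orders; weight = matched bp), split where
   the query gap exceeds ``max_chain_gap``.
2. Chained query intervals are unioned and intersected against the repeat
   mask; the aligned fraction is non-repeat aligned bp over non-repeat
   contig length (repeats excluded from numerator and denominator).
3. Each contig, visited in decreasing length order, is compared against
   every strictly longer contig still held as HGC. Case I: self pair,
   ignored. Case II: no alignment — HGC. Case III: aligned fraction or
   shared-read fraction at/above the 85% threshold — the shorter contig is
   an AS. Case IV: partial alignment below threshold — duplication, HGC.
4. An AS call whose chain mean identity falls below ``min_chain_identity``
   is restored to HGC (automated stand-in for the dot-plot inspection).
"""

from __future__ import annotations

import dataclasses
import logging
from collections import defaultdict
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from . import _intervals
from .asm_stats import n50
from .io_formats import AlignmentMatch, MaskInterval, SequenceRecord

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PurgeParams:
    coverage_threshold: float = 0.85
    read_share_threshold: float = 0.85
    min_chain_identity: float = 0.90
    max_chain_gap: int = 10_000
    #: consecutive chain members whose query AND target gaps are both at
    #: most this many bp are merged into one larger match before coverage
    #: is computed (heterozygous alignments fragment into short exact
    #: matches at every SNP/indel; the merged blocks are what the coverage
    #: fraction is meant to measure)
    match_join_gap: int = 100

    def __post_init__(self) -> None:
        for name in ("coverage_threshold", "read_share_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclasses.dataclass
class MatchChain:
    query_id: str
    target_id: str
    strand: str
    members: List[AlignmentMatch]
    join_gap: int = 0

    @property
    def merged_query_intervals(self) -> List[Tuple[int, int]]:
        """Query intervals of the members, merged into larger matches.

        Consecutive colinear members separated by at most ``join_gap`` bp on
        both the query and the target coalesce into one block.
        """
        if not self.members:
            return []
        ms = sorted(self.members, key=lambda m: m.qstart)
        blocks: List[Tuple[int, int]] = []
        cur_q = [ms[0].qstart, ms[0].qend]
        prev = ms[0]
        for m in ms[1:]:
            qgap = m.qstart - prev.qend
            if self.strand == "+":
                tgap = m.tstart - prev.tend
            else:
                tgap = prev.tstart - m.tend
            if qgap <= self.join_gap and tgap <= self.join_gap:
                cur_q[1] = max(cur_q[1], m.qend)
            else:
                blocks.append((cur_q[0], cur_q[1]))
                cur_q = [m.qstart, m.qend]
            prev = m
        blocks.append((cur_q[0], cur_q[1]))
        return _intervals.merge(blocks)

    @property
    def chain_weight(self) -> int:
        return sum(m.match_len for m in self.members)

    @property
    def mean_identity(self) -> float:
        w = self.chain_weight
        if w == 0:
            return 0.0
        return sum(m.identity * m.match_len for m in self.members) / w


@dataclasses.dataclass
class ContigClassification:
    contig_id: str
    label: str  # HGC | AS
    case: str  # I | II | III | IV
    partner_id: Optional[str] = None
    aligned_fraction: float = 0.0
    read_share: Optional[float] = None
    restored: bool = False


def chain_matches(
    matches: Sequence[AlignmentMatch], params: PurgeParams = PurgeParams()
) -> List[MatchChain]:
    """Best colinear chain per strand for one ordered contig pair.

    Exact weighted-LIS dynamic programme: the retained subset has strictly
    increasing query starts and strictly increasing (``+``) or decreasing
    (``-``, equivalently increasing on the stored ascending coordinates)
    target starts, maximizing summed match length. A query-coordinate gap
    above ``max_chain_gap`` between consecutive members breaks the chain;
    the heaviest chain wins.
    """
    if not matches:
        return []
    pairs = {(m.query_id, m.target_id) for m in matches}
    if len(pairs) != 1:
        raise ValueError(f"matches span multiple contig pairs: {sorted(pairs)}")
    chains: List[MatchChain] = []
    for strand in "+-":
        sub = [m for m in matches if m.strand == strand]
        if not sub:
            continue
        chains.append(_chain_one_strand(sub, strand, params))
    return chains


def _chain_one_strand(
    matches: List[AlignmentMatch], strand: str, params: PurgeParams
) -> MatchChain:
    ms = sorted(matches, key=lambda m: (m.qstart, m.tstart))
    qs = np.array([m.qstart for m in ms])
    qe = np.array([m.qend for m in ms])
    # '-' strand matches are stored with ascending target coordinates, so a
    # colinear reverse chain has target starts decreasing as query advances
    ts = np.array([m.tstart for m in ms])
    if strand == "-":
        ts = -ts
    w = np.array([m.match_len for m in ms])
    n = len(ms)
    dp = w.astype(np.int64).copy()
    parent = np.full(n, -1)
    for i in range(1, n):
        ok = (qs[:i] < qs[i]) & (ts[:i] < ts[i]) & (qs[i] - qe[:i] <= params.max_chain_gap)
        if ok.any():
            cand = np.where(ok, dp[:i], np.iinfo(np.int64).min)
            j = int(np.argmax(cand))
            if cand[j] > 0:
                dp[i] = w[i] + cand[j]
                parent[i] = j
    best = int(np.argmax(dp))
    members: List[AlignmentMatch] = []
    while best != -1:
        members.append(ms[best])
        best = parent[best]
    members.reverse()
    return MatchChain(
        ms[0].query_id, ms[0].target_id, strand, members, params.match_join_gap
    )


def merged_coverage(
    chains: Iterable[MatchChain],
    query_len: int,
    mask: Sequence[Tuple[int, int]] = (),
) -> Tuple[float, List[Tuple[int, int]]]:
    """Non-repeat aligned fraction of the query contig.

    fraction = |union(chained query intervals) \\ mask| / (query_len - |mask|).
    A fully repetitive query (denominator 0) yields fraction 0.0.
    """
    intervals: List[Tuple[int, int]] = []
    for chain in chains:
        intervals.extend(chain.merged_query_intervals)
    if intervals and max(e for _, e in intervals) > query_len:
        raise ValueError("chained interval exceeds query length")
    if mask and max(e for _, e in mask) > query_len:
        raise ValueError("mask interval exceeds query length")
    merged = _intervals.merge(intervals) if intervals else []
    mask_len = _intervals.total_length(list(mask)) if mask else 0
    denom = query_len - mask_len
    if denom <= 0:
        logger.warning("query fully repetitive; aligned fraction defined as 0")
        return 0.0, merged
    covered = _intervals.subtract(merged, list(mask)) if mask else merged
    return _intervals.total_length(covered) / denom, merged


def classify_pair(
    short_id: str,
    long_id: str,
    aligned_fraction: float,
    read_share: Optional[float],
    params: PurgeParams = PurgeParams(),
) -> Tuple[str, str]:
    """(case, label-for-the-shorter-contig) under the 85% rules."""
    if short_id == long_id:
        return "I", "HGC"
    share_hit = read_share is not None and read_share >= params.read_share_threshold
    if aligned_fraction >= params.coverage_threshold or share_hit:
        return "III", "AS"
    if aligned_fraction <= 0.0 and not share_hit:
        return "II", "HGC"
    return "IV", "HGC"


def read_share_fraction(
    read_assignments: Optional[Dict[str, Set[str]]], short_id: str, long_id: str
) -> Optional[float]:
    """Fraction of the short contig's reads also assigned to the long contig."""
    if read_assignments is None:
        return None
    short_reads = [r for r, ctgs in read_assignments.items() if short_id in ctgs]
    if not short_reads:
        return None
    shared = sum(1 for r in short_reads if long_id in read_assignments[r])
    return shared / len(short_reads)


def quality_check(chains: Iterable[MatchChain], params: PurgeParams = PurgeParams()) -> str:
    """'pass' or 'restore' for a Case III call, by chain mean identity."""
    chains = list(chains)
    total = sum(c.chain_weight for c in chains)
    if total == 0:
        return "restore"
    ident = sum(c.mean_identity * c.chain_weight for c in chains) / total
    return "restore" if ident < params.min_chain_identity else "pass"


@dataclasses.dataclass
class PartitionSummary:
    n_hgc: int
    n_as: int
    hgc_bp: int
    as_bp: int
    hgc_n50: int
    as_n50: int

    def as_dict(self) -> Dict[str, int]:
        return dataclasses.asdict(self)


def partition_contigs(
    contigs: Sequence[SequenceRecord],
    matches: Sequence[AlignmentMatch],
    mask: Sequence[MaskInterval] = (),
    read_assignments: Optional[Dict[str, Set[str]]] = None,
    params: PurgeParams = PurgeParams(),
) -> Tuple[List[ContigClassification], PartitionSummary]:
    """Greedy single-pass HGC/AS partition (longest contig first).

    Contigs are visited in strictly decreasing length order (ties broken by
    id); each is chained against every strictly longer contig still labeled
    HGC, the partner with the highest non-repeat aligned fraction decides
    the case, and AS calls failing the chain-identity check are restored.
    AS contigs are ineligible as partners for later contigs.
    """
    ids = [c.id for c in contigs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate contig ids")
    lengths = {c.id: len(c) for c in contigs}
    unknown = {m.query_id for m in matches} | {m.target_id for m in matches}
    unknown -= set(ids)
    if unknown:
        raise ValueError(f"matches reference unknown contigs: {sorted(unknown)[:5]}")

    mask_by_contig: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
    for iv in mask:
        mask_by_contig[iv.contig_id].append((iv.start, iv.end))
    for cid in mask_by_contig:
        mask_by_contig[cid] = _intervals.merge(mask_by_contig[cid])

    by_pair: Dict[Tuple[str, str], List[AlignmentMatch]] = defaultdict(list)
    for m in matches:
        if m.query_id == m.target_id:
            continue  # Case I: self-alignment, ignored
        by_pair[(m.query_id, m.target_id)].append(m)
        by_pair[(m.target_id, m.query_id)].append(m.flipped())
    # deduplicate matches present in both input directions
    for key, ms in by_pair.items():
        seen = set()
        uniq = []
        for m in ms:
            sig = (m.qstart, m.qend, m.tstart, m.tend, m.strand)
            if sig not in seen:
                seen.add(sig)
                uniq.append(m)
        by_pair[key] = uniq

    partners_of: Dict[str, Set[str]] = defaultdict(set)
    for q, t in by_pair:
        partners_of[q].add(t)

    order = sorted(ids, key=lambda cid: (-lengths[cid], cid))
    label: Dict[str, str] = {}
    result: List[ContigClassification] = []
    for cid in order:
        cand = [
            t
            for t in partners_of[cid]
            if lengths[t] > lengths[cid] and label.get(t) == "HGC"
        ]
        best_frac = 0.0
        best_partner: Optional[str] = None
        best_chains: List[MatchChain] = []
        for t in sorted(cand):
            chains = chain_matches(by_pair[(cid, t)], params)
            frac, _ = merged_coverage(chains, lengths[cid], mask_by_contig.get(cid, []))
            if frac > best_frac or (frac == best_frac and best_partner is None):
                best_frac, best_partner, best_chains = frac, t, chains
        share = (
            read_share_fraction(read_assignments, cid, best_partner)
            if best_partner is not None
            else None
        )
        if best_partner is None:
            equal_aln = any(
                lengths[t] == lengths[cid] for t in partners_of[cid] if t != cid
            )
            if equal_aln:
                logger.warning(
                    "%s: alignment only to equal-length contig; kept as HGC (Case IV)",
                    cid,
                )
                cls = ContigClassification(cid, "HGC", "IV")
            else:
                cls = ContigClassification(cid, "HGC", "II")
        else:
            case, lab = classify_pair(cid, best_partner, best_frac, share, params)
            cls = ContigClassification(
                cid, lab, case, best_partner, best_frac, share
            )
            if lab == "AS" and quality_check(best_chains, params) == "restore":
                cls.label = "HGC"
                cls.restored = True
                logger.debug("%s: AS call restored (poor chain identity)", cid)
        logger.debug(
            "%s: case %s label %s partner %s frac %.3f",
            cid, cls.case, cls.label, cls.partner_id, cls.aligned_fraction,
        )
        label[cid] = cls.label
        result.append(cls)

    by_input_order = {cid: i for i, cid in enumerate(ids)}
    result.sort(key=lambda c: by_input_order[c.contig_id])
    hgc_lens = [lengths[c.contig_id] for c in result if c.label == "HGC"]
    as_lens = [lengths[c.contig_id] for c in result if c.label == "AS"]
    summary = PartitionSummary(
        n_hgc=len(hgc_lens),
        n_as=len(as_lens),
        hgc_bp=sum(hgc_lens),
        as_bp=sum(as_lens),
        hgc_n50=n50(hgc_lens) if hgc_lens else 0,
        as_n50=n50(as_lens) if as_lens else 0,
    )
    return result, summary
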