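"""Synthetic heterozygous diploid genomes, contigs, reads and self-matches.

The generator emulates the data regime the pipeline is built for: a diploid
genome with percent-scale SNP heterozygosity (default 2.35%, with indels at
one tenth the SNP rate), a few dispersed near-identical repeat families, an
assembly fragmented into "elementary contigs" where a tunable fraction of
the genome is represented twice (a primary contig plus a strictly shorter
allelic copy from the other haplotype), Illumina-like paired reads carrying
the artefacts the QC stage removes (Ns, low-quality tails, adapter
read-through, PCR duplicates), and PacBio-like subreads with log-normal
lengths and Beta-distributed read scores. Every output is a deterministic
function of the parameters and seed, and every planted difference between
the haplotypes is recorded so truth can be reconstructed exactly.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._kmers import codes_to_seq, kmer_codes, seq_to_codes
from .io_formats import AlignmentMatch, SequenceRecord, write_fastq_pairs

#: Illumina TruSeq read-through adapter (33 bp), the default contaminant.
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

_REPEAT_FAMILIES = 3
_REPEAT_COPY_DIVERGENCE = 0.01  # repeat copies are ~99% identical


@dataclasses.dataclass
class SimulationParams:
    """Study conditions for the synthetic diploid.

    Defaults are the operating point of the pipeline's evaluation: 2 Mb
    genome at 2.35% SNP heterozygosity (indels at a 10:1 SNP:indel ratio),
    10% repeat content in 500-bp dispersed units, and 60% of the genome
    represented by two allelic contig copies.
    """

    genome_size: int = 2_000_000
    het_snp_rate: float = 0.0235
    het_indel_rate: float = 0.00235
    indel_len_geom_p: float = 0.5
    repeat_fraction: float = 0.10
    repeat_unit_len: int = 500
    allelic_fraction: float = 0.6
    contig_len_mean: int = 50_000
    contig_len_min: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("het_snp_rate", "het_indel_rate", "repeat_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.het_snp_rate > 0.5 or self.het_indel_rate > 0.5:
            raise ValueError("heterozygosity rates above 0.5 break the model")
        if not 0.0 <= self.allelic_fraction <= 1.0:
            raise ValueError("allelic_fraction must be in [0, 1]")
        if self.genome_size < 10 * self.contig_len_mean:
            raise ValueError("genome_size must be >= 10 * contig_len_mean")


@dataclasses.dataclass(frozen=True)
class Variant:
    """One planted difference, on haplotype-0 coordinates."""

    pos: int
    kind: str  # snp | ins | del
    ref: str
    alt: str


@dataclasses.dataclass(frozen=True)
class SyntheticTruth:
    contig_id: str
    role: str  # primary | allelic
    haplotype: int
    src_start: int
    src_end: int


# ---------------------------------------------------------------------------
# Diploid genome


def simulate_diploid(
    params: SimulationParams,
) -> Tuple[SequenceRecord, SequenceRecord, List[Variant]]:
    """Simulate the two haplotypes and the complete planted-variant ledger.

    Haplotype 0 is uniform random ACGT with dispersed near-identical repeat
    copies overwritten onto it; haplotype 1 is haplotype 0 with SNPs and
    geometric-length indels planted at the configured rates.
    """
    rng = np.random.default_rng(params.seed)
    G = params.genome_size
    codes = rng.integers(0, 4, G, dtype=np.uint8)

    if params.repeat_fraction > 0:
        ul = params.repeat_unit_len
        n_copies = int(params.repeat_fraction * G / ul)
        units = [rng.integers(0, 4, ul, dtype=np.uint8) for _ in range(_REPEAT_FAMILIES)]
        cand = np.sort(rng.integers(0, max(G - ul, 1), 3 * n_copies + 8))
        positions: List[int] = []
        prev_end = -1
        for p in cand:
            if p > prev_end:
                positions.append(int(p))
                prev_end = p + ul
                if len(positions) == n_copies:
                    break
        for i, p in enumerate(positions):
            u = units[i % _REPEAT_FAMILIES].copy()
            mut = rng.random(ul) < _REPEAT_COPY_DIVERGENCE
            u[mut] = (u[mut] + rng.integers(1, 4, int(mut.sum()), dtype=np.uint8)) % 4
            codes[p : p + ul] = u

    variants = _plant_variants(codes, params, rng)
    hap0 = codes_to_seq(codes)
    hap1 = apply_variants(hap0, variants)
    return (
        SequenceRecord("hap0", hap0),
        SequenceRecord("hap1", hap1),
        variants,
    )


def _plant_variants(
    codes: np.ndarray, params: SimulationParams, rng: np.random.Generator
) -> List[Variant]:
    G = codes.size
    bases = "ACGT"
    indel_pos = np.flatnonzero(rng.random(G) < params.het_indel_rate)
    indels: List[Variant] = []
    prev_end = -1
    for p in indel_pos:
        p = int(p)
        if p <= prev_end:
            continue
        length = int(rng.geometric(params.indel_len_geom_p))
        if rng.random() < 0.5 and p + length < G:  # deletion of hap0[p:p+length]
            ref = codes_to_seq(codes[p : p + length])
            indels.append(Variant(p, "del", ref, ""))
            prev_end = p + length
        else:  # insertion before hap0 position p
            alt = "".join(bases[i] for i in rng.integers(0, 4, length))
            indels.append(Variant(p, "ins", "", alt))
            prev_end = p
    blocked = np.zeros(G, dtype=bool)
    for v in indels:
        blocked[v.pos : max(v.pos + max(len(v.ref), 1), v.pos + 1)] = True
    snp_pos = np.flatnonzero((rng.random(G) < params.het_snp_rate) & ~blocked)
    shift = rng.integers(1, 4, snp_pos.size)
    snps = [
        Variant(int(p), "snp", bases[codes[p]], bases[(codes[p] + s) % 4])
        for p, s in zip(snp_pos, shift)
    ]
    return sorted(snps + indels, key=lambda v: (v.pos, v.kind))


def apply_variants(hap0: str, variants: Sequence[Variant]) -> str:
    """Reconstruct haplotype 1 from haplotype 0 plus the variant ledger."""
    parts: List[str] = []
    cur = 0
    for v in sorted(variants, key=lambda v: (v.pos, v.kind)):
        if v.pos < cur:
            raise ValueError(f"overlapping variants at {v.pos}")
        parts.append(hap0[cur : v.pos])
        if v.kind == "snp":
            if hap0[v.pos] != v.ref:
                raise ValueError(f"snp ref mismatch at {v.pos}")
            parts.append(v.alt)
            cur = v.pos + 1
        elif v.kind == "del":
            if hap0[v.pos : v.pos + len(v.ref)] != v.ref:
                raise ValueError(f"del ref mismatch at {v.pos}")
            cur = v.pos + len(v.ref)
        elif v.kind == "ins":
            parts.append(v.alt)
            cur = v.pos
        else:
            raise ValueError(f"unknown variant kind {v.kind!r}")
    parts.append(hap0[cur:])
    return "".join(parts)


class _CoordMap:
    """Monotone map from haplotype-0 to haplotype-1 coordinates."""

    def __init__(self, variants: Sequence[Variant]):
        pos = [0]
        shift = [0]
        s = 0
        for v in sorted(variants, key=lambda v: v.pos):
            if v.kind == "ins":
                s += len(v.alt)
                pos.append(v.pos)
                shift.append(s)
            elif v.kind == "del":
                s -= len(v.ref)
                pos.append(v.pos + len(v.ref))
                shift.append(s)
        self._pos = np.array(pos)
        self._shift = np.array(shift)

    def __call__(self, x: int) -> int:
        i = int(np.searchsorted(self._pos, x, side="right")) - 1
        return x + int(self._shift[i])


# ---------------------------------------------------------------------------
# Elementary contigs


def fragment_to_contigs(
    hap0: SequenceRecord,
    hap1: SequenceRecord,
    variants: Sequence[Variant],
    params: SimulationParams,
) -> Tuple[List[SequenceRecord], List[SyntheticTruth]]:
    """Tile haplotype 0 into primary contigs and emit allelic copies.

    Primary contigs tile haplotype 0 exactly (no gaps, no overlaps); a
    fraction ``allelic_fraction`` of them also get an allelic contig cut
    from the corresponding haplotype-1 span, truncated by 5-20% so the
    allelic copy is strictly the shorter of the pair.
    """
    rng = np.random.default_rng([params.seed, 1])
    G = len(hap0.sequence)
    lengths: List[int] = []
    remaining = G
    while remaining > 0:
        L = max(params.contig_len_min, int(rng.normal(params.contig_len_mean, params.contig_len_mean / 3)))
        if remaining - L < params.contig_len_min:
            L = remaining
        lengths.append(min(L, remaining))
        remaining -= lengths[-1]
    starts = np.concatenate(([0], np.cumsum(lengths)[:-1]))

    contigs: List[SequenceRecord] = []
    truths: List[SyntheticTruth] = []
    idx = 0
    for s, L in zip(starts, lengths):
        cid = f"tig{idx:05d}"
        idx += 1
        contigs.append(SequenceRecord(cid, hap0.sequence[s : s + L]))
        truths.append(SyntheticTruth(cid, "primary", 0, int(s), int(s + L)))

    coord = _CoordMap(variants)
    n_allelic = int(round(params.allelic_fraction * len(lengths)))
    chosen = rng.choice(len(lengths), size=n_allelic, replace=False) if n_allelic else []
    for ci in sorted(int(c) for c in np.atleast_1d(chosen)):
        s, L = int(starts[ci]), int(lengths[ci])
        s1, e1 = coord(s), coord(s + L)
        seq1 = hap1.sequence[s1:e1]
        f = rng.uniform(0.05, 0.20)
        newlen = min(int(round((1 - f) * len(seq1))), L - 1)
        if newlen < 1:
            continue
        kept_frac = newlen / max(len(seq1), 1)
        if rng.random() < 0.5:
            seq = seq1[:newlen]
            src = (s, s + int(round(L * kept_frac)))
        else:
            seq = seq1[-newlen:]
            src = (s + L - int(round(L * kept_frac)), s + L)
        cid = f"tig{idx:05d}"
        idx += 1
        contigs.append(SequenceRecord(cid, seq))
        truths.append(SyntheticTruth(cid, "allelic", 1, src[0], src[1]))
    return contigs, truths


def write_truth(truths: Sequence[SyntheticTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\trole\thaplotype\tsrc_start\tsrc_end\n")
        for t in truths:
            fh.write(f"{t.contig_id}\t{t.role}\t{t.haplotype}\t{t.src_start}\t{t.src_end}\n")


def read_truth(path) -> List[SyntheticTruth]:
    out: List[SyntheticTruth] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("contig_id"):
            raise ValueError(f"{path}: not a truth table")
        for line in fh:
            cid, role, hap, s, e = line.rstrip("\n").split("\t")
            out.append(SyntheticTruth(cid, role, int(hap), int(s), int(e)))
    return out


# ---------------------------------------------------------------------------
# Short reads


def simulate_read_pairs(
    genome: SequenceRecord,
    coverage: float,
    read_len: int = 100,
    err_rate: float = 0.0,
    n_rate: float = 0.0,
    adapter_rate: float = 0.0,
    dup_rate: float = 0.0,
    insert_mean: int = 420,
    seed: int = 0,
    adapter: str = DEFAULT_ADAPTER,
) -> List[Tuple[SequenceRecord, SequenceRecord]]:
    """Paired reads with the library artefacts the QC stage targets.

    Pair count is ceil(coverage * genome / (2 * read_len)). Substitution
    errors get sub-Q20 qualities; a fraction ``n_rate`` of reads carry an N;
    ``adapter_rate`` of reads have their tail overwritten by the 33-bp
    adapter; ``dup_rate`` of pairs are exact re-emissions of earlier pairs.
    """
    if read_len >= insert_mean:
        raise ValueError("read_len must be smaller than insert_mean")
    rng = np.random.default_rng(seed)
    G = len(genome.sequence)
    n_pairs = int(np.ceil(coverage * G / (2 * read_len)))
    if n_pairs == 0:
        return []
    gcodes = seq_to_codes(genome.sequence)
    ins = np.clip(
        rng.normal(insert_mean, 0.05 * insert_mean, n_pairs).astype(np.int64),
        read_len,
        G,
    )
    start = (rng.random(n_pairs) * (G - ins + 1)).astype(np.int64)
    offs = np.arange(read_len)
    r1 = gcodes[start[:, None] + offs].copy()
    r2 = gcodes[(start + ins)[:, None] - read_len + offs]
    r2 = (3 - r2[:, ::-1]).astype(np.uint8)  # reverse complement

    reads = np.stack([r1, r2])  # (2, n, read_len)
    quals = rng.integers(35, 41, reads.shape).astype(np.int16)
    if err_rate > 0:
        err = rng.random(reads.shape) < err_rate
        reads[err] = (reads[err] + rng.integers(1, 4, int(err.sum()), dtype=np.uint8)) % 4
        quals[err] = rng.integers(2, 20, int(err.sum()))
    if n_rate > 0:
        hit = rng.random((2, n_pairs)) < n_rate
        npos = rng.integers(0, read_len, (2, n_pairs))
        for m in range(2):
            rows = np.flatnonzero(hit[m])
            reads[m, rows, npos[m, rows]] = 4
            quals[m, rows, npos[m, rows]] = 2
    if adapter_rate > 0:
        acodes = seq_to_codes(adapter)
        alen = min(len(acodes), read_len)
        hit = rng.random((2, n_pairs)) < adapter_rate
        for m in range(2):
            rows = np.flatnonzero(hit[m])
            reads[m, rows, read_len - alen :] = acodes[:alen]

    dup_src = np.full(n_pairs, -1, dtype=np.int64)
    if dup_rate > 0:
        is_dup = rng.random(n_pairs) < dup_rate
        is_dup[0] = False
        rows = np.flatnonzero(is_dup)
        dup_src[rows] = (rng.random(rows.size) * rows).astype(np.int64)

    # one decode per mate file, then cheap string slicing per read
    big = [codes_to_seq(reads[m].reshape(-1)) for m in range(2)]
    pairs: List[Tuple[SequenceRecord, SequenceRecord]] = []
    for i in range(n_pairs):
        j = int(dup_src[i])
        if j >= 0:
            src1, src2 = pairs[j]
            pairs.append(
                (
                    SequenceRecord(f"pair{i:07d}", src1.sequence, src1.quality.copy()),
                    SequenceRecord(f"pair{i:07d}", src2.sequence, src2.quality.copy()),
                )
            )
            continue
        o = i * read_len
        pairs.append(
            (
                SequenceRecord(f"pair{i:07d}", big[0][o : o + read_len], quals[0, i]),
                SequenceRecord(f"pair{i:07d}", big[1][o : o + read_len], quals[1, i]),
            )
        )
    return pairs


def simulate_short_reads(
    genome: SequenceRecord,
    coverage: float,
    out1,
    out2,
    **kwargs,
) -> Tuple[str, str]:
    """Simulate paired reads (see simulate_read_pairs) and write FASTQ files."""
    pairs = simulate_read_pairs(genome, coverage, **kwargs)
    write_fastq_pairs(pairs, out1, out2)
    return str(out1), str(out2)


# ---------------------------------------------------------------------------
# PacBio-like subreads


def simulate_subreads(
    genome: SequenceRecord,
    coverage: float,
    len_lognorm_mu: float = 8.9,
    len_lognorm_sigma: float = 0.8,
    score_beta_a: float = 25.1,
    score_beta_b: float = 4.9,
    seed: int = 0,
) -> List[Tuple[SequenceRecord, float]]:
    """Subreads with log-normal lengths and Beta-distributed read scores.

    Defaults give a mean read score of ~0.837 (Beta mean a/(a+b)); total
    bases accumulate until coverage * genome length is reached.
    """
    rng = np.random.default_rng(seed)
    G = len(genome.sequence)
    target = coverage * G
    out: List[Tuple[SequenceRecord, float]] = []
    total = 0
    i = 0
    while total < target:
        L = max(50, min(int(rng.lognormal(len_lognorm_mu, len_lognorm_sigma)), G))
        s = int(rng.integers(0, G - L + 1))
        score = float(rng.beta(score_beta_a, score_beta_b))
        out.append((SequenceRecord(f"subread{i:07d}", genome.sequence[s : s + L]), score))
        total += L
        i += 1
    return out


# ---------------------------------------------------------------------------
# Self-alignment matches


def simulate_self_matches(
    contigs: Sequence[SequenceRecord], anchor_k: int = 21
) -> List[AlignmentMatch]:
    """Exact-anchor stand-in for whole-genome self-alignment.

    For every pair of distinct contigs, k-mers unique within both contigs
    and shared between them seed matches; seeds on a common diagonal are
    merged and extended to maximal exact matches (forward strand; identity
    1.0). Each contig also yields its trivial full-length self match, which
    downstream classification ignores as Case I.
    """
    if anchor_k < 12:
        raise ValueError("anchor_k below 12 hits the spurious-anchor floor")
    uniq_codes: List[np.ndarray] = []
    uniq_pos: List[np.ndarray] = []
    code_arrays: List[np.ndarray] = []
    for rec in contigs:
        codes = seq_to_codes(rec.sequence)
        code_arrays.append(codes)
        kc, valid = kmer_codes(codes, anchor_k, canonical=False)
        kc = np.where(valid, kc, -1)
        u, first, counts = np.unique(kc, return_index=True, return_counts=True)
        keep = (counts == 1) & (u >= 0)
        uniq_codes.append(u[keep])
        uniq_pos.append(first[keep])

    matches: List[AlignmentMatch] = []
    for rec, codes in zip(contigs, code_arrays):
        L = len(rec.sequence)
        if L > 0:
            matches.append(
                AlignmentMatch(rec.id, rec.id, 0, L, 0, L, "+", 1.0, L)
            )

    n = len(contigs)
    all_codes = np.concatenate(uniq_codes) if uniq_codes else np.empty(0, np.int64)
    all_ci = np.concatenate(
        [np.full(a.size, i, dtype=np.int64) for i, a in enumerate(uniq_codes)]
    ) if n else np.empty(0, np.int64)
    all_pos = np.concatenate(uniq_pos) if uniq_pos else np.empty(0, np.int64)
    order = np.argsort(all_codes, kind="stable")
    codes_s, ci_s, pos_s = all_codes[order], all_ci[order], all_pos[order]
    bounds = np.concatenate(
        ([0], np.flatnonzero(codes_s[1:] != codes_s[:-1]) + 1, [codes_s.size])
    )
    seeds: Dict[Tuple[int, int], List[Tuple[int, int]]] = {}
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        if b1 - b0 < 2 or b1 - b0 > 16:
            continue
        members = [(int(ci_s[x]), int(pos_s[x])) for x in range(b0, b1)]
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                (c1, p1), (c2, p2) = members[ai], members[bi]
                if c1 == c2:
                    continue
                if c1 > c2:
                    (c1, p1), (c2, p2) = (c2, p2), (c1, p1)
                seeds.setdefault((c1, c2), []).append((p1, p2))

    for (c1, c2), pairlist in seeds.items():
        q = np.array([p for p, _ in pairlist])
        t = np.array([p for _, p in pairlist])
        diag = t - q
        order = np.lexsort((q, diag))
        q, t, diag = q[order], t[order], diag[order]
        brk = np.concatenate(
            ([True], (diag[1:] != diag[:-1]) | (q[1:] - q[:-1] > anchor_k))
        )
        run_starts = np.flatnonzero(brk)
        run_ends = np.append(run_starts[1:], q.size)
        seen = set()
        for si, ei in zip(run_starts, run_ends):
            qs, qe = int(q[si]), int(q[ei - 1]) + anchor_k
            d = int(diag[si])
            qs, qe = _extend_exact(code_arrays[c1], code_arrays[c2], qs, qe, d)
            if (qs, qe, d) in seen:  # runs split by non-unique k-mers re-merge
                continue
            seen.add((qs, qe, d))
            m = AlignmentMatch(
                contigs[c1].id, contigs[c2].id,
                qs, qe, qs + d, qe + d, "+", 1.0, qe - qs,
            )
            matches.append(m)
            matches.append(m.flipped())
    return matches


def _extend_exact(
    a: np.ndarray, b: np.ndarray, qs: int, qe: int, diag: int
) -> Tuple[int, int]:
    while qs > 0 and qs + diag > 0 and a[qs - 1] == b[qs - 1 + diag] and a[qs - 1] != 4:
        qs -= 1
    while qe < a.size and qe + diag < b.size and a[qe] == b[qe + diag] and a[qe] != 4:
        qe += 1
    return qs, qe
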