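"""k-mer spectrum genome profiling.

Canonical k-mers (lexicographic minimum of a window and its reverse
complement) are counted over a read set; the depth->distinct-k-mer histogram
is then used to place the error valley and the coverage peaks and to derive
a genome-size and heterozygosity estimate.

Model: in a diploid at per-base heterozygosity h, a k-window overlaps no
heterozygous site with probability (1-h)^k and then contributes one k-mer
form at full depth c; otherwise it contributes two forms at depth ~c/2.
Writing b for the fraction of distinct k-mers that sit in the half-depth
(heterozygous) peak, weighted so one heterozygous window balances against
its two forms, b ~= 1 - (1-h)^k, giving h = 1 - (1-b)^(1/k). Genome size is
total above-valley k-mer mass divided by the homozygous peak depth.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Iterable, Optional, Tuple

import numpy as np

from ._kmers import seq_to_codes, kmer_codes
from .io_formats import SequenceRecord


@dataclasses.dataclass
class KmerHistogram:
    """Depth -> number of distinct canonical k-mers observed at that depth."""

    k: int
    counts: Dict[int, int]

    @property
    def total_kmers(self) -> int:
        """Total counted k-mer windows: sum of depth * count."""
        return sum(d * c for d, c in self.counts.items())

    def as_array(self) -> np.ndarray:
        """Dense counts indexed by depth (index 0 unused)."""
        maxd = max(self.counts) if self.counts else 0
        arr = np.zeros(maxd + 2, dtype=np.int64)
        for d, c in self.counts.items():
            arr[d] = c
        return arr

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for d in sorted(self.counts):
                fh.write(f"{d}\t{self.counts[d]}\n")

    @classmethod
    def read_tsv(cls, path, k: int) -> "KmerHistogram":
        counts: Dict[int, int] = {}
        with open(path) as fh:
            for line in fh:
                d, c = line.split()
                counts[int(d)] = int(c)
        return cls(k=k, counts=counts)


@dataclasses.dataclass
class GenomeProfile:
    error_cutoff: int
    hom_peak_depth: int
    het_peak_depth: Optional[int] = None
    genome_size: Optional[float] = None
    heterozygosity: Optional[float] = None


def count_kmers(records: Iterable[SequenceRecord], k: int) -> KmerHistogram:
    """Count canonical k-mers across records; windows containing N are skipped."""
    if k % 2 == 0:
        raise ValueError("k must be odd (even k makes canonicalization ambiguous)")
    if not 11 <= k <= 31:
        raise ValueError("k must be in [11, 31]")
    joined = "N".join(rec.sequence for rec in records)
    codes, valid = kmer_codes(seq_to_codes(joined), k, canonical=True)
    kmers = codes[valid]
    if kmers.size == 0:
        return KmerHistogram(k=k, counts={})
    _, multiplicities = np.unique(kmers, return_counts=True)
    depths, ncounts = np.unique(multiplicities, return_counts=True)
    return KmerHistogram(k=k, counts={int(d): int(c) for d, c in zip(depths, ncounts)})


def _smooth3(arr: np.ndarray) -> np.ndarray:
    padded = np.concatenate(([0.0], arr.astype(float), [0.0]))
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def find_peaks(hist: KmerHistogram) -> Tuple[int, Optional[int], int]:
    """Locate (error_cutoff, het_peak_depth or None, hom_peak_depth).

    The error cutoff is the first local minimum of counts by depth (the
    valley between the error spike and the coverage peaks). The tallest
    smoothed peak beyond the cutoff is either the homozygous peak (unimodal
    spectrum) or — in a strongly heterozygous diploid, where half-depth
    k-mer forms can outnumber full-depth ones — the heterozygous peak. The
    two are disambiguated by looking for a companion local maximum near
    twice the tallest peak's depth: if one exists, it is the homozygous peak
    and the tallest is the heterozygous one. Otherwise a heterozygous peak
    is the tallest local maximum strictly between the cutoff and 75% of the
    homozygous peak depth, kept only if it reaches 5% of the homozygous
    peak height.
    """
    if not hist.counts:
        raise ValueError("empty histogram")
    a = hist.as_array()
    cutoff = None
    for d in range(1, len(a) - 1):
        if a[d] < a[d + 1]:
            cutoff = d
            break
    if cutoff is None:
        raise ValueError("no coverage peak (monotone-decreasing spectrum)")
    sm = _smooth3(a)
    maxima = [
        d
        for d in range(cutoff + 1, len(a))
        if sm[d] >= (sm[d - 1] if d - 1 > cutoff else 0.0)
        and (d + 1 >= len(a) or sm[d] >= sm[d + 1])
    ]
    tallest = max(maxima, key=lambda d: sm[d])
    # companion peak near 2x the tallest depth => tallest is the het peak
    companions = [
        d
        for d in maxima
        if 1.5 * tallest <= d <= 2.5 * tallest and sm[d] >= 0.05 * sm[tallest]
    ]
    if companions:
        hom_peak = max(companions, key=lambda d: sm[d])
        return cutoff, tallest, hom_peak
    hom_peak = tallest
    hom_height = sm[hom_peak]
    het_peak = None
    hi = int(np.floor(0.75 * hom_peak))
    best_height = 0.0
    for d in maxima:
        if cutoff < d < hi and sm[d] >= 0.05 * hom_height and sm[d] > best_height:
            best_height = sm[d]
            het_peak = d
    return cutoff, het_peak, hom_peak


def estimate_genome_size(hist: KmerHistogram, profile: GenomeProfile) -> float:
    """Above-valley k-mer mass divided by the homozygous peak depth."""
    if profile.error_cutoff >= profile.hom_peak_depth:
        raise ValueError("error cutoff at or beyond the coverage peak")
    mass = sum(d * c for d, c in hist.counts.items() if d > profile.error_cutoff)
    return mass / profile.hom_peak_depth


def estimate_heterozygosity(hist: KmerHistogram, profile: GenomeProfile, k: int) -> float:
    """Two-peak k-mer conversion h = 1 - (1-b)^(1/k); 0 when no het peak."""
    if profile.het_peak_depth is None:
        return 0.0
    mid = (profile.het_peak_depth + profile.hom_peak_depth) / 2.0
    het_distinct = sum(
        c for d, c in hist.counts.items() if profile.error_cutoff < d <= mid
    )
    hom_distinct = sum(c for d, c in hist.counts.items() if d > mid)
    denom = het_distinct + 2 * hom_distinct
    if denom == 0:
        return 0.0
    b = het_distinct / denom
    return 1.0 - (1.0 - b) ** (1.0 / k)


def profile_reads(records: Iterable[SequenceRecord], k: int = 17) -> Tuple[KmerHistogram, GenomeProfile]:
    """Count, find peaks, and fill in genome size and heterozygosity."""
    hist = count_kmers(records, k)
    cutoff, het, hom = find_peaks(hist)
    profile = GenomeProfile(error_cutoff=cutoff, het_peak_depth=het, hom_peak_depth=hom)
    profile.genome_size = estimate_genome_size(hist, profile)
    profile.heterozygosity = estimate_heterozygosity(hist, profile, k)
    return hist, profile
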