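"""Readers and writers for the external formats the pipeline touches.

Domain types live here (`SequenceRecord`, `AlignmentMatch`, `MaskInterval`)
and every other module consumes/produces them. Internal coordinates are
0-based half-open everywhere; only the readers and writers convert
(show-coords input is 1-based inclusive, PAF and BED already half-open).
Minus-strand matches are stored PAF-style: ascending coordinates on both
sequences plus a strand flag.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO

# every byte maps to N except ACGTN (case-folded); U is read as T
_NORM = {c: "N" for c in map(chr, range(256))}
_NORM.update({c: c for c in "ACGTN"})
_NORM.update({c.lower(): c for c in "ACGTN"})
_NORM.update({"U": "T", "u": "T"})
_NORM_TABLE = str.maketrans(_NORM)


def normalize_sequence(seq: str) -> str:
    """Uppercase, U->T, any non-ACGTN symbol -> N."""
    return seq.translate(_NORM_TABLE)


@dataclasses.dataclass
class SequenceRecord:
    """A named DNA sequence with optional per-base Phred qualities."""

    id: str
    sequence: str
    quality: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be nonempty")
        if self.quality is not None:
            self.quality = np.asarray(self.quality, dtype=np.int16)
            if len(self.quality) != len(self.sequence):
                raise ValueError(
                    f"{self.id}: quality length {len(self.quality)} != "
                    f"sequence length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class AlignmentMatch:
    """A local match between two contigs (0-based half-open coordinates)."""

    query_id: str
    target_id: str
    qstart: int
    qend: int
    tstart: int
    tend: int
    strand: str = "+"
    identity: float = 1.0
    match_len: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.qstart < self.qend):
            raise ValueError(f"bad query interval [{self.qstart},{self.qend})")
        if not (0 <= self.tstart < self.tend):
            raise ValueError(f"bad target interval [{self.tstart},{self.tend})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.match_len <= 0:
            raise ValueError("match_len must be positive")

    def flipped(self) -> "AlignmentMatch":
        """The same match seen from the other contig."""
        return dataclasses.replace(
            self,
            query_id=self.target_id,
            target_id=self.query_id,
            qstart=self.tstart,
            qend=self.tend,
            tstart=self.qstart,
            tend=self.qend,
        )


@dataclasses.dataclass(frozen=True)
class MaskInterval:
    """A repeat-masked span on a contig (0-based half-open)."""

    contig_id: str
    start: int
    end: int
    label: str = "interspersed"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty mask interval [{self.start},{self.end})")


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path) -> List[SequenceRecord]:
    """Read a FASTA file into normalized SequenceRecords (file order)."""
    records: List[SequenceRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, normalize_sequence(str(rec.seq))))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def _read_fastq(path) -> List[SequenceRecord]:
    records: List[SequenceRecord] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 != 0:
        raise ValueError(f"{path}: truncated FASTQ, {len(lines)} lines")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@"):
            raise ValueError(f"{path}: line {i + 1}: expected '@' header")
        if not plus.startswith("+"):
            raise ValueError(f"{path}: line {i + 3}: expected '+' separator")
        if len(seq) != len(qual):
            raise ValueError(f"{path}: line {i + 4}: quality length mismatch")
        q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
        if q.size and q.min() < 0:
            raise ValueError(f"{path}: line {i + 4}: quality below Phred+33 range")
        records.append(SequenceRecord(head[1:].split()[0], normalize_sequence(seq), q))
    return records


def read_fastq_pairs(path1, path2) -> List[Tuple[SequenceRecord, SequenceRecord]]:
    """Read two mate FASTQ files (Phred+33) into pairs in file order."""
    r1, r2 = _read_fastq(path1), _read_fastq(path2)
    if len(r1) != len(r2):
        raise ValueError(
            f"mate files differ in record count: {len(r1)} vs {len(r2)}"
        )
    return list(zip(r1, r2))


def write_fastq_pairs(
    pairs: Sequence[Tuple[SequenceRecord, SequenceRecord]], path1, path2
) -> None:
    for idx, path in ((0, path1), (1, path2)):
        with open(path, "w") as fh:
            for pair in pairs:
                rec = pair[idx]
                if rec.quality is None:
                    raise ValueError(f"{rec.id}: FASTQ output requires qualities")
                qual = (rec.quality.astype(np.uint8) + 33).tobytes().decode("ascii")
                fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Alignment match tables


def read_matches(path, dialect: str) -> List[AlignmentMatch]:
    """Read a pairwise match table.

    dialect "coords": tab-separated `show-coords -H -T` style rows
    (S1 E1 S2 E2 LEN1 LEN2 %IDY REF QRY; 1-based inclusive; reverse matches
    have S2 > E2 on the query). dialect "paf": standard minimap2/PAF columns
    (already 0-based half-open). Both are normalized to 0-based half-open
    with ascending coordinates plus a strand flag.
    """
    if dialect not in ("coords", "paf"):
        raise ValueError(f"unknown dialect {dialect!r}")
    matches: List[AlignmentMatch] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "coords":
                    matches.append(_parse_coords(fields))
                else:
                    matches.append(_parse_paf(fields))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return matches


def _parse_coords(fields: Sequence[str]) -> AlignmentMatch:
    s1, e1, s2, e2 = (int(x) for x in fields[:4])
    len1, len2 = int(fields[4]), int(fields[5])
    idy = float(fields[6])
    ref_id, qry_id = fields[7], fields[8]
    strand = "+"
    if s2 > e2:
        strand = "-"
        s2, e2 = e2, s2
    if s1 > e1:
        raise ValueError("reference coordinates must ascend")
    return AlignmentMatch(
        query_id=qry_id,
        target_id=ref_id,
        qstart=s2 - 1,
        qend=e2,
        tstart=s1 - 1,
        tend=e1,
        strand=strand,
        identity=idy / 100.0,
        match_len=len2,
    )


def _parse_paf(fields: Sequence[str]) -> AlignmentMatch:
    if len(fields) < 12:
        raise ValueError(f"PAF line has {len(fields)} columns, expected >= 12")
    nmatch, alnlen = int(fields[9]), int(fields[10])
    return AlignmentMatch(
        query_id=fields[0],
        target_id=fields[5],
        qstart=int(fields[2]),
        qend=int(fields[3]),
        tstart=int(fields[7]),
        tend=int(fields[8]),
        strand=fields[4],
        identity=(nmatch / alnlen) if alnlen else 0.0,
        match_len=nmatch,
    )


def write_matches_paf(
    matches: Iterable[AlignmentMatch], path, lengths: Optional[Dict[str, int]] = None
) -> None:
    """Write matches as minimal 12-column PAF (lengths 0 when unknown)."""
    lengths = lengths or {}
    with open(path, "w") as fh:
        for m in matches:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        m.query_id,
                        lengths.get(m.query_id, 0),
                        m.qstart,
                        m.qend,
                        m.strand,
                        m.target_id,
                        lengths.get(m.target_id, 0),
                        m.tstart,
                        m.tend,
                        m.match_len,
                        max(m.match_len, int(round(m.match_len / max(m.identity, 1e-9)))),
                        255,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED masks


def read_bed(path) -> List[MaskInterval]:
    """BED3(+name) -> MaskIntervals; unlabeled rows get label 'external'."""
    out: List[MaskInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                label = fields[3] if len(fields) > 3 else "external"
                out.append(MaskInterval(fields[0], int(fields[1]), int(fields[2]), label))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[MaskInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig_id}\t{iv.start}\t{iv.end}\t{iv.label}\n")


# ---------------------------------------------------------------------------
# Partition output


def write_partition(classifications, sequences: Sequence[SequenceRecord], hgc_path, as_path, table_path) -> None:
    """Write the HGC/AS split: two FASTA files plus a TSV report.

    `classifications` is a sequence of ContigClassification (see as_detect);
    every classified contig must exist in `sequences`.
    """
    by_id = {rec.id: rec for rec in sequences}
    missing = [c.contig_id for c in classifications if c.contig_id not in by_id]
    if missing:
        raise ValueError(f"classified contigs missing from sequence set: {missing[:5]}")
    hgc = [by_id[c.contig_id] for c in classifications if c.label == "HGC"]
    als = [by_id[c.contig_id] for c in classifications if c.label == "AS"]
    write_fasta(hgc, hgc_path)
    write_fasta(als, as_path)
    with open(table_path, "w") as fh:
        fh.write("contig_id\tlabel\tcase\tpartner_id\taligned_fraction\tread_share\trestored\n")
        for c in classifications:
            fh.write(
                f"{c.contig_id}\t{c.label}\t{c.case}\t{c.partner_id or '.'}\t"
                f"{c.aligned_fraction:.4f}\t"
                f"{'.' if c.read_share is None else f'{c.read_share:.4f}'}\t"
                f"{int(c.restored)}\n"
            )


def read_partition_table(path) -> Dict[str, str]:
    """Partition TSV -> {contig_id: label}."""
    labels: Dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("contig_id"):
            raise ValueError(f"{path}: not a partition table")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            labels[fields[0]] = fields[1]
    return labels
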