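"""Simulator contracts: determinism, planted-variant ledger completeness,
tiling conservation, read/subread statistics, anchor matches."""

import numpy as np
import pytest

from hapsever import _intervals
from hapsever.io_formats import SequenceRecord
from hapsever.read_qc import QcParams, filter_pairs
from hapsever import synthetic_data as sd

SMALL = dict(genome_size=200_000, contig_len_mean=15_000, contig_len_min=4_000)


def naive_apply(hap0, variants):
    """Independent reconstruction oracle: apply variants one at a time,
    tracking the coordinate shift explicitly."""
    seq = list(hap0)
    shift = 0
    for v in sorted(variants, key=lambda v: (v.pos, v.kind)):
        p = v.pos + shift
        if v.kind == "snp":
            assert seq[p] == v.ref
            seq[p] = v.alt
        elif v.kind == "del":
            assert "".join(seq[p : p + len(v.ref)]) == v.ref
            del seq[p : p + len(v.ref)]
            shift -= len(v.ref)
        else:
            seq[p:p] = list(v.alt)
            shift += len(v.alt)
    return "".join(seq)


class TestSimulateDiploid:
    def test_zero_rates_give_identical_haplotypes(self):
        p = sd.SimulationParams(het_snp_rate=0, het_indel_rate=0, **SMALL)
        hap0, hap1, variants = sd.simulate_diploid(p)
        assert hap0.sequence == hap1.sequence
        assert variants == []

    def test_snp_divergence_matches_binomial_expectation(self):
        p = sd.SimulationParams(
            genome_size=1_000_000, het_snp_rate=0.0235, het_indel_rate=0,
            repeat_fraction=0, contig_len_mean=50_000, seed=42,
        )
        hap0, hap1, variants = sd.simulate_diploid(p)
        assert len(hap1.sequence) == len(hap0.sequence)
        hamming = sum(a != b for a, b in zip(hap0.sequence, hap1.sequence))
        expected = 0.0235 * 1_000_000
        sd3 = 3 * np.sqrt(expected * (1 - 0.0235))
        assert abs(hamming - expected) < sd3

    def test_same_seed_reproduces_byte_identical_output(self):
        p = sd.SimulationParams(seed=9, **SMALL)
        a = sd.simulate_diploid(p)
        b = sd.simulate_diploid(p)
        assert a[0].sequence == b[0].sequence
        assert a[1].sequence == b[1].sequence
        assert a[2] == b[2]

    def test_variant_ledger_reconstructs_hap1_exactly(self):
        p = sd.SimulationParams(seed=3, **SMALL)
        hap0, hap1, variants = sd.simulate_diploid(p)
        assert naive_apply(hap0.sequence, variants) == hap1.sequence

    def test_excessive_rates_rejected(self):
        with pytest.raises(ValueError, match="0.5"):
            sd.SimulationParams(het_snp_rate=0.6, **SMALL)


class TestFragmentToContigs:
    def _sim(self, **kw):
        p = sd.SimulationParams(seed=5, **{**SMALL, **kw})
        hap0, hap1, variants = sd.simulate_diploid(p)
        return (hap0, hap1, variants, p)

    def test_zero_allelic_fraction_gives_only_primaries(self):
        hap0, hap1, variants, p = self._sim(allelic_fraction=0.0)
        contigs, truths = sd.fragment_to_contigs(hap0, hap1, variants, p)
        assert all(t.role == "primary" for t in truths)

    def test_full_allelic_fraction_pairs_every_primary(self):
        hap0, hap1, variants, p = self._sim(allelic_fraction=1.0)
        contigs, truths = sd.fragment_to_contigs(hap0, hap1, variants, p)
        primaries = [t for t in truths if t.role == "primary"]
        allelics = [t for t in truths if t.role == "allelic"]
        assert len(allelics) == len(primaries)
        # every allelic source interval overlaps >= 80% of itself with a primary
        for a in allelics:
            ov = max(
                _intervals.intersect_length(
                    [(a.src_start, a.src_end)], [(p0.src_start, p0.src_end)]
                )
                for p0 in primaries
            )
            assert ov >= 0.8 * (a.src_end - a.src_start)

    def test_primary_contigs_tile_hap0_exactly(self):
        hap0, hap1, variants, p = self._sim()
        contigs, truths = sd.fragment_to_contigs(hap0, hap1, variants, p)
        by_id = {c.id: c for c in contigs}
        prim = sorted(
            (t for t in truths if t.role == "primary"), key=lambda t: t.src_start
        )
        assert prim[0].src_start == 0
        assert prim[-1].src_end == len(hap0.sequence)
        for a, b in zip(prim, prim[1:]):
            assert a.src_end == b.src_start
        assert sum(len(by_id[t.contig_id]) for t in prim) == len(hap0.sequence)
        reassembled = "".join(by_id[t.contig_id].sequence for t in prim)
        assert reassembled == hap0.sequence

    def test_allelic_contig_strictly_shorter_than_partner(self):
        hap0, hap1, variants, p = self._sim(allelic_fraction=1.0)
        contigs, truths = sd.fragment_to_contigs(hap0, hap1, variants, p)
        by_id = {c.id: len(c) for c in contigs}
        prim = [t for t in truths if t.role == "primary"]
        for a in (t for t in truths if t.role == "allelic"):
            partner = max(
                prim,
                key=lambda p0: _intervals.intersect_length(
                    [(a.src_start, a.src_end)], [(p0.src_start, p0.src_end)]
                ),
            )
            assert by_id[a.contig_id] < by_id[partner.contig_id]


class TestShortReads:
    def test_pair_count_formula(self):
        g = SequenceRecord("g", "ACGT" * 25_000)  # 100 kb
        pairs = sd.simulate_read_pairs(g, coverage=50, read_len=100, seed=0)
        assert len(pairs) == 25_000  # ceil(50*1e5/(2*100))

    def test_clean_library_passes_all_qc_filters(self):
        rng = np.random.default_rng(0)
        g = SequenceRecord("g", "".join("ACGT"[i] for i in rng.integers(0, 4, 50_000)))
        pairs = sd.simulate_read_pairs(g, coverage=4, seed=1)
        kept, report = filter_pairs(pairs, QcParams(adapter_seq=sd.DEFAULT_ADAPTER))
        # no systematic drops; the only possible losses are chance events
        # (a random 12-mer tail matching the adapter within the mismatch
        # budget, or two pairs sampled at identical coordinates)
        assert report.counts["has_n"] == 0
        assert report.counts["lowq"] == 0
        assert report.counts["adapter"] <= 3
        assert report.counts["kept"] >= 0.995 * len(pairs)

    def test_duplicate_rate_recovered_by_deduplication(self):
        rng = np.random.default_rng(1)
        g = SequenceRecord("g", "".join("ACGT"[i] for i in rng.integers(0, 4, 100_000)))
        pairs = sd.simulate_read_pairs(g, coverage=2, dup_rate=0.1, seed=2)
        n = len(pairs)  # 1000 pairs
        kept, report = filter_pairs(pairs, QcParams())
        removed = report.counts["duplicate"]
        assert abs(removed - 0.1 * n) < 3 * np.sqrt(n * 0.1 * 0.9)

    def test_artefact_rates_show_up(self):
        rng = np.random.default_rng(2)
        g = SequenceRecord("g", "".join("ACGT"[i] for i in rng.integers(0, 4, 100_000)))
        pairs = sd.simulate_read_pairs(
            g, coverage=2, n_rate=0.2, adapter_rate=0.2, err_rate=0.01, seed=3
        )
        reads = [r for pr in pairs for r in pr]
        with_n = sum("N" in r.sequence for r in reads)
        assert abs(with_n / len(reads) - 0.2) < 0.05
        with_adapter = sum(
            r.sequence.endswith(sd.DEFAULT_ADAPTER[:33]) for r in reads
        )
        assert with_adapter > 0.1 * len(reads)
        # substitution errors carry sub-Q20 qualities
        lowq = sum(int((r.quality < 20).sum()) for r in reads)
        assert lowq > 0

    def test_fastq_files_round_trip(self, tmp_path):
        from hapsever.io_formats import read_fastq_pairs

        rng = np.random.default_rng(3)
        g = SequenceRecord("g", "".join("ACGT"[i] for i in rng.integers(0, 4, 20_000)))
        sd.simulate_short_reads(g, 1, tmp_path / "1.fq", tmp_path / "2.fq", seed=4)
        back = read_fastq_pairs(tmp_path / "1.fq", tmp_path / "2.fq")
        assert len(back) == 100  # ceil(1 * 20000 / (2 * 100))


class TestSubreads:
    def test_zero_coverage_empty(self):
        g = SequenceRecord("g", "ACGT" * 1000)
        assert sd.simulate_subreads(g, 0) == []

    def test_score_distribution_mean(self):
        rng = np.random.default_rng(4)
        g = SequenceRecord("g", "".join("ACGT"[i] for i in rng.integers(0, 4, 100_000)))
        subs = sd.simulate_subreads(
            g, coverage=120, len_lognorm_mu=7.0, len_lognorm_sigma=0.5, seed=5
        )
        scores = np.array([s for _, s in subs])
        assert len(scores) >= 5_000
        assert abs(scores.mean() - 0.837) < 0.02

    def test_total_bases_near_target_and_deterministic(self):
        g = SequenceRecord("g", "ACGT" * 25_000)
        a = sd.simulate_subreads(g, 3, seed=6)
        b = sd.simulate_subreads(g, 3, seed=6)
        assert [(r.id, r.sequence, s) for r, s in a] == [(r.id, r.sequence, s) for r, s in b]
        total = sum(len(r) for r, _ in a)
        assert total >= 3 * 100_000


class TestSelfMatches:
    def test_identical_contigs_give_full_length_match_each_direction(self):
        rng = np.random.default_rng(5)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 5_000))
        contigs = [SequenceRecord("a", seq), SequenceRecord("b", seq)]
        ms = sd.simulate_self_matches(contigs)
        ab = [m for m in ms if m.query_id == "a" and m.target_id == "b"]
        ba = [m for m in ms if m.query_id == "b" and m.target_id == "a"]
        assert len(ab) == 1 and ab[0].qstart == 0 and ab[0].qend == 5_000
        assert len(ba) == 1 and ba[0].qstart == 0 and ba[0].qend == 5_000

    def test_self_pairs_present_for_case_i(self):
        rng = np.random.default_rng(6)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2_000))
        ms = sd.simulate_self_matches([SequenceRecord("a", seq)])
        assert [(m.query_id, m.target_id, m.qend) for m in ms] == [("a", "a", 2_000)]

    def test_unrelated_contigs_share_nothing_at_k21(self):
        rng = np.random.default_rng(7)
        contigs = [
            SequenceRecord("a", "".join("ACGT"[i] for i in rng.integers(0, 4, 10_000))),
            SequenceRecord("b", "".join("ACGT"[i] for i in rng.integers(0, 4, 10_000))),
        ]
        ms = [m for m in sd.simulate_self_matches(contigs, 21) if m.query_id != m.target_id]
        assert ms == []

    def test_allelic_pair_chained_span_exceeds_85pct(self):
        from hapsever.as_detect import chain_matches, merged_coverage

        rng = np.random.default_rng(8)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 40_000))
        alt = list(seq)
        for pos in rng.choice(40_000, int(40_000 * 0.0235), replace=False):
            alt[pos] = "ACGT"[("ACGT".index(alt[pos]) + 1) % 4]
        contigs = [SequenceRecord("p", seq), SequenceRecord("q", "".join(alt[:36_000]))]
        ms = [
            m
            for m in sd.simulate_self_matches(contigs)
            if m.query_id == "q" and m.target_id == "p"
        ]
        chains = chain_matches(ms)
        frac, _ = merged_coverage(chains, 36_000)
        assert frac > 0.85

    def test_low_anchor_k_rejected(self):
        with pytest.raises(ValueError, match="12"):
            sd.simulate_self_matches([SequenceRecord("a", "ACGT" * 100)], anchor_k=11)
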