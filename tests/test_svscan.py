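"""Read simulation and the discordant-pair translocation scanner."""
import numpy as np
import pysam
import pytest

from lynchscreen.config import SvScanConfig
from lynchscreen.readsim import (
    BreakpointAnatomy,
    complex_junction_anatomy,
    random_reference,
    simulate_translocation_reads,
)
from lynchscreen.svscan import (
    DiscordanceReason,
    DiscordantPair,
    InsertStats,
    cluster_discordant,
    estimate_insert_stats,
    extract_region,
    filter_clusters,
    is_discordant,
    quality_filter,
    scan,
)

HEADER = pysam.AlignmentHeader.from_dict({
    "HD": {"VN": "1.6"},
    "SQ": [{"SN": "chr3", "LN": 10_000_000}, {"SN": "chr5", "LN": 10_000_000}],
})


def make_read(name="r1", chrom="chr3", pos=1000, mapq=60, quals=40,
              mate_chrom="chr3", mate_pos=1300, reverse=False,
              mate_reverse=True, tlen=400, length=100, cigar=None,
              mate_unmapped=False):
    seg = pysam.AlignedSegment(HEADER)
    seg.query_name = name
    seg.query_sequence = "A" * length
    seg.query_qualities = pysam.qualitystring_to_array(chr(quals + 33) * length)
    seg.reference_name = chrom
    seg.reference_start = pos
    seg.mapping_quality = mapq
    seg.cigartuples = cigar or [(0, length)]
    seg.is_paired = True
    seg.is_reverse = reverse
    seg.mate_is_reverse = mate_reverse
    seg.mate_is_unmapped = mate_unmapped
    if not mate_unmapped:
        seg.next_reference_name = mate_chrom
        seg.next_reference_start = mate_pos
    seg.template_length = tlen
    return seg


STATS = InsertStats(mean=400.0, sd=40.0, n_pairs=1000)


class TestQualityFilter:
    def test_mapq_zero_dropped(self):
        assert not quality_filter(make_read(mapq=0, quals=40))

    def test_mean_qual_25_dropped(self):
        assert not quality_filter(make_read(mapq=60, quals=25))

    def test_mean_qual_just_above_kept(self):
        assert quality_filter(make_read(mapq=60, quals=26))


class TestIsDiscordant:
    def test_interchromosomal_pair(self):
        r = make_read(mate_chrom="chr5", tlen=0)
        assert is_discordant(r, STATS) is DiscordanceReason.MATE_UNALIGNED_OR_INTERCHROM

    def test_mate_unmapped(self):
        r = make_read(mate_unmapped=True)
        assert is_discordant(r, STATS) is DiscordanceReason.MATE_UNALIGNED_OR_INTERCHROM

    def test_same_strand_orientation(self):
        r = make_read(reverse=False, mate_reverse=False)
        assert is_discordant(r, STATS) is DiscordanceReason.ORIENTATION

    def test_rf_orientation(self):
        r = make_read(pos=1300, mate_pos=1000, reverse=True, mate_reverse=False,
                      tlen=-400)
        assert is_discordant(r, STATS) is None  # leftmost (mate) is forward: FR
        r = make_read(pos=1000, mate_pos=1300, reverse=True, mate_reverse=False,
                      tlen=400)
        assert is_discordant(r, STATS) is DiscordanceReason.ORIENTATION

    def test_within_three_sd_concordant(self):
        r = make_read(tlen=int(STATS.mean + 2 * STATS.sd))
        assert is_discordant(r, STATS) is None

    def test_beyond_three_sd_discordant(self):
        r = make_read(tlen=int(STATS.mean + 4 * STATS.sd), mate_pos=1000 + 560)
        assert is_discordant(r, STATS) is DiscordanceReason.INSERT_SIZE

    def test_reason_order_interchrom_beats_orientation(self):
        r = make_read(mate_chrom="chr5", reverse=False, mate_reverse=False, tlen=0)
        assert is_discordant(r, STATS) is DiscordanceReason.MATE_UNALIGNED_OR_INTERCHROM


def _oracle_discordant(read, mean, sd, k=3.0):
    """Independent brute-force re-derivation of the pair-discordance rules."""
    if not read.is_paired:
        return None
    if read.mate_is_unmapped or read.reference_name != read.next_reference_name:
        return "mate_unaligned_or_interchrom"
    if read.is_reverse == read.mate_is_reverse:
        return "orientation"
    if read.is_reverse:
        fr = read.next_reference_start <= read.reference_start
    else:
        fr = read.reference_start <= read.next_reference_start
    if not fr:
        return "orientation"
    if abs(abs(read.template_length) - mean) > k * sd:
        return "insert_size"
    return None


def test_discordance_matches_brute_force_oracle():
    rng = np.random.default_rng(9)
    reads = []
    for i in range(1000):
        same_chrom = rng.random() < 0.8
        pos = int(rng.integers(0, 100_000))
        mate_pos = pos + int(rng.integers(-800, 800))
        reverse = bool(rng.random() < 0.5)
        mate_reverse = bool(rng.random() < 0.5)
        tlen = (mate_pos - pos) + (100 if mate_pos >= pos else -100)
        reads.append(make_read(
            name=f"r{i}", pos=pos, mate_pos=max(0, mate_pos),
            mate_chrom="chr3" if same_chrom else "chr5",
            reverse=reverse, mate_reverse=mate_reverse,
            tlen=tlen if same_chrom else 0,
            mate_unmapped=bool(rng.random() < 0.05),
        ))
    for r in reads:
        got = is_discordant(r, STATS)
        want = _oracle_discordant(r, STATS.mean, STATS.sd)
        assert (got.value if got else None) == want, r.query_name


class TestExtractRegion:
    def test_flank_inclusion_and_exclusion(self):
        near = make_read(name="near", pos=1_000_000 - 50_000)
        far = make_read(name="far", pos=1_000_000 - 150_000)
        out = extract_region([near, far], ("chr3", 1_000_000, 1_010_000),
                             flank=100_000)
        assert [r.query_name for r in out] == ["near"]

    def test_zero_flank_gene_body_only(self):
        inside = make_read(name="in", pos=1_000_500)
        outside = make_read(name="out", pos=990_000)
        out = extract_region([inside, outside], ("chr3", 1_000_000, 1_010_000),
                             flank=0)
        assert [r.query_name for r in out] == ["in"]

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError):
            extract_region([make_read()], ("chrX", 0, 100), flank=0)


class TestClustering:
    @staticmethod
    def _pair(name, pa, pb, ca="chr3", cb="chr5"):
        return DiscordantPair(name, ca, pa, pa + 100, cb, pb, pb + 100)

    def test_tight_pairs_form_one_cluster(self):
        pairs = [self._pair(f"p{i}", 5000 + i * 30, 8000 + i * 30) for i in range(10)]
        clusters = cluster_discordant(pairs, max_gap=300)
        assert len(clusters) == 1
        assert clusters[0].support == 10

    def test_distant_pairs_split(self):
        pairs = [self._pair("a", 5000, 8000), self._pair("b", 15_000, 8000)]
        assert len(cluster_discordant(pairs, max_gap=500)) == 2

    def test_empty_input(self):
        assert cluster_discordant([], 500) == []

    def test_order_invariance(self):
        pairs = [self._pair(f"p{i}", 5000 + i * 37, 9000 - i * 11) for i in range(12)]
        a = cluster_discordant(pairs, 400)
        b = cluster_discordant(list(reversed(pairs)), 400)
        assert [(c.interval_a, c.interval_b, c.support) for c in a] == \
            [(c.interval_a, c.interval_b, c.support) for c in b]


class TestFilterClusters:
    def _cluster(self, support=5):
        pairs = [self._make_pair(i) for i in range(support)]
        return cluster_discordant(pairs, 500)[0]

    @staticmethod
    def _make_pair(i):
        return DiscordantPair(f"p{i}", "chr3", 5000 + i, 5100 + i,
                              "chr5", 9000 + i, 9100 + i)

    def test_repeat_mask_drops(self):
        cl = self._cluster()
        assert filter_clusters([cl], repeat_mask=[("chr3", 4000, 6000)]) == []

    def test_common_in_controls_drops(self):
        cl = self._cluster()
        out = filter_clusters([cl], control_presence=lambda c: 40,
                              n_controls=100, max_control_fraction=0.01)
        assert out == []

    def test_clean_supported_cluster_retained(self):
        cl = self._cluster(support=36)
        out = filter_clusters([cl], repeat_mask=[("chr3", 0, 100)],
                              control_presence=lambda c: 0, n_controls=100)
        assert len(out) == 1

    def test_below_min_support_drops(self):
        cl = self._cluster(support=2)
        assert filter_clusters([cl], min_support=3) == []


class TestSimulator:
    REF_A = random_reference(4000, 101)
    REF_B = random_reference(4000, 202)

    def test_truth_record_stores_anatomy(self):
        an = BreakpointAnatomy(dup_len=3, del_len=5, insert_seq="ACGTACGTAC",
                               insert_reverse_complement=True)
        sim = simulate_translocation_reads(self.REF_A, self.REF_B, an, depth=0,
                                           seed=1)
        assert sim.truth["dup_len"] == 3
        assert sim.truth["del_len"] == 5
        assert sim.truth["insert_seq"] == "ACGTACGTAC"
        assert sim.reads == []

    def test_seed_determinism_sam_bytes(self, tmp_path):
        an = complex_junction_anatomy(self.REF_A, 2000)
        p1, p2 = tmp_path / "a.sam", tmp_path / "b.sam"
        simulate_translocation_reads(self.REF_A, self.REF_B, an, depth=10,
                                     seed=5).write(p1)
        simulate_translocation_reads(self.REF_A, self.REF_B, an, depth=10,
                                     seed=5).write(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_read_len_beyond_fragment_rejected(self):
        with pytest.raises(ValueError):
            simulate_translocation_reads(self.REF_A, self.REF_B,
                                         BreakpointAnatomy(), depth=5,
                                         insert_mean=80, read_len=100)

    def test_mate_consistency(self):
        an = complex_junction_anatomy(self.REF_A, 2000)
        sim = simulate_translocation_reads(self.REF_A, self.REF_B, an,
                                           depth=10, seed=2)
        by_name = {}
        for r in sim.reads:
            by_name.setdefault(r.query_name, []).append(r)
        for name, (r1, r2) in by_name.items():
            assert r1.next_reference_name == r2.reference_name, name
            assert r1.next_reference_start == r2.reference_start, name
            assert r2.next_reference_name == r1.reference_name, name
            assert r2.next_reference_start == r1.reference_start, name

    def test_junction_reads_are_soft_clipped(self):
        an = complex_junction_anatomy(self.REF_A, 2000)
        sim = simulate_translocation_reads(self.REF_A, self.REF_B, an,
                                           depth=20, seed=3)
        clipped = [r for r in sim.reads
                   if r.cigartuples and any(op == 4 for op, _ in r.cigartuples)]
        assert clipped
        boundaries = {r.reference_end for r in clipped
                      if r.reference_name == "chr3" and r.cigartuples[-1][0] == 4}
        assert 2000 in boundaries


class TestEndToEnd:
    REF_A = random_reference(5000, 11)
    REF_B = random_reference(5000, 22)
    REFS = {"chr3": REF_A, "chr5": REF_B}
    GENE = ("chr3", 2000, 3000)

    def test_exact_recovery_of_breakpoints_and_anatomy(self):
        an = complex_junction_anatomy(self.REF_A, 2500)
        sim = simulate_translocation_reads(self.REF_A, self.REF_B, an,
                                           depth=25, seed=7, bp_a=2500, bp_b=2500)
        calls = scan(sim.reads, self.REFS, self.GENE)
        assert len(calls) == 1
        c = calls[0]
        assert (c.bp_a, c.bp_b) == (2500, 2500)
        assert (c.dup_len, c.del_len) == (3, 5)
        assert c.insert_seq == an.insert_seq
        assert c.insert_reverse_complement is True
        assert c.n_discordant_support >= 3
        assert c.n_softclip_support >= 1

    def test_blunt_junction(self):
        sim = simulate_translocation_reads(self.REF_A, self.REF_B,
                                           BreakpointAnatomy(), depth=25,
                                           seed=8, bp_a=2500, bp_b=2500)
        c = scan(sim.reads, self.REFS, self.GENE)[0]
        assert (c.bp_a, c.bp_b, c.dup_len, c.del_len, c.insert_seq) == \
            (2500, 2500, 0, 0, "")

    def test_adding_concordant_background_never_changes_call(self):
        an = complex_junction_anatomy(self.REF_A, 2500)
        sim = simulate_translocation_reads(self.REF_A, self.REF_B, an,
                                           depth=20, seed=9, bp_a=2500, bp_b=2500)
        base = scan(sim.reads, self.REFS, self.GENE)
        extra = simulate_translocation_reads(
            self.REF_A, self.REF_B, BreakpointAnatomy(), depth=0,
            background_depth=20, seed=10, include_derivatives=False)
        boosted = scan(sim.reads + extra.reads, self.REFS, self.GENE)
        key = [(c.bp_a, c.bp_b, c.dup_len, c.del_len, c.insert_seq) for c in base]
        assert [(c.bp_a, c.bp_b, c.dup_len, c.del_len, c.insert_seq)
                for c in boosted] == key

    def test_dropping_below_min_support_removes_call(self):
        an = complex_junction_anatomy(self.REF_A, 2500)
        sim = simulate_translocation_reads(self.REF_A, self.REF_B, an,
                                           depth=20, seed=11, bp_a=2500, bp_b=2500)
        cfg = SvScanConfig(min_support=10_000)
        assert scan(sim.reads, self.REFS, self.GENE, cfg) == []

    def test_single_spanning_read_matches_deep_call(self):
        """Junction positions from one spanning read equal those from many
        on noiseless input (brute-force boundary search agreement)."""
        an = BreakpointAnatomy(dup_len=2, del_len=0, insert_seq="")
        sim = simulate_translocation_reads(self.REF_A, self.REF_B, an,
                                           depth=30, seed=12, bp_a=2500, bp_b=2500)
        calls = scan(sim.reads, self.REFS, self.GENE)
        deep = calls[0]
        # brute force: every trailing-clip boundary on chr3 among junction reads
        boundaries = {r.reference_end for r in sim.reads
                      if r.reference_name == "chr3" and r.cigartuples
                      and r.cigartuples[-1][0] == 4}
        assert deep.bp_a in boundaries
        assert len(boundaries) == 1  # noiseless input: all reads agree

    def test_insert_stats_require_minimum_pairs(self):
        with pytest.raises(ValueError):
            estimate_insert_stats([make_read()])

    def test_insert_stats_recover_library_geometry(self):
        sim = simulate_translocation_reads(self.REF_A, self.REF_B,
                                           BreakpointAnatomy(), depth=0,
                                           background_depth=30, seed=13,
                                           insert_mean=350, insert_sd=35,
                                           include_derivatives=False)
        stats = estimate_insert_stats(sim.reads)
        assert stats.mean == pytest.approx(350, abs=10)
        assert stats.sd == pytest.approx(35, abs=8)

    def test_no_calls_without_translocation(self):
        for seed in range(5):
            sim = simulate_translocation_reads(
                self.REF_A, self.REF_B, BreakpointAnatomy(), depth=0,
                background_depth=25, seed=seed, include_derivatives=False)
            assert scan(sim.reads, self.REFS, self.GENE) == []
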