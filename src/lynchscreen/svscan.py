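"""Discordant-read-pair translocation scan with soft-clip breakpoint inference.

The scan mirrors a targeted structural-variation work-up over a gene plus
100 kb flanks: reads are extracted and quality-filtered (mapping quality 0 or
mean base quality <= 25 excluded), read pairs are flagged discordant when the
mate is unaligned or inter-chromosomal, the orientation is not FR, or the
insert size deviates more than three standard deviations from the library
mean; discordant pairs are clustered by the positions of their two sides,
clusters in repetitive regions or common in controls are discarded, and the
surviving cluster's exact breakpoints and target-site micro-events
(duplication, deletion, inserted motif and its orientation) are inferred from
soft-clipped junction-spanning reads.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pysam
from intervaltree import IntervalTree

from .config import SvScanConfig
from .readsim import revcomp


class DiscordanceReason(str, Enum):
    MATE_UNALIGNED_OR_INTERCHROM = "mate_unaligned_or_interchrom"
    ORIENTATION = "orientation"
    INSERT_SIZE = "insert_size"


@dataclass
class InsertStats:
    """Insert-size distribution of the sequencing library (proper FR pairs)."""

    mean: float
    sd: float
    n_pairs: int


@dataclass
class DiscordantPair:
    name: str
    chrom_a: str
    pos_a: int  # leftmost aligned position of the side-a read (0-based)
    end_a: int
    chrom_b: str
    pos_b: int
    end_b: int


@dataclass
class DiscordantCluster:
    chrom_a: str
    interval_a: tuple[int, int]
    chrom_b: str
    interval_b: tuple[int, int]
    pairs: list[DiscordantPair] = field(default_factory=list)
    control_carrier_count: int = 0

    @property
    def support(self) -> int:
        return len(self.pairs)


@dataclass
class TranslocationCall:
    chrom_a: str
    bp_a: Optional[int]  # 0-based junction (first base beyond the retained side-a prefix)
    chrom_b: str
    bp_b: Optional[int]
    dup_len: Optional[int] = None
    del_len: Optional[int] = None
    insert_seq: Optional[str] = None
    insert_reverse_complement: Optional[bool] = None
    n_softclip_support: int = 0
    n_discordant_support: int = 0
    interval_a: Optional[tuple[int, int]] = None  # low-resolution fallback
    interval_b: Optional[tuple[int, int]] = None


# ---------------------------------------------------------------------------
# Read extraction and filtering
# ---------------------------------------------------------------------------


def read_sam(path: str | Path) -> list[pysam.AlignedSegment]:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        return list(fh)


def extract_region(
    reads: Iterable[pysam.AlignedSegment] | str | Path,
    gene_interval: tuple[str, int, int],
    flank: int = 100_000,
    known_chroms: Optional[set[str]] = None,
) -> list[pysam.AlignedSegment]:
    """Reads overlapping the gene interval extended by ``flank`` on both sides.

    The interval is half-open 0-based internally and clipped at zero.

    Raises
    ------
    ValueError
        If flank is negative or the chromosome is unknown.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if isinstance(reads, (str, Path)):
        reads = read_sam(reads)
    else:
        reads = list(reads)
    chrom, start, end = gene_interval
    chroms = known_chroms
    if chroms is None:
        chroms = {r.reference_name for r in reads if r.reference_name is not None}
    if chroms and chrom not in chroms:
        raise ValueError(f"unknown chromosome {chrom!r}")
    lo = max(0, start - flank)
    hi = end + flank
    out = []
    for r in reads:
        if r.is_unmapped or r.reference_name != chrom:
            continue
        if r.reference_start < hi and (r.reference_end or r.reference_start + 1) > lo:
            out.append(r)
    return out


def quality_filter(read: pysam.AlignedSegment,
                   config: Optional[SvScanConfig] = None) -> bool:
    """Keep flag: drop reads with mapping quality 0 or mean base quality <= 25."""
    cfg = config or SvScanConfig()
    if read.mapping_quality <= cfg.min_mapq_exclusive:
        return False
    quals = read.query_qualities
    if quals is not None and len(quals) > 0:
        if float(np.mean(quals)) <= cfg.max_mean_basequal_drop:
            return False
    return True


# ---------------------------------------------------------------------------
# Insert statistics and discordance
# ---------------------------------------------------------------------------


def estimate_insert_stats(
    reads: Iterable[pysam.AlignedSegment],
    config: Optional[SvScanConfig] = None,
    max_pairs: int = 100_000,
) -> InsertStats:
    """Mean/SD of |insert size| over proper same-chromosome FR pairs,
    with symmetric 1%/99% trimming against contamination."""
    cfg = config or SvScanConfig()
    tlens: list[float] = []
    for r in reads:
        if len(tlens) >= max_pairs:
            break
        if r.is_unmapped or r.mate_is_unmapped or not r.is_paired:
            continue
        if r.reference_name != r.next_reference_name:
            continue
        if r.template_length <= 0:  # count each pair once, from its left read
            continue
        if not _is_fr(r):
            continue
        tlens.append(float(r.template_length))
    if len(tlens) < cfg.min_insert_pairs:
        raise ValueError(
            f"only {len(tlens)} proper pairs; need >= {cfg.min_insert_pairs} "
            "to estimate insert statistics"
        )
    arr = np.sort(np.asarray(tlens))
    k = int(len(arr) * cfg.insert_trim_fraction)
    if k > 0:
        arr = arr[k: len(arr) - k]
    sd = float(arr.std(ddof=1))
    if k > 0:
        # symmetric trimming shrinks a Gaussian SD deterministically; undo it
        from scipy import stats as _st

        alpha = cfg.insert_trim_fraction
        z = _st.norm.ppf(1.0 - alpha)
        trunc_var = 1.0 - 2.0 * z * _st.norm.pdf(z) / (1.0 - 2.0 * alpha)
        sd /= float(np.sqrt(trunc_var))
    return InsertStats(mean=float(arr.mean()), sd=sd, n_pairs=len(arr))


def _is_fr(read: pysam.AlignedSegment) -> bool:
    """True when the pair is in the expected forward/reverse orientation."""
    if read.is_reverse == read.mate_is_reverse:
        return False
    return not _leftmost_is_reverse(read)


def _leftmost_is_reverse(read: pysam.AlignedSegment) -> bool:
    if read.reference_start < read.next_reference_start:
        return read.is_reverse
    if read.reference_start > read.next_reference_start:
        return read.mate_is_reverse
    # same start: FR if exactly one is reverse (already checked); call the
    # forward one leftmost
    return False


def is_discordant(
    read: pysam.AlignedSegment,
    stats: InsertStats,
    config: Optional[SvScanConfig] = None,
) -> Optional[DiscordanceReason]:
    """Classify a read's pair as discordant, returning the (ordered) reason.

    Criteria, evaluated in order: (1) mate unaligned or on a different
    chromosome; (2) unexpected orientation (anything but FR); (3) insert size
    deviating more than ``insert_sd_multiplier`` standard deviations from the
    library mean. Returns None for concordant pairs.
    """
    cfg = config or SvScanConfig()
    if not read.is_paired:
        return None
    if read.mate_is_unmapped or read.next_reference_name is None:
        return DiscordanceReason.MATE_UNALIGNED_OR_INTERCHROM
    if read.reference_name != read.next_reference_name:
        return DiscordanceReason.MATE_UNALIGNED_OR_INTERCHROM
    if read.is_reverse == read.mate_is_reverse or _leftmost_is_reverse(read):
        return DiscordanceReason.ORIENTATION
    tlen = abs(read.template_length)
    if abs(tlen - stats.mean) > cfg.insert_sd_multiplier * stats.sd:
        return DiscordanceReason.INSERT_SIZE
    return None


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def pair_up(reads: Iterable[pysam.AlignedSegment]) -> list[DiscordantPair]:
    """Collapse mate records into one canonically ordered pair per read name."""
    by_name: dict[str, list[pysam.AlignedSegment]] = defaultdict(list)
    for r in reads:
        by_name[r.query_name].append(r)
    pairs: list[DiscordantPair] = []
    for name in sorted(by_name):
        mates = by_name[name]
        ends = []
        for r in mates[:2]:
            ends.append((r.reference_name, r.reference_start,
                         r.reference_end or r.reference_start + 1))
        if len(ends) == 1:  # mate outside the extracted region: use mate fields
            r = mates[0]
            ends.append((r.next_reference_name, r.next_reference_start,
                         r.next_reference_start + 1))
        ends.sort(key=lambda e: (str(e[0]), e[1]))
        (ca, pa, ea), (cb, pb, eb) = ends
        pairs.append(DiscordantPair(name, ca, pa, ea, cb, pb, eb))
    return pairs


def cluster_discordant(
    pairs: Sequence[DiscordantPair], max_gap: int = 500
) -> list[DiscordantCluster]:
    """Single-linkage clustering of discordant pairs.

    Pairs join a cluster when their chromosome pair matches and both sides
    lie within ``max_gap`` of some member. Input order does not matter
    (pairs are sorted internally).
    """
    groups: dict[tuple[str, str], list[DiscordantPair]] = defaultdict(list)
    for p in pairs:
        groups[(p.chrom_a, p.chrom_b)].append(p)
    clusters: list[DiscordantCluster] = []
    for (ca, cb), members in sorted(groups.items()):
        members = sorted(members, key=lambda p: (p.pos_a, p.pos_b, p.name))
        n = len(members)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if members[j].pos_a - members[i].end_a > max_gap:
                    break
                near_a = _gap(members[i].pos_a, members[i].end_a,
                              members[j].pos_a, members[j].end_a) <= max_gap
                near_b = _gap(members[i].pos_b, members[i].end_b,
                              members[j].pos_b, members[j].end_b) <= max_gap
                if near_a and near_b:
                    parent[find(i)] = find(j)
        by_root: dict[int, list[DiscordantPair]] = defaultdict(list)
        for i, p in enumerate(members):
            by_root[find(i)].append(p)
        for root in sorted(by_root, key=lambda r: members[r].pos_a):
            ps = by_root[root]
            clusters.append(
                DiscordantCluster(
                    chrom_a=ca,
                    interval_a=(min(p.pos_a for p in ps), max(p.end_a for p in ps)),
                    chrom_b=cb,
                    interval_b=(min(p.pos_b for p in ps), max(p.end_b for p in ps)),
                    pairs=ps,
                )
            )
    return clusters


def _gap(s1: int, e1: int, s2: int, e2: int) -> int:
    if e1 >= s2 and e2 >= s1:
        return 0
    return max(s2 - e1, s1 - e2)


def filter_clusters(
    clusters: Sequence[DiscordantCluster],
    repeat_mask: Sequence[tuple[str, int, int]] = (),
    control_presence: Optional[Callable[[DiscordantCluster], int]] = None,
    n_controls: int = 0,
    min_support: int = 3,
    max_control_fraction: float = 0.01,
) -> list[DiscordantCluster]:
    """Drop repetitive-region clusters, weakly supported clusters, and
    clusters common in sequenced controls."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for chrom, start, end in repeat_mask:
        trees[chrom].addi(start, end)
    out = []
    for cl in clusters:
        if cl.support < min_support:
            continue
        if trees and (
            trees[cl.chrom_a].overlap(*cl.interval_a)
            or trees[cl.chrom_b].overlap(*cl.interval_b)
        ):
            continue
        if control_presence is not None and n_controls > 0:
            count = control_presence(cl)
            cl.control_carrier_count = count
            if count / n_controls > max_control_fraction:
                continue
        out.append(cl)
    return out


# ---------------------------------------------------------------------------
# Breakpoint inference from soft-clipped reads
# ---------------------------------------------------------------------------


def _clip_boundaries(
    softclipped: Iterable[pysam.AlignedSegment],
    chrom: str,
    interval: tuple[int, int],
    pad: int,
) -> tuple[Counter, Counter, dict[int, list[str]], dict[int, list[str]]]:
    """Soft-clip boundary tallies within a window around a cluster side.

    Returns (right-clip boundary counts, left-clip boundary counts,
    right-clip tail sequences keyed by boundary, left-clip head sequences).
    """
    lo, hi = interval[0] - pad, interval[1] + pad
    right = Counter()
    left = Counter()
    tails: dict[int, list[str]] = defaultdict(list)
    heads: dict[int, list[str]] = defaultdict(list)
    for r in softclipped:
        if r.is_unmapped or r.reference_name != chrom:
            continue
        if not (lo <= r.reference_start <= hi or lo <= (r.reference_end or 0) <= hi):
            continue
        cig = r.cigartuples or []
        seq = r.query_sequence or ""
        if len(cig) >= 2 and cig[-1][0] == 4:  # trailing soft clip
            boundary = r.reference_end
            right[boundary] += 1
            tails[boundary].append(seq[len(seq) - cig[-1][1]:])
        if len(cig) >= 2 and cig[0][0] == 4:  # leading soft clip
            boundary = r.reference_start
            left[boundary] += 1
            heads[boundary].append(seq[: cig[0][1]])
    return right, left, tails, heads


def _modal(counter: Counter) -> Optional[int]:
    """Most frequent boundary; ties break toward the smaller coordinate."""
    if not counter:
        return None
    best = max(counter.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0]


def _consensus(seqs: list[str]) -> str:
    """Position-wise majority consensus of left-anchored sequences."""
    if not seqs:
        return ""
    length = max(len(s) for s in seqs)
    out = []
    for i in range(length):
        votes = Counter(s[i] for s in seqs if len(s) > i)
        out.append(votes.most_common(1)[0][0])
    return "".join(out)


def _match_mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def infer_breakpoint(
    cluster: DiscordantCluster,
    softclipped: Sequence[pysam.AlignedSegment],
    refs: dict[str, str],
    config: Optional[SvScanConfig] = None,
) -> TranslocationCall:
    """Resolve exact junctions and target-site anatomy from soft-clipped reads.

    The junction on each side is the modal soft-clip boundary (ties toward
    the smaller coordinate). On each side, a right-clip boundary above the
    left-clip boundary indicates duplicated bases (present on both
    derivatives); the reverse indicates deleted bases. Any inserted motif is
    the prefix of the consensus clipped tail that does not align to the
    partner reference at its junction; the motif is flagged
    reverse-complement when its reverse complement (but not the motif itself)
    occurs near either junction. Without spanning soft-clips the call falls
    back to the discordant-cluster intervals with anatomy unset.
    """
    cfg = config or SvScanConfig()
    pad = cfg.cluster_max_gap
    right_a, left_a, tails_a, _ = _clip_boundaries(
        softclipped, cluster.chrom_a, cluster.interval_a, pad)
    right_b, left_b, tails_b, _ = _clip_boundaries(
        softclipped, cluster.chrom_b, cluster.interval_b, pad)

    ra, la = _modal(right_a), _modal(left_a)
    rb, lb = _modal(right_b), _modal(left_b)
    n_support = sum(right_a.values()) + sum(left_a.values()) + \
        sum(right_b.values()) + sum(left_b.values())
    if ra is None or rb is None or la is None or lb is None:
        return TranslocationCall(
            chrom_a=cluster.chrom_a, bp_a=None,
            chrom_b=cluster.chrom_b, bp_b=None,
            n_softclip_support=n_support,
            n_discordant_support=cluster.support,
            interval_a=cluster.interval_a, interval_b=cluster.interval_b,
        )

    dup_len = max(0, ra - la) + max(0, rb - lb)
    del_len = max(0, la - ra) + max(0, lb - rb)

    # insert: consensus tail beyond the side-a junction, matched against the
    # partner reference starting at its left-clip boundary
    insert_seq = None
    insert_rc = None
    ref_b = refs.get(cluster.chrom_b)
    tail = _consensus(tails_a.get(ra, []))
    if ref_b is not None and tail:
        insert_seq = _insert_from_tail(tail, ref_b, lb)
    if insert_seq is not None:
        if insert_seq == "":
            insert_rc = False
        else:
            insert_rc = _insert_orientation(
                insert_seq, refs, cluster.chrom_a, ra, cluster.chrom_b, lb)
    return TranslocationCall(
        chrom_a=cluster.chrom_a, bp_a=ra,
        chrom_b=cluster.chrom_b, bp_b=rb,
        dup_len=dup_len, del_len=del_len,
        insert_seq=insert_seq, insert_reverse_complement=insert_rc,
        n_softclip_support=n_support,
        n_discordant_support=cluster.support,
    )


def _insert_from_tail(tail: str, partner_ref: str, junction: int) -> str:
    """Shortest prefix of the clipped tail that leaves the remainder aligning
    to the partner reference at its junction."""
    best_k = None
    best_score = None
    for k in range(0, len(tail)):
        ref_seg = partner_ref[junction: junction + len(tail) - k]
        if len(ref_seg) == 0:
            break
        mism = _match_mismatches(tail[k:], ref_seg)
        frac = mism / len(ref_seg)
        score = (frac, k)
        if best_score is None or score < best_score:
            best_score = score
            best_k = k
        if mism == 0:
            return tail[:k]
    return tail[:best_k] if best_k is not None else ""


def _insert_orientation(
    insert_seq: str,
    refs: dict[str, str],
    chrom_a: str, bp_a: int,
    chrom_b: str, bp_b: int,
    window: int = 60,
) -> Optional[bool]:
    neighbourhoods = []
    for chrom, bp in ((chrom_a, bp_a), (chrom_b, bp_b)):
        ref = refs.get(chrom)
        if ref is not None:
            neighbourhoods.append(ref[max(0, bp - window): bp + window])
    fwd = any(insert_seq in nb for nb in neighbourhoods)
    rev = any(revcomp(insert_seq) in nb for nb in neighbourhoods)
    if rev and not fwd:
        return True
    if fwd:
        return False
    return None


# ---------------------------------------------------------------------------
# End-to-end scan
# ---------------------------------------------------------------------------


def scan(
    reads: Iterable[pysam.AlignedSegment] | str | Path,
    refs: dict[str, str],
    gene_interval: tuple[str, int, int],
    config: Optional[SvScanConfig] = None,
    repeat_mask: Sequence[tuple[str, int, int]] = (),
    control_presence: Optional[Callable[[DiscordantCluster], int]] = None,
    n_controls: int = 0,
) -> list[TranslocationCall]:
    """Run the full targeted scan and return translocation calls."""
    cfg = config or SvScanConfig()
    if isinstance(reads, (str, Path)):
        reads = read_sam(reads)
    all_kept = [r for r in reads if quality_filter(r, cfg)]
    region_reads = extract_region(all_kept, gene_interval, cfg.flank,
                                  known_chroms=set(refs))
    stats = estimate_insert_stats(region_reads, cfg)
    discordant = [r for r in region_reads if is_discordant(r, stats, cfg) is not None]
    pairs = pair_up(discordant)
    clusters = cluster_discordant(pairs, cfg.cluster_max_gap)
    # a translocation joins two chromosomes; same-chromosome discordant
    # clusters (deletions, inversions, insert-size outliers) are out of scope
    clusters = [cl for cl in clusters if cl.chrom_a != cl.chrom_b]
    clusters = filter_clusters(
        clusters, repeat_mask, control_presence, n_controls,
        cfg.min_support, cfg.max_control_fraction,
    )
    # junction-spanning soft-clipped reads may sit on either chromosome
    softclipped = [
        r for r in all_kept
        if r.cigartuples and (r.cigartuples[0][0] == 4 or r.cigartuples[-1][0] == 4)
    ]
    return [infer_breakpoint(cl, softclipped, refs, cfg) for cl in clusters]
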