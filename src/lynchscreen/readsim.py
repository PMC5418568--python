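"""Paired-end read simulation across a reciprocal translocation.

A balanced translocation joins two reference sequences into two derivative
chromosomes. Micro-events at the target site are modelled explicitly: a
duplication of the last ``dup_len`` bases of side A present on both
derivatives, a deletion of ``del_len`` bases of side B missing from both, and
an arbitrary motif inserted at one junction (optionally the reverse
complement of nearby sequence). With 0-based junction coordinates ``a`` (side
A) and ``b`` (side B):

    der1 = ref_a[:a] + insert + ref_b[b + del_len:]
    der2 = ref_b[:b] + ref_a[a - dup_len:]

Reads are emitted as SAM records the way an ideal local aligner would report
them: the longest reference-contiguous run of each read is aligned and the
remainder soft-clipped, so junction-spanning reads carry the clip boundaries
the breakpoint scanner consumes.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pysam

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BreakpointAnatomy:
    """Micro-event anatomy at a translocation target site."""

    dup_len: int = 0
    del_len: int = 0
    insert_seq: str = ""
    insert_reverse_complement: bool = False

    def __post_init__(self) -> None:
        if self.dup_len < 0 or self.del_len < 0:
            raise ValueError("duplication/deletion lengths must be >= 0")


def complex_junction_anatomy(ref_a: str, bp_a: int, motif_len: int = 10,
                       dup_len: int = 3, del_len: int = 5) -> BreakpointAnatomy:
    """The published micro-event pattern: small duplication, small deletion,
    and a nearby motif inserted in reverse-complemented orientation."""
    motif = ref_a[bp_a + 10: bp_a + 10 + motif_len]
    return BreakpointAnatomy(dup_len=dup_len, del_len=del_len,
                             insert_seq=revcomp(motif),
                             insert_reverse_complement=True)


@dataclass
class SimulatedReads:
    """Simulated SAM records plus the ground-truth junction bookkeeping."""

    header: dict
    reads: list[pysam.AlignedSegment]
    truth: dict

    def write(self, sam_path: str | Path, truth_path: Optional[str | Path] = None) -> None:
        sam_path = Path(sam_path)
        with pysam.AlignmentFile(str(sam_path), "wh",
                                 header=pysam.AlignmentHeader.from_dict(self.header)) as fh:
            for read in self.reads:
                fh.write(read)
        if truth_path is not None:
            Path(truth_path).write_text(json.dumps(self.truth, indent=2) + "\n")


def random_reference(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _coordinate_map(segments: list[tuple[Optional[str], int, int]]) -> list[Optional[tuple[str, int]]]:
    """Flatten (chrom, start, end) segments into a per-base (chrom, pos) map;
    chrom None marks inserted (unmappable) bases."""
    out: list[Optional[tuple[str, int]]] = []
    for chrom, start, end in segments:
        if chrom is None:
            out.extend([None] * (end - start))
        else:
            out.extend((chrom, p) for p in range(start, end))
    return out


def _align_to_reference(
    coords: list[Optional[tuple[str, int]]], offset: int, read_len: int
) -> Optional[tuple[str, int, int, int, int]]:
    """Ideal local alignment of a haplotype window to the reference.

    Returns (chrom, ref_start, left_clip, match_len, right_clip) for the
    longest reference-contiguous run within the read, or None when nothing
    maps. Ties go to the earlier run.
    """
    window = coords[offset: offset + read_len]
    runs: list[tuple[int, int, str, int]] = []  # (start_in_read, length, chrom, ref_start)
    i = 0
    while i < read_len:
        base = window[i]
        if base is None:
            i += 1
            continue
        chrom, ref_start = base
        j = i + 1
        while j < read_len:
            nxt = window[j]
            if nxt is None or nxt[0] != chrom or nxt[1] != ref_start + (j - i):
                break
            j += 1
        runs.append((i, j - i, chrom, ref_start))
        i = j
    if not runs:
        return None
    best = max(runs, key=lambda r: (r[1], -r[0]))
    start_in_read, length, chrom, ref_start = best
    return chrom, ref_start, start_in_read, length, read_len - start_in_read - length


def _make_segment(
    header: pysam.AlignmentHeader,
    name: str,
    seq: str,
    quals: list[int],
    chrom: str,
    ref_start: int,
    left_clip: int,
    match_len: int,
    right_clip: int,
    is_read1: bool,
    is_reverse: bool,
) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = name
    seg.query_sequence = seq
    seg.query_qualities = pysam.qualitystring_to_array(
        "".join(chr(q + 33) for q in quals)
    )
    seg.reference_name = chrom
    seg.reference_start = ref_start
    seg.mapping_quality = 60
    cigar = []
    if left_clip:
        cigar.append((4, left_clip))
    cigar.append((0, match_len))
    if right_clip:
        cigar.append((4, right_clip))
    seg.cigartuples = cigar
    seg.is_paired = True
    seg.is_read1 = is_read1
    seg.is_read2 = not is_read1
    seg.is_reverse = is_reverse
    return seg


def simulate_translocation_reads(
    ref_a: str,
    ref_b: str,
    anatomy: BreakpointAnatomy,
    depth: int,
    insert_mean: float = 350.0,
    insert_sd: float = 35.0,
    read_len: int = 100,
    seed: int = 0,
    bp_a: Optional[int] = None,
    bp_b: Optional[int] = None,
    chrom_a: str = "chr3",
    chrom_b: str = "chr5",
    base_error: float = 0.0,
    background_depth: Optional[int] = None,
    include_derivatives: bool = True,
) -> SimulatedReads:
    """Simulate paired-end reads from a carrier of a reciprocal translocation.

    Fragments are drawn from both derivative chromosomes (when
    ``include_derivatives``) and from the two intact references (the normal
    haplotypes, giving concordant background). Junction coordinates default
    to the middle of each reference. ``depth`` is the haploid coverage per
    haplotype; ``depth=0`` emits no reads but still returns the truth record.

    Raises
    ------
    ValueError
        If the read length exceeds the mean fragment length.
    """
    if read_len > insert_mean:
        raise ValueError("read_len exceeds mean fragment length")
    rng = np.random.default_rng(seed)
    a = bp_a if bp_a is not None else len(ref_a) // 2
    b = bp_b if bp_b is not None else len(ref_b) // 2
    if not 0 <= a - anatomy.dup_len <= a <= len(ref_a):
        raise ValueError("side-A junction/duplication outside the reference")
    if not 0 <= b <= b + anatomy.del_len <= len(ref_b):
        raise ValueError("side-B junction/deletion outside the reference")

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": chrom_a, "LN": len(ref_a)},
            {"SN": chrom_b, "LN": len(ref_b)},
        ],
    }
    ph = pysam.AlignmentHeader.from_dict(header)

    ins = anatomy.insert_seq
    der1 = ref_a[:a] + ins + ref_b[b + anatomy.del_len:]
    der1_map = _coordinate_map([
        (chrom_a, 0, a),
        (None, 0, len(ins)),
        (chrom_b, b + anatomy.del_len, len(ref_b)),
    ])
    der2 = ref_b[:b] + ref_a[a - anatomy.dup_len:]
    der2_map = _coordinate_map([
        (chrom_b, 0, b),
        (chrom_a, a - anatomy.dup_len, len(ref_a)),
    ])

    haplotypes = []
    if include_derivatives:
        haplotypes += [("d1", der1, der1_map), ("d2", der2, der2_map)]
    bg_depth = depth if background_depth is None else background_depth
    ref_a_map = _coordinate_map([(chrom_a, 0, len(ref_a))])
    ref_b_map = _coordinate_map([(chrom_b, 0, len(ref_b))])
    background = [("na", ref_a, ref_a_map, bg_depth), ("nb", ref_b, ref_b_map, bg_depth)]

    reads: list[pysam.AlignedSegment] = []
    serial = 0

    def emit_pairs(tag: str, hap: str, coords, hap_depth: int) -> None:
        nonlocal serial
        if hap_depth <= 0:
            return
        n_frags = int(round(hap_depth * len(hap) / (2.0 * read_len)))
        for _ in range(n_frags):
            frag_len = int(round(rng.normal(insert_mean, insert_sd)))
            frag_len = max(frag_len, read_len)
            start = int(rng.integers(0, max(1, len(hap) - frag_len + 1)))
            end = min(start + frag_len, len(hap))
            if end - start < read_len:
                continue
            serial += 1
            name = f"{tag}{serial:06d}"
            fwd_seq = _mutate(hap[start: start + read_len], rng, base_error)
            rev_src = hap[end - read_len: end]
            rev_seq = _mutate(rev_src, rng, base_error)
            aln1 = _align_to_reference(coords, start, read_len)
            aln2 = _align_to_reference(coords, end - read_len, read_len)
            if aln1 is None or aln2 is None:
                continue
            quals = [35] * read_len
            r1 = _make_segment(ph, name, fwd_seq, quals, *aln1,
                               is_read1=True, is_reverse=False)
            # the reverse read's soft clips mirror in read orientation
            # SEQ and CIGAR are stored in reference orientation, so the
            # reverse read keeps the forward-strand window as-is
            r2 = _make_segment(ph, name, rev_seq, quals, *aln2,
                               is_read1=False, is_reverse=True)
            _set_mates(r1, r2)
            reads.extend([r1, r2])

    for tag, hap, coords in haplotypes:
        emit_pairs(tag, hap, coords, depth)
    for tag, hap, coords, d in background:
        emit_pairs(tag, hap, coords, d)

    truth = {
        "schema_version": "1",
        "chrom_a": chrom_a,
        "bp_a": a,
        "chrom_b": chrom_b,
        "bp_b": b,
        "dup_len": anatomy.dup_len,
        "del_len": anatomy.del_len,
        "insert_seq": anatomy.insert_seq,
        "insert_reverse_complement": anatomy.insert_reverse_complement,
    }
    return SimulatedReads(header=header, reads=reads, truth=truth)


def _mutate(seq: str, rng: np.random.Generator, base_error: float) -> str:
    if base_error <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < base_error:
            chars[i] = "ACGT"[int(rng.integers(0, 4))]
    return "".join(chars)


def _set_mates(r1: pysam.AlignedSegment, r2: pysam.AlignedSegment) -> None:
    r1.next_reference_name = r2.reference_name
    r1.next_reference_start = r2.reference_start
    r2.next_reference_name = r1.reference_name
    r2.next_reference_start = r1.reference_start
    r1.mate_is_reverse = r2.is_reverse
    r2.mate_is_reverse = r1.is_reverse
    r1.mate_is_unmapped = False
    r2.mate_is_unmapped = False
    if r1.reference_name == r2.reference_name:
        left = min(r1.reference_start, r2.reference_start)
        right = max(r1.reference_end, r2.reference_end)
        tlen = right - left
        if r1.reference_start <= r2.reference_start:
            r1.template_length = tlen
            r2.template_length = -tlen
        else:
            r1.template_length = -tlen
            r2.template_length = tlen
        proper = (not r1.is_reverse) and r2.is_reverse and (
            r1.reference_start <= r2.reference_start
        )
        r1.is_proper_pair = proper
        r2.is_proper_pair = proper
    else:
        r1.template_length = 0
        r2.template_length = 0
        r1.is_proper_pair = False
        r2.is_proper_pair = False
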