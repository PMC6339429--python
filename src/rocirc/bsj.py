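"""Back-splice junction (BSJ) and cirexon detection from split alignments.

A self-contained, simplified BSJ caller: a read supports a BSJ when two of
its aligned segments on one chromosome appear in inverted genomic order
relative to read order and the junction can be adjusted onto canonical
back-splice flanks (AG upstream of the acceptor, GT downstream of the
donor).  Cirexons (a circRNA's exons) are inferred from single-splice events
inside each BSJ: forward-splice junctions observed in the supporting reads
define donor/acceptor sites, which together with the BSJ boundaries delimit
the exon intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rocirc.align import (
    AlignedSegment,
    SplitAlignment,
    VerifyParams,
    adjust_gt_ag,
    extract_bsj,
    orient_to_anchor,
    select_anchor,
)


@dataclass
class BSJ:
    chrom: str
    start: int  # acceptor (5'-most circle base), 1-based inclusive
    end: int  # donor (3'-most circle base)
    strand: str = "+"
    read_ids: set[str] = field(default_factory=set)

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}|{self.end}"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("BSJ end must exceed start")


@dataclass
class Cirexon:
    chrom: str
    start: int
    end: int
    support_bsj: int = 0
    support_ro: int = 0
    annotated: bool | None = None  # None when no annotation was supplied
    provisional: bool = False  # not contiguously covered / not site-bounded

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("cirexon end must be >= start")


@dataclass
class FSJ:
    donor: int  # cirexon end coordinate
    acceptor: int  # cirexon start coordinate (> donor on plus strand)
    support: int = 0
    co_occurring_read_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.acceptor <= self.donor:
            raise ValueError("FSJ acceptor must be downstream of its donor")


def tidy_mate(
    read: str,
    sa: SplitAlignment,
    genome: dict[str, str],
    params: VerifyParams | None = None,
) -> tuple[str, SplitAlignment] | None:
    """Normalise one mate's split alignment for junction calling.

    Orients the read to its anchor's strand, keeps unambiguous segments near
    the anchor, resolves read-coordinate overlaps, and adjusts junctions onto
    GT/AG.  Returns (oriented_read, adjusted_alignment) or None when the
    mate carries no usable alignment.
    """
    params = params or VerifyParams()
    anchor = select_anchor(sa, params)
    if anchor is None:
        return None
    read, sa = orient_to_anchor(read, sa)
    anchor = sa.anchor
    lo = anchor.ref_start - params.window
    hi = anchor.ref_end + params.window
    candidates = [
        s
        for s in sa.segments
        if s.chrom == anchor.chrom
        and s.strand == "+"
        and s.ref_start >= lo
        and s.ref_end <= hi
        and (s.mapq > 0 or s is anchor)
    ]
    candidates.sort(key=lambda s: (s is not anchor, -s.score, s.read_start))
    kept: list[AlignedSegment] = []
    for seg in candidates:
        if all(
            min(seg.read_end, k.read_end) - max(seg.read_start, k.read_start)
            <= params.flank_check
            for k in kept
        ):
            kept.append(seg)
    if not kept:
        return None
    kept.sort(key=lambda s: s.read_start)
    tidy = SplitAlignment(read_id=sa.read_id, segments=kept)
    select_anchor(tidy, params)
    adjusted = adjust_gt_ag(read, tidy, genome, params)
    if adjusted is None:
        return None
    return read, adjusted


def detect_bsj(
    mate_alignments: dict[str, list[tuple[str, SplitAlignment]]],
    genome: dict[str, str],
    params: VerifyParams | None = None,
    min_reads: int = 1,
) -> tuple[list[BSJ], dict[str, list[SplitAlignment]], dict[str, str]]:
    """Call BSJs from per-pair mate alignments.

    ``mate_alignments`` maps pair id -> [(mate_seq, SplitAlignment), ...].
    A pair supports a BSJ when one of its mates shows a back-spliced split
    alignment with canonical flanks; the other mate contributes coverage and
    forward-splice evidence but cannot itself create a different BSJ call
    for the pair.

    Returns (bsj_list, tidied mate alignments per pair, pair -> bsj_id).
    """
    params = params or VerifyParams()
    tidied: dict[str, list[SplitAlignment]] = {}
    assignment: dict[str, str] = {}
    registry: dict[tuple[str, int, int], BSJ] = {}
    for pair_id, mates in mate_alignments.items():
        keep: list[SplitAlignment] = []
        pair_bsj: tuple[str, int, int] | None = None
        for read, sa in mates:
            result = tidy_mate(read, sa, genome, params)
            if result is None:
                continue
            _oriented, adjusted = result
            keep.append(adjusted)
            if pair_bsj is None:
                hit = extract_bsj(adjusted)
                if hit is not None:
                    pair_bsj = hit
        if keep:
            tidied[pair_id] = keep
        if pair_bsj is not None:
            chrom, a, d = pair_bsj
            bsj = registry.get((chrom, a, d))
            if bsj is None:
                bsj = BSJ(chrom=chrom, start=a, end=d)
                registry[(chrom, a, d)] = bsj
            bsj.read_ids.add(pair_id)
            assignment[pair_id] = bsj.id
    bsjs = [b for b in registry.values() if len(b.read_ids) >= min_reads]
    bsjs.sort(key=lambda b: (b.chrom, b.start, b.end))
    return bsjs, tidied, assignment


def infer_cirexons(
    bsj: BSJ,
    alignments: list[tuple[str, SplitAlignment]],
    annotation: dict[str, list[tuple[str, int, int, str]]] | None = None,
) -> tuple[list[Cirexon], list[FSJ]]:
    """Infer cirexons and forward-splice junctions within one BSJ.

    ``alignments`` are (read_or_pair_id, adjusted SplitAlignment) for the
    BSJ's supporting reads (mates and/or RO-merged reads).  Forward splice
    junctions inside [start, end] define donor/acceptor sites; together with
    the BSJ boundaries these delimit the cirexon intervals.  Support counts
    are distinct reads.  With an annotation, cirexons matching no annotated
    exon are flagged (intronic/intergenic circular fragments).
    """
    import numpy as np

    fsj_reads: dict[tuple[int, int], set[str]] = {}
    for rid, sa in alignments:
        segs = sorted(sa.segments, key=lambda s: s.read_start)
        for left, right in zip(segs, segs[1:]):
            if left.chrom != bsj.chrom:
                continue
            d, a = left.ref_end, right.ref_start
            if a > d and bsj.start <= d and a <= bsj.end:
                fsj_reads.setdefault((d, a), set()).add(rid)
    starts = {bsj.start} | {a for (_d, a) in fsj_reads}
    ends = {bsj.end} | {d for (d, _a) in fsj_reads}
    intervals: list[tuple[int, int]] = []
    for s in sorted(starts):
        cands = [e for e in ends if e >= s]
        if not cands:
            continue
        e = min(cands)
        if (s, e) not in intervals:
            intervals.append((s, e))
    if not intervals:
        intervals = [(bsj.start, bsj.end)]

    # a cirexon is a covered interval between splice sites.  Short uncovered
    # interiors are filled from the genome (the interval is splice-bounded,
    # like the same-cirexon fill for RO reads), but a long hole means a
    # splice event was missed -- an intron would sit inside the interval --
    # so the interval is only provisional and cannot certify completeness.
    max_fill_hole = 50
    span = bsj.end - bsj.start + 1
    depth = np.zeros(span, dtype=np.int32)
    for _rid, sa in alignments:
        for seg in sa.segments:
            if seg.chrom != bsj.chrom:
                continue
            lo = max(seg.ref_start, bsj.start) - bsj.start
            hi = min(seg.ref_end, bsj.end) - bsj.start + 1
            if hi > lo:
                depth[lo:hi] += 1

    def contiguously_covered(s: int, e: int) -> bool:
        window = depth[s - bsj.start : e - bsj.start + 1]
        if window.size == 0 or window[0] == 0 or window[-1] == 0:
            return False
        uncovered = window == 0
        if not uncovered.any():
            return True
        # longest zero run
        runs = np.diff(np.flatnonzero(np.diff(np.concatenate(([0], uncovered, [0])))))
        longest = int(runs[::2].max()) if runs.size else 0
        return longest <= max_fill_hole

    def overlap_reads(s: int, e: int) -> set[str]:
        hits = set()
        for rid, sa in alignments:
            for seg in sa.segments:
                if seg.chrom == bsj.chrom and seg.ref_start <= e and seg.ref_end >= s:
                    hits.add(rid)
                    break
        return hits

    annotated_exons: set[tuple[int, int]] | None = None
    if annotation is not None:
        annotated_exons = {
            (s, e)
            for exons in annotation.values()
            for (c, s, e, _strand) in exons
            if c == bsj.chrom
        }
    cirexons = []
    for s, e in intervals:
        support = len(overlap_reads(s, e))
        cirexons.append(
            Cirexon(
                chrom=bsj.chrom,
                start=s,
                end=e,
                support_bsj=support,
                annotated=None if annotated_exons is None else (s, e) in annotated_exons,
                provisional=not contiguously_covered(s, e),
            )
        )
    fsjs = [
        FSJ(donor=d, acceptor=a, support=len(rids), co_occurring_read_ids=set(rids))
        for (d, a), rids in sorted(fsj_reads.items())
    ]
    return cirexons, fsjs
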