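"""Genome alignment and verification of candidate RO-merged reads.

A candidate merged read is split-aligned to the genome (either by parsing an
external local aligner's SAM, or with the built-in k-mer seed-and-extend
aligner for small references), an anchor alignment is chosen, accumulated
mapping length around the anchor is checked, unmapped or abnormal fragments
are realigned by local dynamic programming, junction boundaries are shifted
onto canonical GT/AG splice signals, and linear-transcript / lariat
contaminants are removed.  All verification logic operates on plus-strand
reads; a read whose anchor maps to the minus strand is reverse-complemented
first.

The fixed stage order is: map -> anchor -> window filter -> realign ->
linear filter -> GT/AG adjustment -> full-length classification.  Each stage
only removes or refines alignments; nothing is invented outside the anchor
window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio import Align

from rocirc.io import revcomp


@dataclass
class VerifyParams:
    min_score: int = 19  # minimum alignment score to keep a segment
    min_anchor_mapq: int = 15  # anchor needs mapq strictly greater
    window: int = 100_000  # bases either side of the anchor
    flank_check: int = 5  # junction flank bases that must match exactly
    boundary_search: int = 10  # max junction shift when hunting GT/AG
    seed_k: int = 16  # internal aligner k-mer size
    seed_step: int = 5  # internal aligner read sampling step
    chain_gap: int = 3  # same-diagonal runs merged across gaps this size
    max_kmer_hits: int = 50  # repeat guard for seeding

    def __post_init__(self) -> None:
        for name in ("min_score", "window", "flank_check", "boundary_search"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class AlignedSegment:
    """One local alignment of a read interval to a genomic interval.

    ``read_start``/``read_end`` are 0-based half-open on the read as given;
    ``ref_start``/``ref_end`` are 1-based inclusive.
    """

    read_start: int
    read_end: int
    chrom: str
    ref_start: int
    ref_end: int
    strand: str = "+"
    score: float = 0.0
    mapq: int = 60

    @property
    def read_len(self) -> int:
        return self.read_end - self.read_start

    def __post_init__(self) -> None:
        if self.read_end <= self.read_start:
            raise ValueError("read interval must be non-empty")
        if self.ref_end < self.ref_start:
            raise ValueError("ref interval must be non-empty")


@dataclass
class SplitAlignment:
    read_id: str
    segments: list[AlignedSegment] = field(default_factory=list)
    anchor_index: int | None = None

    def sort(self) -> None:
        anchor = (
            self.segments[self.anchor_index]
            if self.anchor_index is not None
            else None
        )
        self.segments.sort(key=lambda s: (s.read_start, s.read_end))
        if anchor is not None:
            self.anchor_index = self.segments.index(anchor)

    @property
    def anchor(self) -> AlignedSegment | None:
        if self.anchor_index is None:
            return None
        return self.segments[self.anchor_index]


# ---------------------------------------------------------------------------
# Internal seed-and-extend aligner
# ---------------------------------------------------------------------------


class GenomeIndex:
    """Exact k-mer index over a genome dict, for the internal aligner."""

    def __init__(self, genome: dict[str, str], k: int = 16):
        self.genome = genome
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.items():
            for pos in range(len(seq) - k + 1):
                self.index.setdefault(seq[pos : pos + k], []).append((chrom, pos))

    def hits(self, kmer: str, cap: int) -> list[tuple[str, int]]:
        h = self.index.get(kmer, ())
        return list(h) if len(h) <= cap else []


def _extend_exact(read: str, ref: str, rpos: int, gpos: int, length: int):
    """Extend an exact match [rpos, rpos+length) on a fixed diagonal."""
    a, b = rpos, rpos + length
    diag = gpos - rpos
    while a > 0 and diag + a - 1 >= 0 and read[a - 1] == ref[diag + a - 1]:
        a -= 1
    n = len(read)
    m = len(ref)
    while b < n and diag + b < m and read[b] == ref[diag + b]:
        b += 1
    return a, b


def _align_one_strand(
    seq: str, index: GenomeIndex, params: VerifyParams
) -> list[tuple[str, int, int, int, float]]:
    """Return (chrom, read_start, read_end, diag, score) exact/chained runs."""
    k, step = params.seed_k, params.seed_step
    by_diag: dict[tuple[str, int], list[int]] = {}
    n = len(seq)
    positions = list(range(0, max(n - k, 0) + 1, step))
    if positions and positions[-1] != n - k and n >= k:
        positions.append(n - k)
    for p in positions:
        for chrom, gpos in index.hits(seq[p : p + k], params.max_kmer_hits):
            by_diag.setdefault((chrom, gpos - p), []).append(p)
    out = []
    for (chrom, diag), plist in by_diag.items():
        ref = index.genome[chrom]
        runs: list[tuple[int, int]] = []
        for p in sorted(plist):
            if runs and runs[-1][0] <= p < runs[-1][1]:
                continue  # already inside an extended run
            a, b = _extend_exact(seq, ref, p, p + diag, k)
            runs.append((a, b))
        runs = sorted(set(runs))
        # chain runs separated by small gaps (gap bases scored as mismatches)
        chained: list[tuple[int, int, int]] = []  # (start, end, mismatches)
        for a, b in runs:
            if chained and 0 < a - chained[-1][1] <= params.chain_gap:
                pa, _pb, mm = chained[-1]
                chained[-1] = (pa, b, mm + (a - chained[-1][1]))
            elif chained and a <= chained[-1][1]:
                pa, pb, mm = chained[-1]
                chained[-1] = (pa, max(pb, b), mm)
            else:
                chained.append((a, b, 0))
        for a, b, mm in chained:
            score = (b - a - mm) - 4 * mm
            out.append((chrom, a, b, diag, score))
    return out


def align_read_internal(
    read: str, index: GenomeIndex, params: VerifyParams | None = None
) -> list[AlignedSegment]:
    """Split-align one read against an indexed genome.

    Reports plus- and minus-strand local segments with score >= ``min_score``
    (match +1 / mismatch -4 over chained exact runs).  MAPQ is 60 for a
    uniquely placed read interval, 0 when an equally scoring alternative
    placement exists.
    """
    params = params or VerifyParams()
    n = len(read)
    raw: list[AlignedSegment] = []
    for strand, seq in (("+", read), ("-", revcomp(read))):
        for chrom, a, b, diag, score in _align_one_strand(seq, index, params):
            if score < params.min_score:
                continue
            if strand == "+":
                rs, re_ = a, b
            else:
                rs, re_ = n - b, n - a
            raw.append(
                AlignedSegment(
                    read_start=rs,
                    read_end=re_,
                    chrom=chrom,
                    ref_start=diag + a + 1,
                    ref_end=diag + b,
                    strand=strand,
                    score=score,
                )
            )
    segments = _dedupe_contained(raw)
    _assign_mapq(segments)
    segments.sort(key=lambda s: (s.read_start, s.read_end))
    return segments


def _dedupe_contained(segments: list[AlignedSegment]) -> list[AlignedSegment]:
    """Remove exact duplicates and segments contained in an equal-or-better
    segment at the *same* genomic placement."""
    seen: set[tuple] = set()
    uniq: list[AlignedSegment] = []
    for s in sorted(segments, key=lambda x: (-x.read_len, -x.score)):
        key = (s.chrom, s.ref_start, s.ref_end, s.read_start, s.read_end, s.strand)
        if key in seen:
            continue
        contained = False
        for k in uniq:
            if (
                k.chrom == s.chrom
                and k.strand == s.strand
                and k.read_start <= s.read_start
                and s.read_end <= k.read_end
                and k.ref_start <= s.ref_start
                and s.ref_end <= k.ref_end
            ):
                contained = True
                break
        if not contained:
            seen.add(key)
            uniq.append(s)
    return uniq


def _assign_mapq(segments: list[AlignedSegment]) -> None:
    """MAPQ 0 for read intervals with an equally good alternative placement."""
    for i, s in enumerate(segments):
        ambiguous = False
        for j, t in enumerate(segments):
            if i == j:
                continue
            inter = min(s.read_end, t.read_end) - max(s.read_start, t.read_start)
            if inter >= 0.9 * s.read_len and t.score >= s.score:
                ambiguous = True
                break
        s.mapq = 0 if ambiguous else 60


def map_candidates(
    reads: dict[str, str],
    genome: dict[str, str],
    mode: str = "internal",
    sam: str | None = None,
    params: VerifyParams | None = None,
    index: GenomeIndex | None = None,
) -> dict[str, "SplitAlignment"]:
    """Split-align candidate reads to the genome.

    mode "internal": built-in seed-and-extend aligner (small references).
    mode "external": parse split/supplementary records from a SAM file
    produced by a local aligner run with minimum output score ``min_score``.
    Reads absent from the result are unaligned.
    """
    params = params or VerifyParams()
    out: dict[str, SplitAlignment] = {}
    if mode == "external":
        if sam is None:
            raise ValueError("external mode requires a SAM path")
        for read_id, segs in parse_sam_segments(sam, params).items():
            if read_id in reads and segs:
                out[read_id] = SplitAlignment(read_id=read_id, segments=segs)
                out[read_id].sort()
        return out
    if mode != "internal":
        raise ValueError(f"unknown mode: {mode}")
    if index is None:
        index = GenomeIndex(genome, k=params.seed_k)
    for read_id, seq in reads.items():
        segs = align_read_internal(seq, index, params)
        if segs:
            out[read_id] = SplitAlignment(read_id=read_id, segments=segs)
    return out


def parse_sam_segments(
    sam_path: str, params: VerifyParams | None = None
) -> dict[str, list[AlignedSegment]]:
    """Collect per-read alignment segments from a SAM file.

    Primary and supplementary records are used (secondary records skipped);
    soft and hard clips are honoured so read coordinates always refer to the
    original, forward-orientation read.  A record whose CIGAR jumps the
    reference by ``min_intron_gap`` or more (a long deletion, or an N skip)
    is split into separate segments at each jump -- a DNA local aligner
    represents a short intron that way instead of emitting a chimeric pair.
    """
    import pysam

    params = params or VerifyParams()
    min_intron_gap = 10
    out: dict[str, list[AlignedSegment]] = {}
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            cig = rec.cigartuples or []
            qlen = rec.infer_read_length() or rec.query_length or 0
            mapq = rec.mapping_quality
            # walk the CIGAR, splitting blocks at long reference jumps;
            # hard clips advance the query cursor so coordinates refer to
            # the full original read
            blocks: list[tuple[int, int, int, int]] = []  # (qs, qe, rs, re)
            q = 0
            r = rec.reference_start
            cur = None  # open block
            for op, ln in cig:
                if op in (0, 7, 8):  # M/=/X
                    if cur is None:
                        cur = [q, q + ln, r, r + ln]
                    else:
                        cur[1] = q + ln
                        cur[3] = r + ln
                    q += ln
                    r += ln
                elif op == 1:  # I
                    q += ln
                elif op in (2, 3):  # D / N
                    if (op == 3 or ln >= min_intron_gap) and cur is not None:
                        blocks.append(tuple(cur))
                        cur = None
                    r += ln
                elif op == 4:  # S
                    q += ln
                elif op == 5:  # H
                    q += ln
            if cur is not None:
                blocks.append(tuple(cur))
            for qs, qe, rs, re_ in blocks:
                if qe - qs < params.min_score:
                    continue
                if rec.is_reverse:
                    read_start, read_end = qlen - qe, qlen - qs
                else:
                    read_start, read_end = qs, qe
                out.setdefault(rec.query_name, []).append(
                    AlignedSegment(
                        read_start=read_start,
                        read_end=read_end,
                        chrom=rec.reference_name,
                        ref_start=rs + 1,
                        ref_end=re_,
                        strand="-" if rec.is_reverse else "+",
                        score=float(qe - qs),
                        mapq=mapq,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Verification stages
# ---------------------------------------------------------------------------


def select_anchor(
    sa: SplitAlignment, params: VerifyParams | None = None
) -> AlignedSegment | None:
    """Longest read-interval segment with mapq strictly above the threshold.

    Ties go to the leftmost genomic coordinate.  Returns None (read
    discarded) when no segment qualifies.
    """
    params = params or VerifyParams()
    best = None
    for i, seg in enumerate(sa.segments):
        if seg.mapq <= params.min_anchor_mapq:
            continue
        key = (-seg.read_len, seg.chrom, seg.ref_start)
        if best is None or key < best[0]:
            best = (key, i)
    if best is None:
        sa.anchor_index = None
        return None
    sa.anchor_index = best[1]
    return sa.segments[best[1]]


def window_filter(
    sa: SplitAlignment,
    anchor: AlignedSegment,
    params: VerifyParams,
    read_len: int,
) -> bool:
    """Keep the read iff mapped length near the anchor exceeds half its length.

    Sums the read-interval lengths of segments whose genomic span lies within
    ``anchor +/- window`` on the anchor's chromosome.
    """
    lo = anchor.ref_start - params.window
    hi = anchor.ref_end + params.window
    total = sum(
        seg.read_len
        for seg in sa.segments
        if seg.chrom == anchor.chrom and seg.ref_start >= lo and seg.ref_end <= hi
    )
    return total > read_len / 2


def orient_to_anchor(read: str, sa: SplitAlignment) -> tuple[str, SplitAlignment]:
    """Reverse-complement the read when its anchor maps to the minus strand.

    Segment read coordinates and strands are flipped accordingly so that all
    downstream junction logic can assume plus-strand alignments.
    """
    anchor = sa.anchor
    if anchor is None or anchor.strand == "+":
        return read, sa
    n = len(read)
    flipped = [
        replace(
            s,
            read_start=n - s.read_end,
            read_end=n - s.read_start,
            strand="+" if s.strand == "-" else "-",
        )
        for s in sa.segments
    ]
    new = SplitAlignment(read_id=sa.read_id, segments=flipped)
    new.anchor_index = sa.anchor_index
    new.sort()
    return revcomp(read), new


_dp_aligner = Align.PairwiseAligner()
_dp_aligner.mode = "local"
_dp_aligner.match_score = 1
_dp_aligner.mismatch_score = -4
_dp_aligner.open_gap_score = -7  # gap open -6 plus first extension -1
_dp_aligner.extend_gap_score = -1


def dp_place_fragment(
    fragment: str, target: str
) -> tuple[int, int, int, int, float] | None:
    """Best local (Smith-Waterman, affine-gap) placement of a fragment.

    Returns (frag_start, frag_end, target_start, target_end, score) with
    0-based half-open coordinates on both sequences, or None when nothing
    aligns.
    """
    if not fragment or not target:
        return None
    try:
        alignments = _dp_aligner.align(target, fragment)
        best = alignments[0]
    except (IndexError, ValueError, OverflowError):
        return None
    tblocks, qblocks = best.aligned
    if len(tblocks) == 0:
        return None
    return (
        int(qblocks[0][0]),
        int(qblocks[-1][1]),
        int(tblocks[0][0]),
        int(tblocks[-1][1]),
        float(best.score),
    )


def local_realign(
    read: str,
    sa: SplitAlignment,
    genome: dict[str, str],
    params: VerifyParams | None = None,
) -> SplitAlignment | None:
    """Fix reliable fragments and realign the rest by dynamic programming.

    Abnormal segments (strand-discordant with the anchor, ambiguous mapq off
    the anchor, off-chromosome, outside the window, or read-overlapping a
    better segment by more than ``flank_check``) are removed; uncovered read
    intervals are then placed by local DP against the genomic window around
    the anchor.  An internal fragment that cannot be placed with score >=
    ``min_score`` discards the read; an unplaceable terminal fragment shorter
    than ``min_score`` is left soft-clipped.
    """
    params = params or VerifyParams()
    anchor = sa.anchor
    if anchor is None:
        return None
    if anchor.strand != "+":
        raise ValueError("orient_to_anchor must run before local_realign")
    chrom_seq = genome[anchor.chrom]
    lo = max(0, anchor.ref_start - 1 - params.window)
    hi = min(len(chrom_seq), anchor.ref_end + params.window)

    def in_window(seg: AlignedSegment) -> bool:
        return (
            seg.chrom == anchor.chrom
            and seg.strand == "+"
            and seg.ref_start - 1 >= lo
            and seg.ref_end <= hi
        )

    candidates = [s for s in sa.segments if in_window(s) and (s.mapq > 0 or s is anchor)]
    # greedy keep by score, limiting read-coordinate overlap
    candidates.sort(key=lambda s: (s is not anchor, -s.score, s.read_start))
    kept: list[AlignedSegment] = []
    for seg in candidates:
        if all(
            min(seg.read_end, k.read_end) - max(seg.read_start, k.read_start)
            <= params.flank_check
            for k in kept
        ):
            kept.append(seg)
    kept.sort(key=lambda s: s.read_start)

    # uncovered read intervals
    gaps: list[tuple[int, int, bool]] = []  # (start, end, terminal)
    cursor = 0
    for seg in kept:
        if seg.read_start - cursor > 0:
            gaps.append((cursor, seg.read_start, cursor == 0))
        cursor = max(cursor, seg.read_end)
    if cursor < len(read):
        gaps.append((cursor, len(read), True))

    target = chrom_seq[lo:hi]
    for g0, g1, terminal in gaps:
        if g1 - g0 <= params.flank_check:
            continue  # small gap: junction adjustment will compensate
        placed = dp_place_fragment(read[g0:g1], target)
        if placed is not None and placed[4] >= params.min_score:
            f0, f1, t0, t1, score = placed
            kept.append(
                AlignedSegment(
                    read_start=g0 + f0,
                    read_end=g0 + f1,
                    chrom=anchor.chrom,
                    ref_start=lo + t0 + 1,
                    ref_end=lo + t1,
                    strand="+",
                    score=score,
                    mapq=60,
                )
            )
        elif terminal and (g1 - g0) < params.min_score:
            continue  # soft-clip a short unplaceable end
        else:
            return None  # fragment unplaceable: read discarded
    kept.sort(key=lambda s: s.read_start)
    out = SplitAlignment(read_id=sa.read_id, segments=kept)
    select_anchor(out, params)
    if out.anchor_index is None and kept:
        out.anchor_index = max(range(len(kept)), key=lambda i: kept[i].read_len)
    return out


def _is_backsplice(left: AlignedSegment, right: AlignedSegment) -> bool:
    """Adjacent segments in back-spliced (genomically inverted) order."""
    return left.chrom == right.chrom and right.ref_start <= left.ref_end


def has_bsj(sa: SplitAlignment) -> bool:
    segs = sorted(sa.segments, key=lambda s: s.read_start)
    return any(_is_backsplice(a, b) for a, b in zip(segs, segs[1:]))


def adjust_gt_ag(
    read: str,
    sa: SplitAlignment,
    genome: dict[str, str],
    params: VerifyParams | None = None,
) -> SplitAlignment | None:
    """Shift junction boundaries onto GT/AG splice signals; verify flanks.

    For every junction between adjacent segments the junction read position
    may shift by up to ``boundary_search`` bases (absorbing any unaligned
    bases between the segments); a shift is feasible only where the
    re-assigned read bases match the genome exactly.  The junction must read
    GT..AG on the intron/backsplice side, otherwise the read is discarded.
    Finally the ``flank_check`` read bases on both sides of every junction
    must align without gap or mismatch.
    """
    params = params or VerifyParams()
    segs = [replace(s) for s in sorted(sa.segments, key=lambda s: s.read_start)]
    if any(s.strand != "+" for s in segs):
        return None
    for i in range(len(segs) - 1):
        left, right = segs[i], segs[i + 1]
        if left.chrom != right.chrom:
            return None
        gseq = genome[left.chrom]
        r1l, g1l = left.read_end, left.ref_end  # left end (read 0-excl, ref 1-incl)
        r0r, g0r = right.read_start, right.ref_start
        lo_p = max(left.read_start + 1, min(r1l, r0r) - params.boundary_search)
        hi_p = min(right.read_end - 1, max(r1l, r0r) + params.boundary_search)
        chosen = None
        for p in sorted(range(lo_p, hi_p + 1), key=lambda x: (abs(x - r1l), x)):
            # left boundary at read position p -> donor end D
            ext_l = p - r1l
            D = g1l + ext_l
            if ext_l > 0:
                if D > len(gseq) or read[r1l:p] != gseq[g1l : g1l + ext_l]:
                    continue
            ext_r = r0r - p
            A = g0r - ext_r
            if ext_r > 0:
                if A < 1 or read[p:r0r] != gseq[A - 1 : g0r - 1]:
                    continue
            if D < 1 or A < 1 or D + 2 > len(gseq) or A - 3 < 0:
                continue
            if gseq[D : D + 2] == "GT" and gseq[A - 3 : A - 1] == "AG":
                chosen = (p, D, A)
                break
        if chosen is None:
            return None
        p, D, A = chosen
        left.read_end, left.ref_end = p, D
        right.read_start, right.ref_start = p, A
        if left.read_end <= left.read_start or right.read_end <= right.read_start:
            return None
    # flank verification
    f = params.flank_check
    for i in range(len(segs) - 1):
        left, right = segs[i], segs[i + 1]
        gseq = genome[left.chrom]
        p, D, A = left.read_end, left.ref_end, right.ref_start
        if p - f < left.read_start or p + f > right.read_end:
            return None
        if read[p - f : p] != gseq[D - f : D]:
            return None
        if read[p : p + f] != gseq[A - 1 : A - 1 + f]:
            return None
    out = SplitAlignment(read_id=sa.read_id, segments=segs)
    select_anchor(out, params)
    return out


def filter_linear(
    read: str,
    sa: SplitAlignment,
    ro5_len: int,
    genome: dict[str, str],
    params: VerifyParams | None = None,
) -> bool:
    """Linear-transcript filter: True = keep, False = drop.

    A read is dropped when it contains no back-splice junction AND the
    terminal subsequences of length ``ro5_len`` have no placement inside the
    anchor window.  Partial adapters attached to a short linear fragment
    mimic a 5' RO; their bases are not genomic, so the merged read's ends
    find no home near the anchor.  The ends of a genuine circular read are
    either part of its own split alignment or re-place exactly (tandem
    repeats), so both criteria fail and the read is kept.
    """
    params = params or VerifyParams()
    if has_bsj(sa):
        return True
    anchor = sa.anchor
    if anchor is None:
        return False
    u = ro5_len
    if u <= 0 or u > len(read):
        return False
    chrom_seq = genome[anchor.chrom]
    lo = max(0, anchor.ref_start - 1 - params.window)
    hi = min(len(chrom_seq), anchor.ref_end + params.window)
    target = chrom_seq[lo:hi]

    def end_has_hit(e0: int, e1: int) -> bool:
        # covered by the read's own alignment near the anchor?
        covered = 0
        for seg in sa.segments:
            if seg.chrom != anchor.chrom:
                continue
            covered += max(0, min(e1, seg.read_end) - max(e0, seg.read_start))
        if covered >= 0.8 * (e1 - e0):
            return True
        if target.find(read[e0:e1]) >= 0:
            return True
        # partial local placement (a circular read's end may straddle the
        # back-splice point, mapping only piecewise); adapter bases never
        # reach half-length identity against the window
        placed = dp_place_fragment(read[e0:e1], target)
        return placed is not None and placed[4] >= 0.5 * (e1 - e0)

    return end_has_hit(0, u) and end_has_hit(len(read) - u, len(read))


def classify_full_length(
    sa: SplitAlignment,
    cirexons: list[tuple[int, int]] | None = None,
) -> str:
    """Classify a verified RO-merged read.

    "full_length_3ro" when two distinct terminal segments' genomic intervals
    overlap (the walk covered the whole circle); "full_length_same_cirexon"
    when the read crosses a BSJ and its disjoint ends fall inside one known
    cirexon (the short uncovered interior is then implied); otherwise
    "reserve" for combined assembly.
    """
    segs = sorted(sa.segments, key=lambda s: s.read_start)
    first, last = segs[0], segs[-1]
    if len(segs) >= 2 and first.chrom == last.chrom:
        inter = min(first.ref_end, last.ref_end) - max(first.ref_start, last.ref_start)
        if inter >= 0:
            return "full_length_3ro"
        if cirexons and has_bsj(sa):
            for s, e in cirexons:
                if (
                    s <= first.ref_start
                    and first.ref_end <= e
                    and s <= last.ref_start
                    and last.ref_end <= e
                ):
                    return "full_length_same_cirexon"
    return "reserve"


def extract_bsj(sa: SplitAlignment) -> tuple[str, int, int] | None:
    """The back-splice junction implied by a split alignment.

    Returns (chrom, acceptor_start, donor_end) -- the circle's outer
    boundaries -- or None when the read is colinear.
    """
    segs = sorted(sa.segments, key=lambda s: s.read_start)
    for left, right in zip(segs, segs[1:]):
        if _is_backsplice(left, right):
            return left.chrom, right.ref_start, left.ref_end
    return None


def verify_merged_read(
    read: str,
    sa: SplitAlignment,
    ro5_len: int,
    genome: dict[str, str],
    params: VerifyParams | None = None,
    cirexons: list[tuple[int, int]] | None = None,
) -> tuple[str, str | None, SplitAlignment | None, str]:
    """Run the whole verification cascade on one candidate RO-merged read.

    Returns (status, reason, final_alignment, oriented_read) where status is
    one of "full_length_3ro", "full_length_same_cirexon", "reserve", or
    "dropped" (reason then names the failing stage).
    """
    params = params or VerifyParams()
    anchor = select_anchor(sa, params)
    if anchor is None:
        return "dropped", "no_anchor", None, read
    read, sa = orient_to_anchor(read, sa)
    anchor = sa.anchor
    if not window_filter(sa, anchor, params, len(read)):
        return "dropped", "window", None, read
    realigned = local_realign(read, sa, genome, params)
    if realigned is None:
        return "dropped", "unplaceable", None, read
    if not filter_linear(read, realigned, ro5_len, genome, params):
        return "dropped", "linear", None, read
    adjusted = adjust_gt_ag(read, realigned, genome, params)
    if adjusted is None:
        return "dropped", "noncanonical", None, read
    status = classify_full_length(adjusted, cirexons)
    return status, None, adjusted, read
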