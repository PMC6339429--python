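"""Full-length circRNA reconstruction from RO and BSJ evidence.

Per BSJ, three routes can produce a full-length sequence: (i) a verified
RO-merged read whose ends overlap on the genome (3' RO) or sit on the same
cirexon covers the circle on its own; (ii) when every BSJ read pair falls
exclusively on the known cirexons, the circle is the cirexons linearly
connected; (iii) otherwise the two evidence streams are combined -- RO reads
contribute cirexons the BSJ reads missed -- and the exclusivity check is
re-run.  CircRNAs that still fail are reported as partially reconstructed
with whatever cirexons are known.  A reconstructed chain whose internal
junctions are not all directly read-supported is "nearly complete".
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rocirc.align import SplitAlignment
from rocirc.bsj import BSJ, Cirexon, FSJ


@dataclass
class FullLengthCircRNA:
    bsj_id: str
    chrom: str
    cirexons: list[tuple[int, int]]
    sequence: str
    status: str  # complete | nearly_complete | partial
    evidence: str  # RO | BSJ | combined
    n_bsj_reads: int = 0
    n_ro_reads: int = 0
    chains: list[tuple[tuple[int, int], ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status in ("complete", "nearly_complete"):
            expected = sum(e - s + 1 for s, e in self.cirexons)
            if len(self.sequence) != expected:
                raise ValueError("sequence length must equal summed cirexon lengths")


# Ragged read ends can extend past a true splice boundary by chance base
# matches (microhomology); overhangs up to this many bases at a read's
# outermost ends are treated as alignment noise, never as evidence.
_SOFT_END_SLOP = 10


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of genomic intervals; merges overlapping (not merely adjacent)."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def chain_sequence(
    genome: dict[str, str], chrom: str, chain: list[tuple[int, int]]
) -> str:
    """Concatenate exon sequences in genomic order (circle linearised at the
    BSJ acceptor, plus strand)."""
    return "".join(genome[chrom][s - 1 : e] for s, e in chain)


def chain_from_ro_read(
    sa: SplitAlignment,
    status: str,
    cirexons: list[Cirexon] | None = None,
) -> tuple[tuple[int, int], ...] | None:
    """Cirexon chain covered by one full-length RO-merged read.

    The read is a contiguous walk around the circle, so the union of its
    segment intervals tiles the circle; rolling-circle duplicates collapse in
    the union.  Interior segment boundaries are splice-junction-defined
    ("hard"); the read's two outermost ends are ragged ("soft") and may
    overrun a true boundary by a few chance-matching bases, so soft merged
    boundaries snap to a nearby hard one.  For the same-cirexon case the
    uncovered interior of that cirexon is filled from the known cirexon
    interval.
    """
    segs = sorted(sa.segments, key=lambda s: s.read_start)
    ivs = [(s.ref_start, s.ref_end) for s in segs]
    hard_starts = {s.ref_start for s in segs[1:]}
    hard_ends = {s.ref_end for s in segs[:-1]}
    if status == "full_length_same_cirexon":
        if not cirexons:
            return None
        first, last = ivs[0], ivs[-1]
        home = None
        for ce in cirexons:
            if getattr(ce, "provisional", False):
                continue  # not splice-certified: cannot vouch for a fill
            if (
                ce.start <= first[0] + _SOFT_END_SLOP
                and first[1] <= ce.end + _SOFT_END_SLOP
                and ce.start <= last[0] + _SOFT_END_SLOP
                and last[1] <= ce.end + _SOFT_END_SLOP
            ):
                home = ce
                break
        if home is None:
            return None
        ivs.append((home.start, home.end))
        hard_starts.add(home.start)
        hard_ends.add(home.end)
    elif status != "full_length_3ro":
        return None
    merged = _merge_intervals(ivs)
    snapped = []
    for s, e in merged:
        if s not in hard_starts:
            near = [h for h in hard_starts if s < h <= s + _SOFT_END_SLOP]
            if near:
                s = min(near)
        if e not in hard_ends:
            near = [h for h in hard_ends if e - _SOFT_END_SLOP <= h < e]
            if near:
                e = max(near)
        if e >= s:
            snapped.append((s, e))
    return tuple(snapped)


def assemble_from_ro(
    bsj: BSJ,
    ro_reads: list[tuple[str, str, SplitAlignment]],  # (read_id, status, sa)
    cirexons: list[Cirexon],
    genome: dict[str, str],
) -> tuple[dict[tuple[tuple[int, int], ...], set[str]], list[str]]:
    """Assemble full-length chains from verified RO-merged reads.

    Returns (distinct chains with supporting read ids, reserved read ids).
    Conflicting chains from different reads are all kept as distinct isoform
    evidence.
    """
    chains: dict[tuple[tuple[int, int], ...], set[str]] = {}
    reserved: list[str] = []
    for read_id, status, sa in ro_reads:
        chain = chain_from_ro_read(sa, status, cirexons)
        if chain is None:
            reserved.append(read_id)
            continue
        chains.setdefault(chain, set()).add(read_id)
    return chains, reserved


def _segments_on_cirexons(
    alignments: list[SplitAlignment],
    chrom: str,
    cirexons: list[tuple[int, int]],
) -> bool:
    """True iff every segment lies within some cirexon.

    A read's outermost ends are not junction-defined and may overrun a true
    boundary by a few chance-matching bases, so terminal segments get
    ``_SOFT_END_SLOP`` bases of grace at their ragged end; interior segments
    must be contained exactly.
    """
    for sa in alignments:
        segs = sorted(sa.segments, key=lambda s: s.read_start)
        for i, seg in enumerate(segs):
            if seg.chrom != chrom:
                return False
            lo = seg.ref_start + (_SOFT_END_SLOP if i == 0 else 0)
            hi = seg.ref_end - (_SOFT_END_SLOP if i == len(segs) - 1 else 0)
            if hi < lo:
                continue  # a tiny terminal sliver carries no information
            if not any(s <= lo and hi <= e for s, e in cirexons):
                return False
    return True


def assemble_from_bsj(
    bsj: BSJ,
    cirexons: list[Cirexon],
    bsj_read_alignments: list[SplitAlignment],
    genome: dict[str, str],
) -> FullLengthCircRNA | None:
    """Reconstruct the circle by linearly connecting cirexons.

    Succeeds only when every BSJ read pair's segments fall exclusively on
    supported cirexons; otherwise returns None (reserved for combination).
    """
    if not cirexons or not bsj_read_alignments:
        return None
    if any(ce.provisional or ce.support_bsj + ce.support_ro == 0 for ce in cirexons):
        return None  # provisional/unsupported cirexon: not trustworthy
    ivs = [ce.interval for ce in cirexons]
    if not _segments_on_cirexons(bsj_read_alignments, bsj.chrom, ivs):
        return None
    chain = sorted(ivs)
    return FullLengthCircRNA(
        bsj_id=bsj.id,
        chrom=bsj.chrom,
        cirexons=chain,
        sequence=chain_sequence(genome, bsj.chrom, chain),
        status="complete",
        evidence="BSJ",
        n_bsj_reads=len(bsj.read_ids),
    )


def _audit_junction_support(
    chain: list[tuple[int, int]],
    fsjs: list[FSJ],
    ro_chains: dict[tuple[tuple[int, int], ...], set[str]],
) -> bool:
    """True when every internal junction of the chain has direct read support."""
    supported = {(f.donor, f.acceptor) for f in fsjs if f.support > 0}
    for chain_ro in ro_chains:
        for (s1, e1), (s2, e2) in zip(chain_ro, chain_ro[1:]):
            supported.add((e1, s2))
    for (s1, e1), (s2, e2) in zip(chain, chain[1:]):
        if (e1, s2) not in supported:
            return False
    return True


def combine(
    bsj: BSJ,
    cirexons: list[Cirexon],
    ro_cirexons: list[tuple[int, int]],
    bsj_read_alignments: list[SplitAlignment],
    fsjs: list[FSJ],
    ro_chains: dict[tuple[tuple[int, int], ...], set[str]],
    genome: dict[str, str],
    n_ro_reads: int = 0,
) -> FullLengthCircRNA:
    """Combined assembly: RO-derived cirexons complement BSJ evidence.

    The cirexon set becomes the union of both streams (boundaries already
    GT/AG-adjusted, so identical cirexons unify exactly); the exclusivity
    check is re-run.  Success gives a complete (evidence=combined) circRNA,
    downgraded to nearly_complete when an internal junction lacks direct
    read support; failure yields a partial reconstruction carrying the known
    cirexons.
    """
    known = {
        ce.interval
        for ce in cirexons
        if not ce.provisional and ce.support_bsj + ce.support_ro > 0
    }
    known.update(ro_cirexons)
    for chain in ro_chains:
        known.update(chain)
    chain = sorted(known)
    exclusive = bool(chain) and _segments_on_cirexons(
        bsj_read_alignments, bsj.chrom, chain
    )
    if exclusive:
        status = (
            "complete"
            if _audit_junction_support(chain, fsjs, ro_chains)
            else "nearly_complete"
        )
        seq = chain_sequence(genome, bsj.chrom, chain)
    else:
        status = "partial"
        seq = ""
    return FullLengthCircRNA(
        bsj_id=bsj.id,
        chrom=bsj.chrom,
        cirexons=chain,
        sequence=seq,
        status=status,
        evidence="combined",
        n_bsj_reads=len(bsj.read_ids),
        n_ro_reads=n_ro_reads,
    )


def assemble_bsj_locus(
    bsj: BSJ,
    cirexons: list[Cirexon],
    fsjs: list[FSJ],
    ro_reads: list[tuple[str, str, SplitAlignment]],
    bsj_read_alignments: list[SplitAlignment],
    genome: dict[str, str],
) -> FullLengthCircRNA:
    """Run the full assembly cascade for one BSJ (RO -> BSJ -> combined).

    Every BSJ yields exactly one record; the distinct full-length chains
    observed on RO reads are attached for isoform-level analysis.
    """
    if not ro_reads:
        pure = assemble_from_bsj(bsj, cirexons, bsj_read_alignments, genome)
        if pure is not None:
            if not _audit_junction_support(pure.cirexons, fsjs, {}):
                pure.status = "nearly_complete"
            return pure
    ro_chains, _reserved = assemble_from_ro(bsj, ro_reads, cirexons, genome)
    ro_internal: list[tuple[int, int]] = []
    for _rid, _status, sa in ro_reads:
        segs = sorted(sa.segments, key=lambda s: s.read_start)
        for seg in segs[1:-1]:  # internal segments have both boundaries spliced
            if seg.chrom == bsj.chrom:
                ro_internal.append((seg.ref_start, seg.ref_end))
    result = combine(
        bsj,
        cirexons,
        ro_internal,
        bsj_read_alignments,
        fsjs,
        ro_chains,
        genome,
        n_ro_reads=len(ro_reads),
    )
    if ro_chains:
        # a full-length RO read is definitive on its own
        union = sorted({iv for chain in ro_chains for iv in chain})
        if result.status == "partial":
            result = FullLengthCircRNA(
                bsj_id=bsj.id,
                chrom=bsj.chrom,
                cirexons=union,
                sequence=chain_sequence(genome, bsj.chrom, union),
                status="complete",
                evidence="RO",
                n_bsj_reads=len(bsj.read_ids),
                n_ro_reads=len(ro_reads),
            )
        elif result.evidence == "combined" and not bsj_read_alignments:
            result.evidence = "RO"
    result.chains = sorted(ro_chains)
    return result
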