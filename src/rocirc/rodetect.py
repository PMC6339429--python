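"""Detection of 5' reverse-overlap (RO) read pairs and merging into long reads.

A read pair drawn from a rolling-circle fragment whose length exceeds the
circle length shows a reverse-complementary overlap between the two mates'
5' ends: ``read1[:v] == revcomp(read2[:v])`` for overlap length v.  Detection
seeds short windows from read1's 5' end against the reverse complement of
read2, demands a single consistent overlap offset supported by every seed,
then verifies the full overlap for length and identity before merging the
pair into one long read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from rocirc.io import revcomp

_N_BYTE = ord("N")


@dataclass
class ROParams:
    """Seed-and-verify thresholds for 5' RO detection.

    The first ``seed_region`` bases of read1 are cut into windows of
    ``seed_window`` bases every ``seed_step`` bases; each window must match
    with at least ``seed_min_match`` identical bases.  The implied overlap is
    accepted when it is at least ``min_overlap`` bases long with per-base
    identity at least ``min_identity`` (gapless comparison; N counts as a
    mismatch).
    """

    seed_region: int = 10
    seed_window: int = 8
    seed_step: int = 1
    seed_min_match: int = 7
    min_overlap: int = 13
    min_identity: float = 0.95

    def __post_init__(self) -> None:
        if self.seed_window > self.seed_region:
            raise ValueError("seed_window must not exceed seed_region")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    seq2: str
    qual1: str | None = None
    qual2: str | None = None

    def __post_init__(self) -> None:
        if not self.seq1 or not self.seq2:
            raise ValueError("read sequences must be non-empty")


@dataclass
class ROMergedRead:
    """A merged long read built from a verified 5' reverse overlap."""

    read_id: str
    sequence: str
    ro5_len: int
    source_pair: str
    identity: float = 1.0
    has_3ro: bool | None = None  # set by alignment verification


def extract_seeds(seq: str, params: ROParams) -> list[str]:
    """Sliding windows over the read's 5' seed region.

    Returns ``floor((seed_region - seed_window) / seed_step) + 1`` windows, or
    an empty list when the read is shorter than the seed region (the pair is
    then skipped).
    """
    if len(seq) < params.seed_region:
        return []
    n = (params.seed_region - params.seed_window) // params.seed_step + 1
    return [
        seq[i * params.seed_step : i * params.seed_step + params.seed_window]
        for i in range(n)
    ]


def _hamming_matches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x == y and x != "N")


def find_5p_ro(
    pair: ReadPair, params: ROParams | None = None
) -> tuple[int, float] | None:
    """Locate a 5' reverse overlap between the mates of a pair.

    Seeds from read1's 5' end are matched against the reverse complement of
    read2 at every candidate offset; an offset is viable when all seeds reach
    ``seed_min_match`` identical bases.  The smallest viable offset (largest
    overlap) is verified over the whole overlap region.  Returns
    ``(ro5_len, identity)`` or None.
    """
    params = params or ROParams()
    if len(pair.seq1) < params.seed_region or len(pair.seq2) < params.seed_region:
        return None
    rc2 = revcomp(pair.seq2)
    a1 = np.frombuffer(pair.seq1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(rc2.encode(), dtype=np.uint8)
    w, step = params.seed_window, params.seed_step
    n_seeds = (params.seed_region - w) // step + 1
    n2 = len(a2)
    if n2 < w:
        return None
    windows = np.lib.stride_tricks.sliding_window_view(a2, w)
    # candidate offsets o (seed j must sit at rc2 position o + j*step)
    m = (n2 - w + 1) - (n_seeds - 1) * step
    if m <= 0:
        return None
    viable = np.ones(m, dtype=bool)
    for j in range(n_seeds):
        seed = a1[j * step : j * step + w]
        score = ((windows == seed) & (seed != _N_BYTE)).sum(axis=1)
        viable &= (score >= params.seed_min_match)[j * step : j * step + m]
    for o in np.nonzero(viable)[0]:
        v = n2 - int(o)
        aligned = min(v, len(a1))
        if aligned < params.min_overlap:
            return None  # offsets ascend, overlaps only shrink
        seg1 = a1[:aligned]
        seg2 = a2[o : o + aligned]
        matches = int(((seg1 == seg2) & (seg1 != _N_BYTE)).sum())
        identity = matches / aligned
        if identity >= params.min_identity:
            return aligned, identity
        return None  # the single consistent (smallest) offset failed
    return None


def merge_pair(
    pair: ReadPair, ro5_len: int, params: ROParams | None = None
) -> ROMergedRead:
    """Merge a verified RO pair into one long read.

    The merged read is ``revcomp(read2)`` overlapped with read1 on the
    ``ro5_len`` 5' bases; disagreeing overlap bases are resolved toward the
    higher base quality (ties toward read1).  Length contract:
    ``len(merged) == len(seq1) + len(seq2) - ro5_len``.
    """
    rc2 = revcomp(pair.seq2)
    o = len(rc2) - ro5_len
    prefix = rc2[:o]
    overlap1 = pair.seq1[:ro5_len]
    overlap2 = rc2[o:]
    if overlap1 == overlap2:
        overlap = overlap1
    else:
        q1 = pair.qual1[:ro5_len] if pair.qual1 else "I" * ro5_len
        q2 = (pair.qual2[::-1])[o:] if pair.qual2 else "I" * ro5_len
        overlap = "".join(
            b1 if (b1 == b2 or q1[i] >= q2[i]) else b2
            for i, (b1, b2) in enumerate(zip(overlap1, overlap2))
        )
    merged = prefix + overlap + pair.seq1[ro5_len:]
    assert len(merged) == len(pair.seq1) + len(pair.seq2) - ro5_len
    return ROMergedRead(
        read_id=pair.read_id,
        sequence=merged,
        ro5_len=ro5_len,
        source_pair=pair.read_id,
    )


def detect_ro_pairs(
    pairs, params: ROParams | None = None
) -> tuple[list[ROMergedRead], list[str]]:
    """Scan an iterable of ReadPair; return merged candidates and non-RO ids."""
    params = params or ROParams()
    merged: list[ROMergedRead] = []
    rest: list[str] = []
    for pair in pairs:
        hit = find_5p_ro(pair, params)
        if hit is None:
            rest.append(pair.read_id)
            continue
        ro5, identity = hit
        rec = merge_pair(pair, ro5, params)
        rec.identity = identity
        merged.append(rec)
    return merged, rest
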