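"""Synthetic rolling-circle circRNA read simulator.

Generates paired-end RNA-seq reads from circular templates together with
ground-truth tables, emulating the rolling-circle reverse transcription that
creates reverse-overlap (RO) read pairs: a sequenced fragment is a contiguous
walk around the circle, so whenever the insert length exceeds the circle
length the two mates share a reverse-complementary 5' overlap, and when the
walk covers the circle entirely the merged read carries a 3' overlap as well.

Insert lengths follow a Normal(mu, sigma^2) realised through the Box-Muller
transform; per-transcript coverage follows the heavy-tailed law
``C = ((D - 0.5) * 3 + 1) / (1 - sqrt(x))`` with x uniform on (0,1), capped
(the uncapped law has infinite mean).  Circle lengths are Normal, truncated
from below.  Multi-isoform circRNAs share their back-splice junction and
differ by skipping internal cirexons.

Synthetic genomes place one locus per chromosome, with canonical GT/AG
dinucleotides implanted at every forward-splice and back-splice boundary so
the downstream junction-adjustment logic sees the same signals a spliced
genome provides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from rocirc.io import revcomp, write_fasta, write_fastq, write_tsv

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class InsertLengthError(RuntimeError):
    """Raised when insert-length resampling exceeds the retry limit."""


@dataclass
class SimConfig:
    """Study conditions for a simulated circRNA sequencing run.

    Defaults follow the benchmark design used throughout: 150 bp paired-end
    reads, insert length 350 +/- 200 bp, circle lengths Normal(300, 150)
    truncated at 100 bp, and the heavy-tailed per-transcript coverage law
    driven by ``depth_D``.
    """

    read_length: int = 150
    depth_D: float = 10.0
    error_rate: float = 0.0
    insert_mu: float = 350.0
    insert_sigma: float = 200.0
    n_circ: int = 50
    circ_len_mu: float = 300.0
    circ_len_sigma: float = 150.0
    n_isoforms_per_circ: int = 1
    coverage_cap: float = 500.0
    seed: int = 0
    # Structural choices for the synthetic loci (see docs/methods.md).
    min_circ_len: int = 100
    min_exon_len: int = 30
    target_exon_len: int = 120
    max_exons: int = 8
    intron_min: int = 100
    intron_max: int = 500
    flank: int = 500
    linear_fraction: float = 0.0
    # Optional fixed relative abundances shared by every circRNA; when set,
    # one coverage is drawn per circRNA and split by these ratios instead of
    # drawing an independent coverage per isoform.
    isoform_ratios: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.insert_mu <= 0 or self.insert_sigma < 0:
            raise ValueError("insert_mu must be > 0 and insert_sigma >= 0")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.coverage_cap <= 0:
            raise ValueError("coverage_cap must be positive")
        if self.isoform_ratios is not None:
            if len(self.isoform_ratios) != self.n_isoforms_per_circ:
                raise ValueError("isoform_ratios length must equal n_isoforms_per_circ")
            if abs(sum(self.isoform_ratios) - 1.0) > 1e-6:
                raise ValueError("isoform_ratios must sum to 1")


@dataclass
class CircTemplate:
    """One circular isoform: an ordered chain of genomic exon intervals."""

    circ_id: str
    chrom: str
    cirexons: list[tuple[int, int]]  # 1-based inclusive, genomic order
    sequence: str  # linearised at the BSJ acceptor (5'-most base)
    isoform_index: int
    true_abundance: float  # fold coverage

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class TruthRecord:
    read_id: str
    circ_id: str
    isoform_index: int
    fragment_start_on_circle: int  # 0-based offset
    insert_length: int


@dataclass
class SimResult:
    genome: dict[str, str]
    templates: list[CircTemplate]
    pairs: list[tuple[str, str, str]]  # (read_id, seq1, seq2)
    truth: list[TruthRecord]
    config: SimConfig = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Elementary draws
# ---------------------------------------------------------------------------

def draw_insert_length(
    mu: float,
    sigma: float,
    rng: np.random.Generator,
    min_len: int | None = None,
    max_retry: int = 1000,
) -> int:
    """Draw one insert length L = sqrt(-2 ln x1) * cos(2 pi x2) * sigma + mu.

    x1, x2 are independent uniforms on (0, 1) (Box-Muller).  With a
    ``min_len`` floor, draws are rejected until L > min_len -- a fragment
    shorter than one read is never sequenced as a proper pair -- with a hard
    retry limit.  Without a floor the untruncated normal is returned.
    """
    if mu <= 0 or sigma < 0:
        raise ValueError("require mu > 0 and sigma >= 0")
    for _ in range(max_retry):
        x1 = rng.random()
        x2 = rng.random()
        if x1 <= 0.0:  # open interval
            continue
        L = math.sqrt(-2.0 * math.log(x1)) * math.cos(2.0 * math.pi * x2) * sigma + mu
        Li = int(round(L))
        if min_len is None or Li > min_len:
            return Li
    raise InsertLengthError(
        f"no insert length > {min_len} after {max_retry} draws (mu={mu}, sigma={sigma})"
    )


def draw_coverage(
    depth_D: float, rng: np.random.Generator, cap: float = 500.0
) -> float:
    """Draw a per-transcript fold coverage.

    C = ((D - 0.5) * 3 + 1) * (1 - sqrt(x)), x uniform on (0, 1), capped at
    ``cap``.  With k = (D - 0.5) * 3 + 1 the law has mean k/3 = D - 1/6, so
    ``depth_D`` is the average per-transcript depth, while the density is
    monotone decreasing from zero coverage -- most circular transcripts are
    lowly expressed, mirroring real circRNA libraries.  The CDF is
    P(C <= c) = 1 - (1 - c/k)^2 for 0 <= c <= k.
    """
    if depth_D <= 0.5:
        raise ValueError("depth_D must exceed 0.5")
    k = (depth_D - 0.5) * 3.0 + 1.0
    x = rng.random()
    cov = k * (1.0 - math.sqrt(x))
    return min(cov, cap)


# ---------------------------------------------------------------------------
# Template construction
# ---------------------------------------------------------------------------

def _random_seq(n: int, rng: np.random.Generator) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)].copy()


def _partition_length(
    total: int, n_parts: int, min_part: int, rng: np.random.Generator
) -> list[int]:
    """Split ``total`` into n parts each >= min_part (random composition)."""
    slack = total - n_parts * min_part
    if slack < 0:
        raise ValueError("total too small for requested parts")
    if n_parts == 1:
        return [total]
    cuts = np.sort(rng.integers(0, slack + 1, size=n_parts - 1))
    pieces = np.diff(np.concatenate(([0], cuts, [slack])))
    return [int(p) + min_part for p in pieces]


def _skip_subsets(
    n_internal: int, n_needed: int, rng: np.random.Generator
) -> list[frozenset[int]]:
    """Pick ``n_needed`` distinct non-empty subsets of internal exon indices."""
    all_subsets = []
    for mask in range(1, 2**n_internal):
        all_subsets.append(frozenset(i for i in range(n_internal) if mask >> i & 1))
    if len(all_subsets) < n_needed:
        raise ValueError("not enough internal exons for requested isoforms")
    idx = rng.permutation(len(all_subsets))[:n_needed]
    return [all_subsets[i] for i in idx]


def make_templates(
    config: SimConfig,
    rng: np.random.Generator,
    genome: dict[str, str] | None = None,
    annotation: dict[str, list[tuple[str, int, int, str]]] | None = None,
) -> tuple[list[CircTemplate], dict[str, str]]:
    """Create circular templates and (when none is given) a synthetic genome.

    With no genome, each circRNA gets its own chromosome: random sequence,
    exons separated by introns, flanked both sides, with GT..AG implanted in
    every intron and AG / GT implanted immediately upstream / downstream of
    the circle boundaries so the back-splice junction is canonical too.

    With a genome plus a GTF-style ``annotation`` (transcript_id -> exon
    list), templates are cut from annotated exon chains instead; without
    annotation, exon intervals are drawn at random on the given genome (no
    splice signals are implanted in a user-supplied genome).
    """
    if genome is not None:
        return _templates_on_genome(config, rng, genome, annotation), genome

    genome = {}
    templates: list[CircTemplate] = []
    made = 0
    attempts = 0
    while made < config.n_circ:
        attempts += 1
        if attempts > 50 * config.n_circ:
            raise RuntimeError("template generation failed to converge")
        # circle (union-isoform) length: truncated normal
        L = int(round(rng.normal(config.circ_len_mu, config.circ_len_sigma)))
        if L < config.min_circ_len:
            continue
        n_iso = config.n_isoforms_per_circ
        min_internal = 0
        if n_iso > 1:
            min_internal = max(1, math.ceil(math.log2(n_iso)))  # 2^m >= n_iso-1+1
            while 2**min_internal - 1 < n_iso - 1:
                min_internal += 1
        n_min = min_internal + 2 if n_iso > 1 else 1
        n_exons = int(np.clip(round(L / config.target_exon_len), n_min, config.max_exons))
        if L < n_exons * config.min_exon_len:
            n_exons = max(n_min, L // config.min_exon_len)
            if L < n_exons * config.min_exon_len:
                continue  # circle too short for the structure; redraw
        exon_lens = _partition_length(L, n_exons, config.min_exon_len, rng)
        intron_lens = [
            int(rng.integers(config.intron_min, config.intron_max + 1))
            for _ in range(n_exons - 1)
        ]

        chrom = f"chr{made + 1}"
        chrom_len = 2 * config.flank + sum(exon_lens) + sum(intron_lens)
        seq = _random_seq(chrom_len, rng)
        pos = config.flank
        exons: list[tuple[int, int]] = []  # 1-based inclusive
        for i, el in enumerate(exon_lens):
            exons.append((pos + 1, pos + el))
            pos += el
            if i < n_exons - 1:
                il = intron_lens[i]
                seq[pos : pos + 2] = [b"G", b"T"]
                seq[pos + il - 2 : pos + il] = [b"A", b"G"]
                pos += il
        # back-splice signals: AG upstream of the acceptor, GT downstream of
        # the donor
        first_start0 = exons[0][0] - 1
        last_end0 = exons[-1][1]
        seq[first_start0 - 2 : first_start0] = [b"A", b"G"]
        seq[last_end0 : last_end0 + 2] = [b"G", b"T"]
        chrom_seq = seq.tobytes().decode()
        genome[chrom] = chrom_seq

        circ_id = f"{chrom}:{exons[0][0]}|{exons[-1][1]}"
        n_internal = n_exons - 2
        skips: list[frozenset[int]] = [frozenset()]
        if n_iso > 1:
            skips += _skip_subsets(n_internal, n_iso - 1, rng)
        if config.isoform_ratios is not None:
            total_cov = draw_coverage(config.depth_D, rng, config.coverage_cap)
            covs = [total_cov * r for r in config.isoform_ratios]
        else:
            covs = [
                draw_coverage(config.depth_D, rng, config.coverage_cap)
                for _ in range(n_iso)
            ]
        for iso, skip in enumerate(skips):
            chain = [
                ex
                for j, ex in enumerate(exons)
                if j == 0 or j == n_exons - 1 or (j - 1) not in skip
            ]
            circ_seq = "".join(chrom_seq[s - 1 : e] for s, e in chain)
            templates.append(
                CircTemplate(
                    circ_id=circ_id,
                    chrom=chrom,
                    cirexons=chain,
                    sequence=circ_seq,
                    isoform_index=iso,
                    true_abundance=covs[iso],
                )
            )
        made += 1
    return templates, genome


def _templates_on_genome(
    config: SimConfig,
    rng: np.random.Generator,
    genome: dict[str, str],
    annotation: dict[str, list[tuple[str, int, int, str]]] | None,
) -> list[CircTemplate]:
    """Cut templates from a user genome (annotated exons or random intervals)."""
    templates: list[CircTemplate] = []
    if annotation:
        tids = sorted(annotation)
        usable = [t for t in tids if len(annotation[t]) >= 1]
        if not usable:
            raise ValueError("annotation contains no exons")
        for i in range(config.n_circ):
            tid = usable[int(rng.integers(len(usable)))]
            exons = [
                (c, s, e)
                for (c, s, e, _strand) in annotation[tid]
                if c in genome and e <= len(genome[c])
            ]
            if not exons:
                continue
            chrom = exons[0][0]
            chain = [(s, e) for (_c, s, e) in exons]
            circ_seq = "".join(genome[chrom][s - 1 : e] for s, e in chain)
            templates.append(
                CircTemplate(
                    circ_id=f"{chrom}:{chain[0][0]}|{chain[-1][1]}",
                    chrom=chrom,
                    cirexons=chain,
                    sequence=circ_seq,
                    isoform_index=0,
                    true_abundance=draw_coverage(
                        config.depth_D, rng, config.coverage_cap
                    ),
                )
            )
        return templates
    chroms = sorted(genome)
    made = 0
    attempts = 0
    while made < config.n_circ:
        attempts += 1
        if attempts > 100 * config.n_circ:
            raise RuntimeError("could not place templates on the given genome")
        chrom = chroms[int(rng.integers(len(chroms)))]
        L = int(round(rng.normal(config.circ_len_mu, config.circ_len_sigma)))
        if L < config.min_circ_len or L >= len(genome[chrom]):
            continue
        start = int(rng.integers(1, len(genome[chrom]) - L + 1))
        chain = [(start, start + L - 1)]
        templates.append(
            CircTemplate(
                circ_id=f"{chrom}:{start}|{start + L - 1}",
                chrom=chrom,
                cirexons=chain,
                sequence=genome[chrom][start - 1 : start + L - 1],
                isoform_index=0,
                true_abundance=draw_coverage(config.depth_D, rng, config.coverage_cap),
            )
        )
        made += 1
    return templates


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------

def _inject_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        cur = arr[i]
        choices = [b for b in (b"A", b"C", b"G", b"T") if b != cur]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode()


def roll_reads(
    template: CircTemplate,
    coverage: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[tuple[str, str, str]], list[TruthRecord]]:
    """Generate read pairs from one circular template at the given coverage.

    A fragment is a contiguous walk of length L (drawn per pair) around the
    circle from a uniform start; read1 is the first R bases of the walk and
    read2 the reverse complement of the last R bases.  Pair count is
    ``round(coverage * circle_len / (2 R))``.
    """
    circ = template.sequence
    n = len(circ)
    if n == 0:
        raise ValueError("empty template sequence")
    R = config.read_length
    n_pairs = int(round(coverage * n / (2.0 * R)))
    pairs: list[tuple[str, str, str]] = []
    truth: list[TruthRecord] = []
    for serial in range(n_pairs):
        start = int(rng.integers(n))
        L = draw_insert_length(
            config.insert_mu, config.insert_sigma, rng, min_len=R
        )
        reps = (start + L) // n + 2
        walk = (circ * reps)[start : start + L]
        r1 = _inject_errors(walk[:R], config.error_rate, rng)
        r2 = _inject_errors(revcomp(walk[L - R :]), config.error_rate, rng)
        rid = f"{template.circ_id}|{template.isoform_index}|{serial}"
        pairs.append((rid, r1, r2))
        truth.append(
            TruthRecord(
                read_id=rid,
                circ_id=template.circ_id,
                isoform_index=template.isoform_index,
                fragment_start_on_circle=start,
                insert_length=L,
            )
        )
    return pairs, truth


def _linear_reads(
    genome: dict[str, str],
    n_pairs: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[tuple[str, str, str]], list[TruthRecord]]:
    """Plain linear-fragment contamination (no RO structure)."""
    chroms = sorted(genome)
    R = config.read_length
    pairs: list[tuple[str, str, str]] = []
    truth: list[TruthRecord] = []
    made = 0
    while made < n_pairs:
        chrom = chroms[int(rng.integers(len(chroms)))]
        cseq = genome[chrom]
        L = draw_insert_length(config.insert_mu, config.insert_sigma, rng, min_len=R)
        if L >= len(cseq):
            continue
        start = int(rng.integers(0, len(cseq) - L + 1))
        frag = cseq[start : start + L]
        rid = f"linear|{chrom}|{made}"
        pairs.append(
            (
                rid,
                _inject_errors(frag[:R], config.error_rate, rng),
                _inject_errors(revcomp(frag[L - R :]), config.error_rate, rng),
            )
        )
        truth.append(TruthRecord(rid, "linear", -1, start, L))
        made += 1
    return pairs, truth


# ---------------------------------------------------------------------------
# Dataset assembly and serialisation
# ---------------------------------------------------------------------------

def simulate_dataset(
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> SimResult:
    """Run the full simulator: genome, templates, reads, truth."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    templates, genome = make_templates(config, rng)
    pairs: list[tuple[str, str, str]] = []
    truth: list[TruthRecord] = []
    for tpl in templates:
        p, t = roll_reads(tpl, tpl.true_abundance, config, rng)
        pairs.extend(p)
        truth.extend(t)
    if config.linear_fraction > 0:
        n_lin = int(round(config.linear_fraction * len(pairs)))
        p, t = _linear_reads(genome, n_lin, config, rng)
        pairs.extend(p)
        truth.extend(t)
    return SimResult(genome=genome, templates=templates, pairs=pairs, truth=truth,
                     config=config)


def write_dataset(result: SimResult, outdir: str) -> dict[str, str]:
    """Write FASTQ pair, genome/circle FASTA and truth/template TSVs.

    Returns a dict of logical name -> path.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "reads_1": os.path.join(outdir, "reads_1.fastq"),
        "reads_2": os.path.join(outdir, "reads_2.fastq"),
        "genome": os.path.join(outdir, "genome.fa"),
        "circles": os.path.join(outdir, "circles.fa"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "templates": os.path.join(outdir, "templates.tsv"),
    }
    R = result.config.read_length if result.config else len(result.pairs[0][1])
    qual = "I" * R
    write_fastq(paths["reads_1"], [(f"{rid}/1", s1, qual) for rid, s1, _ in result.pairs])
    write_fastq(paths["reads_2"], [(f"{rid}/2", s2, qual) for rid, _, s2 in result.pairs])
    write_fasta(paths["genome"], sorted(result.genome.items()))
    write_fasta(
        paths["circles"],
        [(f"{t.circ_id}|{t.isoform_index}", t.sequence) for t in result.templates],
    )
    write_tsv(
        paths["truth"],
        ["read_id", "circ_id", "isoform_index", "fragment_start_on_circle", "insert_length"],
        [
            (t.read_id, t.circ_id, t.isoform_index, t.fragment_start_on_circle, t.insert_length)
            for t in result.truth
        ],
    )
    total = {}
    for t in result.templates:
        total[t.circ_id] = total.get(t.circ_id, 0.0) + t.true_abundance
    write_tsv(
        paths["templates"],
        ["circ_id", "isoform_index", "cirexons", "length", "true_abundance", "relative_abundance"],
        [
            (
                t.circ_id,
                t.isoform_index,
                ",".join(f"{s}-{e}" for s, e in t.cirexons),
                t.length,
                f"{t.true_abundance:.4f}",
                f"{t.true_abundance / total[t.circ_id]:.6f}",
            )
            for t in result.templates
        ],
    )
    return paths
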