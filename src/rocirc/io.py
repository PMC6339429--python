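"""Format adapters: FASTA/FASTQ/SAM/GTF/TSV.

Thin wrappers over Biopython and pysam so the rest of the package deals in
plain dictionaries and dataclasses.  Genomic coordinates are 1-based
inclusive at every external surface (matching ``chrom:start|end`` circRNA
identifiers) and 0-based half-open internally.
"""

from __future__ import annotations

import os
import re
from typing import Iterator

from Bio import SeqIO

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> dict[str, str]:
    """Load a FASTA file into ``{name: sequence}`` (uppercased)."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"FASTA not found: {path}")
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(path: str, records: list[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality-string) records."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"FASTQ not found: {path}")
    for rec in SeqIO.parse(path, "fastq"):
        yield (
            rec.id,
            str(rec.seq).upper(),
            "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]),
        )


def write_fastq(path: str, records: list[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_pairs(fastq1: str, fastq2: str) -> Iterator[tuple[str, str, str, str, str]]:
    """Yield (pair_id, seq1, qual1, seq2, qual2) from two mate files.

    Mate suffixes ``/1``/``/2`` are stripped from the pair id.  Files must be
    synchronised (same order, same count); a mismatch raises ValueError with
    the offending record number.
    """
    it1, it2 = read_fastq(fastq1), read_fastq(fastq2)
    n = 0
    for (id1, s1, q1), (id2, s2, q2) in zip(it1, it2, strict=True):
        n += 1
        base1 = re.sub(r"/[12]$", "", id1)
        base2 = re.sub(r"/[12]$", "", id2)
        if base1 != base2:
            raise ValueError(f"mate id mismatch at record {n}: {id1!r} vs {id2!r}")
        yield base1, s1, q1, s2, q2


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gtf_exons(path: str) -> dict[str, list[tuple[str, int, int, str]]]:
    """Group GTF exon lines by transcript_id.

    Returns ``{transcript_id: [(chrom, start, end, strand), ...]}`` with
    1-based inclusive coordinates, exons sorted by start.
    """
    tx: dict[str, list[tuple[str, int, int, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: malformed GTF line")
            if fields[2] != "exon":
                continue
            attrs = dict(_GTF_ATTR.findall(fields[8]))
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ValueError(f"{path}:{lineno}: exon without transcript_id")
            tx.setdefault(tid, []).append(
                (fields[0], int(fields[3]), int(fields[4]), fields[6])
            )
    for exons in tx.values():
        exons.sort(key=lambda e: e[1])
    return tx


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def write_tsv(path: str, header: list[str], rows: list[tuple]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
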