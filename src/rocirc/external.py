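"""Invocation of an external local aligner (BWA-MEM) for large references.

The verification stage wants split (chimeric) local alignments with a
minimum output score; BWA-MEM run with ``-T <min_score>`` provides exactly
that.  The built-in aligner covers small references and tests; for anything
genome-sized these helpers shell out to ``bwa`` when it is on PATH.
"""

from __future__ import annotations

import os
import shutil
import subprocess


def bwa_available() -> bool:
    return shutil.which("bwa") is not None


def bwa_index(genome_fa: str) -> None:
    """Build a BWA index next to the FASTA (idempotent)."""
    if all(os.path.exists(genome_fa + ext) for ext in (".bwt", ".sa", ".pac")):
        return
    subprocess.run(
        ["bwa", "index", genome_fa],
        check=True,
        stdout=subprocess.DEVNULL,
        stderr=subprocess.DEVNULL,
    )


def bwa_align(
    reads_fa: str,
    genome_fa: str,
    out_sam: str,
    min_score: int = 19,
    threads: int = 1,
) -> str:
    """Run ``bwa mem -T <min_score>`` and write a SAM of split alignments."""
    bwa_index(genome_fa)
    with open(out_sam, "w") as out:
        subprocess.run(
            ["bwa", "mem", "-t", str(threads), "-T", str(min_score), genome_fa, reads_fa],
            check=True,
            stdout=out,
            stderr=subprocess.DEVNULL,
        )
    return out_sam
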