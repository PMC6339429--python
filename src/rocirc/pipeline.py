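"""End-to-end pipeline driver: reads in, circRNA tables out.

Stage order: RO detection -> alignment (internal aligner, BWA-MEM, or a
user-supplied SAM) -> RO verification and BSJ calling (independent
branches) -> cirexon inference -> assembly -> forward-splice-graph isoform
quantification.  Per-stage read counts are conserved in the run log (reads
in = kept + dropped-with-reason).
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field, asdict

import numpy as np

from rocirc import assemble as _assemble
from rocirc import bsj as _bsj
from rocirc import quantify as _quant
from rocirc.align import (
    GenomeIndex,
    SplitAlignment,
    VerifyParams,
    classify_full_length,
    extract_bsj,
    map_candidates,
    verify_merged_read,
)
from rocirc.bsj import BSJ
from rocirc.io import read_fasta, read_pairs, write_fasta, write_tsv
from rocirc.quantify import QuantParams, fit_insert_model
from rocirc.rodetect import ROParams, ReadPair, detect_ro_pairs

logger = logging.getLogger("rocirc")


@dataclass
class PipelineConfig:
    ro: ROParams = field(default_factory=ROParams)
    verify: VerifyParams = field(default_factory=VerifyParams)
    quant: QuantParams = field(default_factory=QuantParams)
    aligner: str = "internal"  # internal | bwa | external
    min_bsj_reads: int = 1
    insert_mu: float = 350.0  # fallback insert model
    insert_sigma: float = 200.0
    seed: int = 0
    threads: int = 1

    _SECTIONS = {"ro": ROParams, "verify": VerifyParams, "quant": QuantParams}

    def to_dict(self) -> dict:
        flat = {}
        for section in self._SECTIONS:
            for key, val in asdict(getattr(self, section)).items():
                flat[f"{section}.{key}"] = val
        for key in ("aligner", "min_bsj_reads", "insert_mu", "insert_sigma", "seed", "threads"):
            flat[key] = getattr(self, key)
        return flat

    @classmethod
    def from_dict(cls, flat: dict) -> "PipelineConfig":
        cfg = cls()
        for key, val in flat.items():
            if "." in key:
                section, name = key.split(".", 1)
                if section not in cls._SECTIONS:
                    raise KeyError(f"unknown config section: {section}")
                target = getattr(cfg, section)
                if not hasattr(target, name):
                    raise KeyError(f"unknown config key: {key}")
                setattr(target, name, type(getattr(target, name))(val))
            else:
                if not hasattr(cfg, key) or key.startswith("_"):
                    raise KeyError(f"unknown config key: {key}")
                cur = getattr(cfg, key)
                setattr(cfg, key, type(cur)(val) if cur is not None else val)
        return cfg

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        """Flat ``key = value`` config file; unknown keys are rejected."""
        flat: dict = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key = value")
                key, val = (part.strip() for part in line.split("=", 1))
                flat[key] = val
        return cls.from_dict(flat)


@dataclass
class CircRecord:
    """Everything the pipeline knows about one BSJ locus."""

    bsj: BSJ
    cirexons: list = field(default_factory=list)
    fsjs: list = field(default_factory=list)
    assembly: object = None
    isoforms: list = field(default_factory=list)
    quant_distance: float = 0.0


@dataclass
class PipelineResult:
    records: list[CircRecord]
    counts: dict[str, int]
    insert_model: object = None
    verification_log: list[tuple[str, str, str]] = field(default_factory=list)


class StageError(RuntimeError):
    def __init__(self, stage: str, reason: str):
        super().__init__(f"[{stage}] {reason}")
        self.stage = stage


def _align_reads(
    seqs: dict[str, str],
    genome: dict[str, str],
    genome_fa: str,
    config: PipelineConfig,
    workdir: str,
    tag: str,
    sam: str | None,
    index: GenomeIndex | None,
) -> dict[str, SplitAlignment]:
    if config.aligner == "internal":
        return map_candidates(seqs, genome, mode="internal",
                              params=config.verify, index=index)
    if config.aligner == "bwa":
        from rocirc.external import bwa_align, bwa_available

        if not bwa_available():
            raise StageError("align", "bwa not found on PATH")
        fa = os.path.join(workdir, f"{tag}.fa")
        write_fasta(fa, sorted(seqs.items()))
        sam_path = bwa_align(
            fa, genome_fa, os.path.join(workdir, f"{tag}.sam"),
            min_score=config.verify.min_score, threads=config.threads,
        )
        return map_candidates(seqs, genome, mode="external", sam=sam_path,
                              params=config.verify)
    if config.aligner == "external":
        if sam is None:
            raise StageError("align", f"external mode needs a SAM for {tag}")
        return map_candidates(seqs, genome, mode="external", sam=sam,
                              params=config.verify)
    raise StageError("align", f"unknown aligner: {config.aligner}")


def run_pipeline(
    fastq1: str,
    fastq2: str,
    genome_fa: str,
    outdir: str | None = None,
    config: PipelineConfig | None = None,
    sam_merged: str | None = None,
    sam_mates: str | None = None,
    annotation: dict | None = None,
    workdir: str | None = None,
) -> PipelineResult:
    """Run the whole pipeline on one paired-end library.

    Returns a PipelineResult; when ``outdir`` is given, also writes the BSJ,
    cirexon, FSJ, circRNA-summary and isoform TSVs, the verified-read and
    full-length FASTA files, and a run log.
    """
    config = config or PipelineConfig()
    if not os.path.exists(genome_fa):
        raise StageError("input", f"genome FASTA not found: {genome_fa}")
    genome = read_fasta(genome_fa)
    counts: dict[str, int] = {}
    tmp_ctx = None
    if workdir is not None:
        os.makedirs(workdir, exist_ok=True)
    if workdir is None:
        if outdir is not None:
            workdir = os.path.join(outdir, "work")
            os.makedirs(workdir, exist_ok=True)
        else:
            tmp_ctx = tempfile.TemporaryDirectory(prefix="rocirc_")
            workdir = tmp_ctx.name

    try:
        pairs = [
            ReadPair(read_id=pid, seq1=s1, seq2=s2, qual1=q1, qual2=q2)
            for pid, s1, q1, s2, q2 in read_pairs(fastq1, fastq2)
        ]
        counts["pairs_in"] = len(pairs)
        if not pairs:
            logger.warning("empty input FASTQ; writing empty outputs")
            result = PipelineResult(records=[], counts=counts)
            if outdir:
                _write_outputs(result, genome, outdir)
            return result
        read_len = max(len(p.seq1) for p in pairs)

        # --- stage 1: RO detection -------------------------------------
        merged, _non_ro = detect_ro_pairs(pairs, config.ro)
        counts["ro_candidates"] = len(merged)
        logger.info("RO candidates: %d / %d pairs", len(merged), len(pairs))

        # --- stage 2: alignment ----------------------------------------
        index = None
        if config.aligner == "internal":
            index = GenomeIndex(genome, k=config.verify.seed_k)
        merged_seqs = {m.read_id: m.sequence for m in merged}
        sa_merged = _align_reads(merged_seqs, genome, genome_fa, config,
                                 workdir, "merged", sam_merged, index)
        # "|m1"/"|m2" suffixes survive external aligners that strip "/1"
        mate_seqs: dict[str, str] = {}
        for p in pairs:
            mate_seqs[p.read_id + "|m1"] = p.seq1
            mate_seqs[p.read_id + "|m2"] = p.seq2
        sa_mates = _align_reads(mate_seqs, genome, genome_fa, config,
                                workdir, "mates", sam_mates, index)

        # --- stage 3a: RO verification ---------------------------------
        verified: dict[str, dict] = {}
        vlog: list[tuple[str, str, str]] = []
        by_id = {m.read_id: m for m in merged}
        for rid, m in by_id.items():
            sa = sa_merged.get(rid)
            if sa is None:
                vlog.append((rid, "dropped", "unaligned"))
                continue
            status, reason, adj, oriented = verify_merged_read(
                m.sequence, sa, m.ro5_len, genome, config.verify
            )
            vlog.append((rid, status, reason or "-"))
            if status != "dropped":
                verified[rid] = {
                    "status": status,
                    "sa": adj,
                    "read": oriented,
                    "ro5": m.ro5_len,
                }
        counts["ro_verified"] = len(verified)
        counts["ro_dropped"] = len(merged) - len(verified)

        # --- stage 3b: BSJ detection from mates ------------------------
        mate_alignments = {}
        for p in pairs:
            mates = []
            for suffix, seq in (("|m1", p.seq1), ("|m2", p.seq2)):
                sa = sa_mates.get(p.read_id + suffix)
                if sa is not None:
                    mates.append((seq, sa))
            if mates:
                mate_alignments[p.read_id] = mates
        bsjs, tidied, assignment = _bsj.detect_bsj(
            mate_alignments, genome, config.verify, min_reads=1
        )
        registry: dict[tuple[str, int, int], BSJ] = {
            (b.chrom, b.start, b.end): b for b in bsjs
        }
        # RO-merged reads register BSJs too (that is the point of the RO
        # feature: even a single read pins a circRNA)
        for rid, rec in verified.items():
            hit = extract_bsj(rec["sa"])
            if hit is None:
                continue
            key = hit
            b = registry.get(key)
            if b is None:
                b = BSJ(chrom=key[0], start=key[1], end=key[2])
                registry[key] = b
            b.read_ids.add(rid)
            assignment[rid] = b.id
        all_bsjs = [
            b for b in registry.values() if len(b.read_ids) >= config.min_bsj_reads
        ]
        all_bsjs.sort(key=lambda b: (b.chrom, b.start, b.end))
        counts["bsjs"] = len(all_bsjs)

        # --- stage 4: cirexons, assembly, quantification ----------------
        records: list[CircRecord] = []
        # distances for the insert model come from full-length 3'RO reads:
        # L = circle length + 5'RO length, exactly
        distances: list[float] = []
        dist_lo: list[float] = []
        dist_hi: list[float] = []
        for bsj in all_bsjs:
            pair_ids = sorted(bsj.read_ids)
            ro_here = [
                (rid, verified[rid]["status"], verified[rid]["sa"])
                for rid in pair_ids
                if rid in verified
            ]
            mate_here = {
                rid: tidied[rid] for rid in pair_ids if rid in tidied
            }
            evidence: list[tuple[str, SplitAlignment]] = []
            for rid, sas in mate_here.items():
                for sa in sas:
                    evidence.append((rid, sa))
            for rid, _status, sa in ro_here:
                evidence.append((rid, sa))
            cirexons, fsjs = _bsj.infer_cirexons(bsj, evidence, annotation)
            ce_ivs = [ce.interval for ce in cirexons if not ce.provisional]
            # final classification now that cirexons are known
            ro_final = []
            for rid, status, sa in ro_here:
                if status == "reserve":
                    status = classify_full_length(sa, ce_ivs)
                ro_final.append((rid, status, sa))
            mate_sa_list = [sa for sas in mate_here.values() for sa in sas]
            assembly = _assemble.assemble_bsj_locus(
                bsj, cirexons, fsjs, ro_final, mate_sa_list, genome
            )
            rec = CircRecord(bsj=bsj, cirexons=cirexons, fsjs=fsjs, assembly=assembly)
            records.append(rec)
            for rid, status, sa in ro_final:
                if status == "full_length_3ro":
                    chain = _assemble.chain_from_ro_read(sa, status, cirexons)
                    if chain:
                        n = sum(e - s + 1 for s, e in chain)
                        distances.append(n + verified[rid]["ro5"])
                        dist_lo.append(n + config.ro.min_overlap)
                        dist_hi.append(n + read_len)
        insert_model = fit_insert_model(
            np.array(distances),
            read_len,
            fallback=(config.insert_mu, config.insert_sigma),
            min_pairs=config.quant.min_pairs_for_fit,
            upper_bounds=np.array(dist_hi) if dist_hi else None,
            lower_bounds=np.array(dist_lo) if dist_lo else None,
        )
        logger.info(
            "insert model: mu=%.1f sigma=%.1f (%s)",
            insert_model.mu_hat,
            insert_model.sigma_hat,
            "fitted" if insert_model.fitted else "fallback",
        )

        for rec in records:
            bsj = rec.bsj
            if rec.assembly is not None and rec.assembly.status == "partial":
                continue  # isoforms are quantified on reconstructed circRNAs
            pair_ids = sorted(bsj.read_ids)
            ro_sa = {rid: verified[rid]["sa"] for rid in pair_ids if rid in verified}
            mate_sa = {rid: tidied[rid] for rid in pair_ids if rid in tidied}
            fsg = _quant.build_fsg(bsj, rec.cirexons, rec.fsjs, mate_sa, ro_sa)
            rng = np.random.default_rng(
                [config.seed & 0x7FFFFFFF, bsj.start % 100_000, bsj.end % 100_000]
            )
            isoforms, dist = _quant.quantify_bsj(
                fsg, insert_model, read_len, rng, config.quant
            )
            rec.isoforms = isoforms
            rec.quant_distance = dist
        counts["quantified"] = sum(1 for r in records if r.isoforms)

        result = PipelineResult(
            records=records,
            counts=counts,
            insert_model=insert_model,
            verification_log=vlog,
        )
        if outdir:
            _write_outputs(result, genome, outdir)
        return result
    finally:
        if tmp_ctx is not None:
            tmp_ctx.cleanup()


def _write_outputs(result: PipelineResult, genome: dict[str, str], outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    write_tsv(
        os.path.join(outdir, "bsj.tsv"),
        ["bsj_id", "chrom", "start", "end", "strand", "n_reads"],
        [
            (r.bsj.id, r.bsj.chrom, r.bsj.start, r.bsj.end, r.bsj.strand, len(r.bsj.read_ids))
            for r in result.records
        ],
    )
    write_tsv(
        os.path.join(outdir, "cirexon.tsv"),
        ["bsj_id", "start", "end", "support_bsj", "support_ro", "annotated"],
        [
            (r.bsj.id, ce.start, ce.end, ce.support_bsj, ce.support_ro,
             "." if ce.annotated is None else ce.annotated)
            for r in result.records
            for ce in r.cirexons
        ],
    )
    write_tsv(
        os.path.join(outdir, "fsj.tsv"),
        ["bsj_id", "donor", "acceptor", "support"],
        [
            (r.bsj.id, f.donor, f.acceptor, f.support)
            for r in result.records
            for f in r.fsjs
        ],
    )
    write_tsv(
        os.path.join(outdir, "circ_summary.tsv"),
        ["bsj_id", "status", "evidence", "n_cirexons", "length", "n_bsj_reads", "n_ro_reads"],
        [
            (
                r.bsj.id,
                r.assembly.status if r.assembly else "none",
                r.assembly.evidence if r.assembly else ".",
                len(r.assembly.cirexons) if r.assembly else 0,
                sum(e - s + 1 for s, e in r.assembly.cirexons) if r.assembly else 0,
                len(r.bsj.read_ids),
                r.assembly.n_ro_reads if r.assembly else 0,
            )
            for r in result.records
        ],
    )
    write_tsv(
        os.path.join(outdir, "isoforms.tsv"),
        ["bsj_id", "serial", "cirexons", "kind", "abundance", "relative_abundance", "length"],
        [
            (
                iso.bsj_id,
                i,
                "|".join(f"{s}-{e}" for s, e in iso.cirexons),
                iso.kind,
                iso.putative_abundance,
                f"{iso.relative_abundance:.6f}",
                iso.length,
            )
            for r in result.records
            for i, iso in enumerate(r.isoforms)
        ],
    )
    full = [
        (
            f"{r.assembly.bsj_id} + {r.assembly.status} {r.assembly.evidence}",
            r.assembly.sequence,
        )
        for r in result.records
        if r.assembly and r.assembly.sequence
    ]
    write_fasta(os.path.join(outdir, "full_length.fa"), full)
    write_tsv(
        os.path.join(outdir, "verification_log.tsv"),
        ["read_id", "status", "reason"],
        result.verification_log,
    )
    with open(os.path.join(outdir, "run_log.txt"), "w") as fh:
        for key, val in result.counts.items():
            fh.write(f"{key}\t{val}\n")
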