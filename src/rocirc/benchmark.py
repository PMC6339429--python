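"""Synthetic benchmarks: simulate, run the pipeline, score against truth.

These helpers bundle the evaluation designs used throughout development:
multi-isoform reconstruction and quantification accuracy, insert-length
generator statistics, and round-trip checks of the detection stages.  Both
the test suite and the reproduction script build on them.
"""

from __future__ import annotations

import collections
import math
import tempfile
from dataclasses import dataclass

import numpy as np

from rocirc.pipeline import PipelineConfig, run_pipeline
from rocirc.simulate import SimConfig, draw_insert_length, simulate_dataset, write_dataset


@dataclass
class IsoformBenchmark:
    n_circ: int
    n_isoforms: int
    pct_all_isoforms_reconstructed: float  # % of circRNAs with every true
    # isoform chain recovered exactly
    pct_isoforms_quantified: float  # % of all true isoforms reconstructed
    # with relative abundance within 0.2 of truth
    n_isoforms_total: int
    n_isoforms_reconstructed: int


def _run_on_dataset(dataset, seed: int, aligner: str = "internal"):
    with tempfile.TemporaryDirectory(prefix="rocirc_bench_") as tmp:
        paths = write_dataset(dataset, tmp)
        cfg = PipelineConfig(aligner=aligner, seed=seed)
        return run_pipeline(
            paths["reads_1"], paths["reads_2"], paths["genome"], config=cfg
        )


def multi_isoform_benchmark(
    n_circ: int = 200,
    n_isoforms: int = 3,
    depth: float = 50.0,
    read_length: int = 150,
    seed: int = 0,
    aligner: str = "internal",
    isoform_ratios: tuple[float, ...] | None = None,
    min_bsj_reads: int = 0,
) -> IsoformBenchmark:
    """Simulate multi-isoform circRNAs, run the pipeline, score recovery.

    A circRNA counts as fully recovered when every one of its true isoform
    cirexon chains appears among the reported isoform paths; an isoform is
    correctly quantified when it is recovered and its estimated relative
    abundance is within 0.2 of the designed one.  ``min_bsj_reads``
    restricts scoring to circRNAs with at least that many supporting pairs.
    """
    cfg = SimConfig(
        n_circ=n_circ,
        depth_D=depth,
        read_length=read_length,
        n_isoforms_per_circ=n_isoforms,
        isoform_ratios=isoform_ratios,
        seed=seed,
    )
    dataset = simulate_dataset(cfg)
    result = _run_on_dataset(dataset, seed, aligner)

    truth = collections.defaultdict(dict)
    totals = collections.defaultdict(float)
    for t in dataset.templates:
        truth[t.circ_id][tuple(t.cirexons)] = t
        totals[t.circ_id] += t.true_abundance
    by_id = {r.bsj.id: r for r in result.records}

    n_scored = 0
    n_full = 0
    iso_total = 0
    iso_recon = 0
    iso_ok = 0
    for cid, chains in truth.items():
        rec = by_id.get(cid)
        if min_bsj_reads and (rec is None or len(rec.bsj.read_ids) < min_bsj_reads):
            continue
        n_scored += 1
        found = {tuple(i.cirexons): i for i in rec.isoforms} if rec else {}
        hits = sum(1 for ch in chains if ch in found)
        if hits == len(chains):
            n_full += 1
        for ch, tpl in chains.items():
            iso_total += 1
            if ch in found:
                iso_recon += 1
                true_rel = tpl.true_abundance / totals[cid]
                if abs(found[ch].relative_abundance - true_rel) < 0.2:
                    iso_ok += 1
    return IsoformBenchmark(
        n_circ=n_scored,
        n_isoforms=n_isoforms,
        pct_all_isoforms_reconstructed=100.0 * n_full / max(n_scored, 1),
        pct_isoforms_quantified=100.0 * iso_ok / max(iso_total, 1),
        n_isoforms_total=iso_total,
        n_isoforms_reconstructed=iso_recon,
    )


def insert_length_stats(
    n: int = 100_000, mu: float = 350.0, sigma: float = 200.0, seed: int = 0
) -> tuple[float, float, float, float]:
    """Sample mean/SD of the Box-Muller insert generator, with their
    standard errors (no resampling floor)."""
    rng = np.random.default_rng(seed)
    draws = np.array([draw_insert_length(mu, sigma, rng) for _ in range(n)])
    se_mean = sigma / math.sqrt(n)
    se_sd = sigma / math.sqrt(2 * n)
    return float(draws.mean()), float(draws.std(ddof=1)), se_mean, se_sd


def full_length_roundtrip(
    n_circ: int = 25, seed: int = 0, aligner: str = "internal"
) -> tuple[int, int, int]:
    """Round-trip check in the favourable regime circle_len < insert <= 2R.

    Simulates short circles with inserts mostly covering them fully, then
    counts the eligible circles (those with at least one fragment satisfying
    circle_len < L <= 2R), how many were recalled as BSJs, and how many were
    reconstructed completely with the exact circle sequence.
    """
    cfg = SimConfig(
        n_circ=n_circ,
        depth_D=10.0,
        read_length=150,
        insert_mu=280.0,
        insert_sigma=20.0,
        circ_len_mu=220.0,
        circ_len_sigma=20.0,
        seed=seed,
    )
    dataset = simulate_dataset(cfg)
    result = _run_on_dataset(dataset, seed, aligner)
    lengths = {t.circ_id: t.length for t in dataset.templates}
    seqs = {t.circ_id: t.sequence for t in dataset.templates}
    # a pair certifies its circle when the 5' overlap is detectable
    # (>= 13 bases) and its merged walk crosses every junction of the
    # circle -- the back-splice point and each forward splice -- at least
    # one minimum-placeable fragment (19 bases) away from both walk ends;
    # a junction hidden inside a walk end is invisible to any local
    # aligner with that score floor
    R = cfg.read_length
    min_overlap, min_place = 13, 19
    chains = {t.circ_id: t.cirexons for t in dataset.templates}
    junctions: dict[str, list[int]] = {}
    for cid, chain in chains.items():
        cums = [0]
        for s, e in chain[:-1]:
            cums.append(cums[-1] + (e - s + 1))
        junctions[cid] = [c % lengths[cid] for c in cums]
    eligible = set()
    for t in dataset.truth:
        n = lengths[t.circ_id]
        L = t.insert_length
        v = L - n
        if not (min_overlap <= v and L <= 2 * R):
            continue
        walk_len = 2 * R - v
        a = (t.fragment_start_on_circle + L - R) % n

        def visible(c: int) -> bool:
            t0 = (c - a) % n
            return any(
                min_place <= off <= walk_len - min_place
                for off in range(t0, walk_len + 1, n)
            )

        if all(visible(c) for c in junctions[t.circ_id]):
            eligible.add(t.circ_id)
    by_id = {r.bsj.id: r for r in result.records}
    recalled = sum(1 for cid in eligible if cid in by_id)
    exact = sum(
        1
        for cid in eligible
        if cid in by_id
        and by_id[cid].assembly.status == "complete"
        and by_id[cid].assembly.sequence == seqs[cid]
    )
    return len(eligible), recalled, exact


def ratio_recovery(
    ratios: tuple[float, ...] = (0.5, 0.75, 0.9),
    n_circ: int = 25,
    depth: float = 75.0,
    min_bsj_reads: int = 30,
    seed: int = 0,
    aligner: str = "internal",
) -> tuple[int, int]:
    """Two-isoform ratio recovery at moderate-to-high expression.

    For each designed major-isoform fraction, simulates two-isoform
    circRNAs, and over circRNAs with at least ``min_bsj_reads`` supporting
    pairs counts those whose both isoform abundances are recovered within
    0.2.  Returns (n_correct, n_assessed) pooled over the ratios.
    """
    correct = 0
    assessed = 0
    for k, r in enumerate(ratios):
        cfg = SimConfig(
            n_circ=n_circ,
            depth_D=depth,
            read_length=150,
            n_isoforms_per_circ=2,
            isoform_ratios=(r, round(1.0 - r, 6)),
            seed=seed + 1000 * (k + 1),
        )
        dataset = simulate_dataset(cfg)
        result = _run_on_dataset(dataset, seed + 1000 * (k + 1), aligner)
        truth = collections.defaultdict(dict)
        totals = collections.defaultdict(float)
        for t in dataset.templates:
            truth[t.circ_id][tuple(t.cirexons)] = t
            totals[t.circ_id] += t.true_abundance
        by_id = {rec.bsj.id: rec for rec in result.records}
        for cid, chains in truth.items():
            rec = by_id.get(cid)
            if rec is None or len(rec.bsj.read_ids) < min_bsj_reads:
                continue
            assessed += 1
            found = {tuple(i.cirexons): i for i in rec.isoforms}
            ok = all(
                ch in found
                and abs(
                    found[ch].relative_abundance
                    - tpl.true_abundance / totals[cid]
                )
                < 0.2
                for ch, tpl in chains.items()
            )
            correct += int(ok)
    return correct, assessed
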