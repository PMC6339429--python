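"""Isoform-level circRNA quantification on a forward splice graph (FSG).

Per BSJ, the FSG has cirexons as nodes and forward-splice junctions as
edges, closed into a circuit by the back-splice edge from the last cirexon
back to the first.  Every simple circular path through the BSJ edge is a
candidate isoform.  Edges fall into four categories: the BSJ edge, phasing
FSJs (carried by exactly one enumerated path), co-occurred FSJ sets (seen
together on a single RO-merged read), and the remainder.  Paths pinned by a
phasing edge or a co-occurred set are "phased" isoforms and always retained;
the rest are ranked by node sequencing depth to fill a fixed quota.

Abundances are assigned by an approximate exhaustive search: each retained
path's expected per-read footprint over nodes and edges is obtained by Monte
Carlo simulation of BSJ read pairs (insert lengths from a model fitted to
the library), and positive integer path abundances summing to the total BSJ
read count are iteratively adjusted to minimise the L1 distance between the
accumulated putative node/edge abundances and the observed ones, with random
restarts whenever a local minimum is reached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from rocirc.align import SplitAlignment
from rocirc.bsj import BSJ, Cirexon, FSJ


@dataclass
class QuantParams:
    max_paths: int = 10  # screened path quota
    n_sim: int = 10_000  # Monte-Carlo virtual pairs per path
    flank: int = 5  # junction flank bases defining a junction-crossing read
    max_restarts: int = 50
    patience: int = 20  # restarts without improvement before stopping
    path_cap: int = 1000  # enumeration guard
    min_pairs_for_fit: int = 100


@dataclass
class FSG:
    """Closed splice graph for one BSJ: nodes are cirexons, edges are FSJs
    plus the closing BSJ edge; node depths and edge supports are observed
    from the BSJ reads."""

    bsj_id: str
    nodes: list[tuple[int, int]]  # cirexon intervals, genomic order
    node_depth: list[float]  # mean per-base read depth per node
    edges: dict[tuple[int, int], set[str]]  # (u, v) node indices -> read ids
    co_sets: list[frozenset[tuple[int, int]]] = field(default_factory=list)
    total_reads: int = 0

    @property
    def bsj_edge(self) -> tuple[int, int]:
        return (len(self.nodes) - 1, 0)

    def node_len(self, i: int) -> int:
        s, e = self.nodes[i]
        return e - s + 1


@dataclass
class IsoformPath:
    bsj_id: str
    nodes: tuple[int, ...]
    kind: str  # phased | candidate
    putative_abundance: int = 0
    relative_abundance: float = 0.0
    cirexons: tuple[tuple[int, int], ...] = ()
    length: int = 0


@dataclass
class InsertLengthModel:
    """Insert-length distribution of the library, Normal(mu, sigma) left-
    truncated at the read length (a fragment shorter than one read is never
    sequenced as a proper pair)."""

    mu_hat: float
    sigma_hat: float
    min_len: int = 0
    fitted: bool = True

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sigma_hat <= 0:
            return np.full(n, max(self.mu_hat, self.min_len + 1))
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.normal(self.mu_hat, self.sigma_hat, size=2 * (n - filled) + 16)
            good = draw[draw > self.min_len]
            take = min(len(good), n - filled)
            out[filled : filled + take] = good[:take]
            filled += take
        return out


# ---------------------------------------------------------------------------
# FSG construction
# ---------------------------------------------------------------------------


def build_fsg(
    bsj: BSJ,
    cirexons: list[Cirexon],
    fsjs: list[FSJ],
    bsj_read_alignments: dict[str, list[SplitAlignment]],
    ro_alignments: dict[str, SplitAlignment] | None = None,
) -> FSG:
    """Assemble the forward splice graph for one BSJ.

    Node depths are mean per-base coverage over the BSJ read pairs (an RO
    pair contributes through its merged read); edge supports are distinct
    pairs whose alignment contains the junction.  FSJ pairs observed on a
    single RO-merged read are recorded as co-occurring edge sets.
    """
    ro_alignments = ro_alignments or {}
    nodes = sorted({ce.interval for ce in cirexons})
    node_of_start = {s: i for i, (s, _e) in enumerate(nodes)}
    node_of_end = {e: i for i, (_s, e) in enumerate(nodes)}
    span_lo = bsj.start
    cover = {i: 0 for i in range(len(nodes))}

    def junction_edge(d: int, a: int) -> tuple[int, int] | None:
        u, v = node_of_end.get(d), node_of_start.get(a)
        if u is None or v is None:
            return None
        return (u, v)

    edges: dict[tuple[int, int], set[str]] = {}
    n_nodes = len(nodes)
    bsj_edge = (n_nodes - 1, 0)
    edges[bsj_edge] = set()

    def scan(pair_id: str, sas: list[SplitAlignment], co_bucket=None) -> None:
        local_edges = set()
        for sa in sas:
            segs = sorted(sa.segments, key=lambda s: s.read_start)
            for seg in segs:
                if seg.chrom != bsj.chrom:
                    continue
                for i, (s, e) in enumerate(nodes):
                    lo, hi = max(s, seg.ref_start), min(e, seg.ref_end)
                    if hi >= lo:
                        cover[i] += hi - lo + 1
            for left, right in zip(segs, segs[1:]):
                if left.chrom != bsj.chrom:
                    continue
                d, a = left.ref_end, right.ref_start
                if a <= d:  # back-splice
                    if d == bsj.end and a == bsj.start:
                        edges[bsj_edge].add(pair_id)
                    continue
                edge = junction_edge(d, a)
                if edge is not None:
                    edges.setdefault(edge, set()).add(pair_id)
                    local_edges.add(edge)
        if co_bucket is not None and len(local_edges) >= 2:
            co_bucket.append(frozenset(local_edges))

    co_sets: list[frozenset] = []
    for pair_id, sas in bsj_read_alignments.items():
        if pair_id in ro_alignments:
            scan(pair_id, [ro_alignments[pair_id]], co_sets)
        else:
            scan(pair_id, sas)
    for pair_id, sa in ro_alignments.items():
        if pair_id not in bsj_read_alignments:
            scan(pair_id, [sa], co_sets)

    total = len(set(bsj_read_alignments) | set(ro_alignments))
    depth = [cover[i] / (nodes[i][1] - nodes[i][0] + 1) for i in range(n_nodes)]
    return FSG(
        bsj_id=bsj.id,
        nodes=nodes,
        node_depth=depth,
        edges=edges,
        co_sets=sorted(set(co_sets), key=sorted),
        total_reads=total,
    )


# ---------------------------------------------------------------------------
# Path enumeration and screening
# ---------------------------------------------------------------------------


def enumerate_paths(
    fsg: FSG, params: QuantParams | None = None
) -> tuple[list[tuple[int, ...]], list[tuple[int, ...]]]:
    """All simple circular paths through the BSJ edge, plus open fragments.

    The forward edges form a DAG on genomic node order, so closed circuits
    are exactly the simple paths from the start cirexon (BSJ acceptor) to
    the end cirexon (BSJ donor), closed by the BSJ edge.  When the graph is
    broken (a node unreachable or unable to reach the end), the maximal open
    fragments are returned separately, flagged by exclusion from the closed
    list.  Sub-paths of longer paths and duplicates never arise by
    construction (all paths are maximal 0 -> last walks).
    """
    params = params or QuantParams()
    n = len(fsg.nodes)
    if n == 1:
        return [(0,)], []
    adj: dict[int, list[int]] = {}
    for (u, v) in fsg.edges:
        if (u, v) == fsg.bsj_edge:
            continue
        adj.setdefault(u, []).append(v)
    for vs in adj.values():
        vs.sort()
    closed: list[tuple[int, ...]] = []
    fragments: list[tuple[int, ...]] = []
    last = n - 1

    def dfs(u: int, path: list[int]) -> None:
        if len(closed) >= params.path_cap:
            return
        if u == last:
            closed.append(tuple(path))
            return
        nxt = adj.get(u, [])
        if not nxt:
            fragments.append(tuple(path))
            return
        for v in nxt:
            path.append(v)
            dfs(v, path)
            path.pop()

    dfs(0, [0])
    # fragments starting after a breakpoint (nodes with no incoming edge)
    has_incoming = {v for vs in adj.values() for v in vs}
    for start in range(1, n):
        if start not in has_incoming:
            stack = [(start, (start,))]
            while stack:
                u, path = stack.pop()
                nxt = adj.get(u, [])
                if not nxt or u == last:
                    if path not in fragments and len(path) > 1:
                        fragments.append(path)
                    continue
                for v in nxt:
                    stack.append((v, path + (v,)))
    return closed, fragments


def screen_paths(
    paths: list[tuple[int, ...]],
    fsg: FSG,
    k: int = 10,
) -> list[IsoformPath]:
    """Select up to k paths: phased isoforms first, then by node depth.

    A path is phased when it contains a phasing FSJ (an edge carried by
    exactly one path) or a complete co-occurred edge set.  Remaining paths
    are ranked by length-weighted mean node depth; ties break toward the
    lexicographically smallest node sequence.
    """
    if not paths:
        return []

    def path_edges(p: tuple[int, ...]) -> set[tuple[int, int]]:
        return set(zip(p, p[1:]))

    edge_count: dict[tuple[int, int], int] = {}
    for p in paths:
        for e in path_edges(p):
            edge_count[e] = edge_count.get(e, 0) + 1
    phasing = {e for e, c in edge_count.items() if c == 1 and e in fsg.edges}

    def depth_rank(p: tuple[int, ...]) -> float:
        total_len = sum(fsg.node_len(i) for i in p)
        return sum(fsg.node_depth[i] * fsg.node_len(i) for i in p) / total_len

    phased, rest = [], []
    for p in paths:
        pe = path_edges(p)
        is_phased = bool(pe & phasing) or any(cs <= pe for cs in fsg.co_sets if cs)
        (phased if is_phased else rest).append(p)
    rest.sort(key=lambda p: (-depth_rank(p), p))
    selected = phased + rest[: max(0, k - len(phased))]
    out = []
    for p in selected:
        cirexons = tuple(fsg.nodes[i] for i in p)
        out.append(
            IsoformPath(
                bsj_id=fsg.bsj_id,
                nodes=p,
                kind="phased" if p in phased else "candidate",
                cirexons=cirexons,
                length=sum(e - s + 1 for s, e in cirexons),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Insert-length model
# ---------------------------------------------------------------------------


def fit_insert_model(
    distances: np.ndarray,
    read_len: int,
    fallback: tuple[float, float] = (350.0, 200.0),
    min_pairs: int = 100,
    upper_bounds: np.ndarray | None = None,
    lower_bounds: np.ndarray | None = None,
) -> InsertLengthModel:
    """Fit the library insert-length distribution from mapping distances.

    Distances are modelled as Normal(mu, sigma) truncated below at the read
    length (library floor); per-observation upper truncation bounds may be
    supplied for distances measured on circles, where only inserts below
    circle length + overlap threshold are observable unambiguously.  A
    robust median/MAD estimate initialises a truncated-normal MLE.  With
    fewer than ``min_pairs`` observations the configured fallback is used.
    """
    d = np.asarray(distances, dtype=float)
    if d.size < min_pairs:
        return InsertLengthModel(fallback[0], fallback[1], read_len, fitted=False)
    if np.ptp(d) == 0:
        return InsertLengthModel(float(d[0]), 0.0, read_len)
    mu0 = float(np.median(d))
    sigma0 = float(1.4826 * np.median(np.abs(d - mu0)))
    if sigma0 <= 0:
        sigma0 = float(np.std(d)) or 1.0
    lo = (
        np.asarray(lower_bounds, dtype=float)
        if lower_bounds is not None
        else np.full_like(d, float(read_len))
    )
    hi = (
        np.asarray(upper_bounds, dtype=float)
        if upper_bounds is not None
        else np.full_like(d, np.inf)
    )

    def nll(theta: np.ndarray) -> float:
        mu, log_sigma = theta
        sigma = math.exp(log_sigma)
        z = (d - mu) / sigma
        a = (lo - mu) / sigma
        b = (hi - mu) / sigma
        log_mass = np.where(
            np.isinf(b),
            stats.norm.logsf(a),
            np.log(np.clip(stats.norm.cdf(b) - stats.norm.cdf(a), 1e-300, None)),
        )
        return float(np.sum(0.5 * z**2 + log_sigma + log_mass))

    try:
        res = optimize.minimize(
            nll, x0=[mu0, math.log(sigma0)], method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 500},
        )
        if res.success or res.fun < nll(np.array([mu0, math.log(sigma0)])):
            return InsertLengthModel(
                float(res.x[0]), float(math.exp(res.x[1])), read_len
            )
    except (ValueError, FloatingPointError):
        pass
    return InsertLengthModel(mu0, sigma0, read_len)


# ---------------------------------------------------------------------------
# Monte-Carlo read profiles
# ---------------------------------------------------------------------------


def _circular_coverage(M: int, starts: np.ndarray, length: int) -> np.ndarray:
    """Summed coverage of intervals [s, s+length) on a circle of size M."""
    cov = np.zeros(M + 1)
    full, rem = divmod(length, M)
    base = full * len(starts)
    if rem:
        s = starts % M
        e = s + rem
        np.add.at(cov, s, 1.0)
        wrap = e > M
        np.add.at(cov, np.where(wrap, M, e), -1.0)
        if wrap.any():
            cov[0] += wrap.sum()
            np.add.at(cov, (e[wrap] - M), -1.0)
    out = np.cumsum(cov[:M])
    return out + base


def simulate_read_profile(
    path: tuple[int, ...],
    fsg: FSG,
    insert_model: InsertLengthModel,
    read_len: int,
    n_sim: int,
    rng: np.random.Generator,
    flank: int = 5,
) -> dict:
    """Expected per-BSJ-read node/edge footprint of one path.

    Virtual read pairs are placed uniformly around the circularised path
    with insert lengths drawn from the model; only pairs that actually cross
    the BSJ (with ``flank`` intact bases either side, as a real BSJ read
    must) are retained.  Returns, per node, the expected per-base depth
    contributed by one BSJ read of this path, and per edge the probability
    that such a read's alignment contains the junction.
    """
    node_lens = [fsg.node_len(i) for i in path]
    M = sum(node_lens)
    R = read_len
    bounds = np.cumsum([0] + node_lens)  # path coords of node starts
    junctions = [0] + [int(b) for b in bounds[1:-1]]  # 0 = BSJ junction
    edge_keys = [fsg.bsj_edge] + [
        (path[i], path[i + 1]) for i in range(len(path) - 1)
    ]

    accepted_starts1 = []
    accepted_starts2 = []
    n_acc = 0
    draws = 0
    while n_acc < n_sim and draws < 20 * n_sim + 1000:
        batch = max(n_sim, 1000)
        draws += batch
        s = rng.integers(0, M, size=batch)
        L = np.maximum(np.rint(insert_model.draw(batch, rng)).astype(int), R + 1)
        a1 = s
        a2 = s + L - R

        def crosses(a: np.ndarray, c: int) -> np.ndarray:
            off = (c - a - flank) % M
            span = R - 2 * flank
            if span < 0:
                return np.zeros(len(a), dtype=bool)
            return (off <= span) | (off + M <= span)

        ok = crosses(a1, 0) | crosses(a2, 0)
        accepted_starts1.append(a1[ok])
        accepted_starts2.append(a2[ok])
        n_acc += int(ok.sum())
    s1 = np.concatenate(accepted_starts1)[:n_sim]
    s2 = np.concatenate(accepted_starts2)[:n_sim]
    n_used = len(s1)
    if n_used == 0:
        # degenerate: no simulated pair can cross the BSJ (tiny path)
        node_prof = {path[i]: 1.0 for i in range(len(path))}
        edge_prof = {k: 1.0 for k in edge_keys}
        return {"nodes": node_prof, "edges": edge_prof}
    cov = _circular_coverage(M, s1, R) + _circular_coverage(M, s2, R)
    node_prof = {}
    for i, node in enumerate(path):
        seg = cov[bounds[i] : bounds[i + 1]]
        node_prof[node] = float(seg.mean() / n_used)
    edge_prof = {}
    for c, key in zip(junctions, edge_keys):
        off1 = (c - s1 - flank) % M
        off2 = (c - s2 - flank) % M
        span = R - 2 * flank
        hit = ((off1 <= span) | (off1 + M <= span)) | (
            (off2 <= span) | (off2 + M <= span)
        )
        edge_prof[key] = float(hit.mean())
    return {"nodes": node_prof, "edges": edge_prof}


# ---------------------------------------------------------------------------
# Approximate exhaustive abundance search
# ---------------------------------------------------------------------------


def _random_composition(
    total: int, parts: int, rng: np.random.Generator
) -> np.ndarray:
    """Random positive integer composition of ``total`` into ``parts``."""
    if parts == 1:
        return np.array([total])
    a = rng.multinomial(total - parts, np.full(parts, 1.0 / parts))
    return a + 1


def abundance_distance(
    abundances: np.ndarray, profile_matrix: np.ndarray, observed: np.ndarray
) -> float:
    """L1 distance between accumulated putative and observed node/edge
    abundances."""
    return float(np.abs(profile_matrix.T @ abundances - observed).sum())


def estimate_abundance(
    fsg: FSG,
    paths: list[IsoformPath],
    profiles: list[dict],
    total_reads: int,
    rng: np.random.Generator,
    params: QuantParams | None = None,
) -> tuple[list[IsoformPath], float, bool]:
    """Assign positive integer abundances (summing to the BSJ read count)
    minimising the L1 distance between putative and observed node/edge
    abundances.

    Starting from a random composition, the single count move (one unit or a
    geometric step between two paths) that most reduces the distance is
    applied greedily; a local minimum triggers a fresh random restart, and
    the best solution over restarts is kept.  Convergence is declared when
    ``patience`` consecutive restarts fail to improve the best distance.
    """
    params = params or QuantParams()
    n = len(paths)
    if n == 0 or total_reads < 1:
        return [], 0.0, True
    keys = [("n", i) for i in range(len(fsg.nodes))] + [
        ("e", e) for e in sorted(fsg.edges)
    ]
    observed = np.array(
        [
            fsg.node_depth[key[1]] if key[0] == "n" else len(fsg.edges[key[1]])
            for key in keys
        ],
        dtype=float,
    )
    P = np.zeros((n, len(keys)))
    for p_idx, prof in enumerate(profiles):
        for j, key in enumerate(keys):
            if key[0] == "n":
                P[p_idx, j] = prof["nodes"].get(key[1], 0.0)
            else:
                P[p_idx, j] = prof["edges"].get(key[1], 0.0)

    if n == 1:
        a = np.array([total_reads])
        d = abundance_distance(a, P, observed)
        result = [paths[0]]
        result[0].putative_abundance = total_reads
        result[0].relative_abundance = 1.0
        return result, d, True

    if total_reads < n:
        # cannot give every path a positive count; keep the first
        # ``total_reads`` phased/top paths at one read each
        a_best = np.zeros(n, dtype=int)
        a_best[:total_reads] = 1
        d_best = abundance_distance(a_best, P, observed)
    else:
        steps = []
        step = max(1, total_reads // 4)
        while step >= 1:
            steps.append(step)
            step //= 2
        if steps[-1] != 1:
            steps.append(1)
        a_best, d_best = None, math.inf
        stale = 0
        for _restart in range(params.max_restarts):
            a = _random_composition(total_reads, n, rng)
            pred = P.T @ a
            d = float(np.abs(pred - observed).sum())
            while True:
                best_move = None
                for i in range(n):
                    for j in range(n):
                        if i == j:
                            continue
                        diff = P[j] - P[i]
                        for s in steps:
                            if a[i] - s < 1:
                                continue
                            cand = float(np.abs(pred + s * diff - observed).sum())
                            if cand < d - 1e-12 and (
                                best_move is None or cand < best_move[0]
                            ):
                                best_move = (cand, i, j, s)
                if best_move is None:
                    break
                d, i, j, s = best_move
                a[i] -= s
                a[j] += s
                pred = pred + s * (P[j] - P[i])
            if d < d_best - 1e-12:
                a_best, d_best = a.copy(), d
                stale = 0
            else:
                stale += 1
                if stale >= params.patience:
                    break
        if a_best is None:
            a_best = _random_composition(total_reads, n, rng)
            d_best = abundance_distance(a_best, P, observed)
    converged = True
    for p, cnt in zip(paths, a_best):
        p.putative_abundance = int(cnt)
        p.relative_abundance = float(cnt) / total_reads
    return paths, float(d_best), converged


def fsg_to_dot(fsg: FSG) -> str:
    """DOT-like text rendering of one FSG, for debugging."""
    lines = [f'digraph "{fsg.bsj_id}" {{']
    for i, (s, e) in enumerate(fsg.nodes):
        lines.append(
            f'  n{i} [label="{s}-{e}\\ndepth={fsg.node_depth[i]:.1f}"];'
        )
    for (u, v), reads in sorted(fsg.edges.items()):
        style = ' style=dashed label="BSJ"' if (u, v) == fsg.bsj_edge else ""
        lines.append(f"  n{u} -> n{v} [weight={len(reads)}{style}];")
    lines.append("}")
    return "\n".join(lines)


def quantify_bsj(
    fsg: FSG,
    insert_model: InsertLengthModel,
    read_len: int,
    rng: np.random.Generator,
    params: QuantParams | None = None,
) -> tuple[list[IsoformPath], float]:
    """Enumerate, screen and quantify the isoforms of one BSJ."""
    params = params or QuantParams()
    closed, _fragments = enumerate_paths(fsg, params)
    screened = screen_paths(closed, fsg, k=params.max_paths)
    if not screened:
        return [], 0.0
    profiles = [
        simulate_read_profile(
            p.nodes, fsg, insert_model, read_len, params.n_sim, rng, params.flank
        )
        for p in screened
    ]
    total = max(fsg.total_reads, 1)
    result, distance, _ok = estimate_abundance(
        fsg, screened, profiles, total, rng, params
    )
    return result, distance
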