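# Methods

This note documents the models and procedures implemented in `rocirc`, the
defaults and why they were chosen, the numerical and design decisions made
where the problem was genuinely open, and the limits of what the synthetic
benchmarks can show.

## 1. The reverse-overlap signature

A circular RNA of length `n` is reverse-transcribed in a rolling circle, so
a sequenced fragment is a contiguous walk of insert length `L` around the
circle from a uniform start. For `L > n` the mates of a read pair (read
length `R`) satisfy `read1[:v] == revcomp(read2[:v])` with `v = L − n` — the
5' reverse overlap. Merging the pair on that overlap yields a single
contiguous walk of `2R − v` bases. Since `2R − v > n` exactly when a 5' RO
exists with `R > v`, the merged read covers the whole circle whenever the
overlap is detectable and the circle is not longer than roughly `2R`; its
two end alignments then overlap on the genome (the 3' RO), and the circle
sequence is read directly off the genome between the junction-adjusted
boundaries.

### Detection thresholds

The first 10 bases of read1 are cut into three 8-mer windows (step 1); each
window must match the reverse complement of read2 with ≥ 7 identical bases
at a common overlap offset. Candidate offsets are scanned from the largest
implied overlap down, and the first (smallest-offset) consistent one is
verified over the whole overlap: aligned length ≥ 13 and identity ≥ 0.95,
gapless, `N` counting as mismatch. Overlap disagreements during merging are
resolved toward the higher base quality, ties toward read1.

Open choices made here: seed matching is only attempted with seeds from
read1 (no retry with read2's seeds when read1's fail — symmetric in all our
tests because overlap is mutual); the overlap alignment is gapless because
the stated thresholds are per-aligned-base with no gap model.

## 2. Verification of candidate merged reads

Stage order is fixed: map → anchor → window filter → realign → linear
filter → GT/AG adjustment → classification. Each stage removes or refines;
nothing is invented outside the anchor window.

* **Mapping.** Split local alignments with minimum score 19 come either
  from BWA-MEM (`-T 19`; primary + supplementary records, soft/hard clips
  honoured, records split at long deletion/N CIGAR operations, since a DNA
  aligner writes a short intron as an in-read deletion) or from the
  built-in k-mer seed-and-extend aligner (k = 16, read sampling step 5,
  exact-extension with chaining across ≤ 3-base gaps; match +1 /
  mismatch −4; MAPQ 60 unless an equally scoring alternative placement of
  the same read interval exists, then 0). Both routes produce identical
  downstream calls on the simulator fixtures; the internal aligner is the
  default and is what every test and benchmark uses.
* **Anchor.** Longest read interval with MAPQ strictly above 15, ties to
  the leftmost genomic coordinate.
* **Window filter.** Keep iff summed read-interval length of segments
  within ±100 kb of the anchor exceeds half the read length.
* **Realignment.** Abnormal segments (strand-discordant with the anchor,
  ambiguous MAPQ away from the anchor, off-chromosome/window, or
  read-overlapping a better segment by > 5 bases) are removed; uncovered
  read intervals longer than 5 bases are placed by local affine-gap DP
  (match +1, mismatch −4, gap open −6, extend −1 — the scheme is not
  dictated by the method description; it is recorded in the config) against
  the window. An internal fragment that cannot reach score 19 discards the
  read; an unplaceable terminal fragment shorter than 19 bases is left
  soft-clipped, because no local aligner with that score floor could place
  it anywhere.
* **Linear filter.** A read with no back-spliced junction is dropped unless
  both terminal subsequences of length `v` find a placement near the
  anchor: covered ≥ 80% by the read's own alignment, an exact window hit,
  or a DP hit scoring at least half the subsequence length. Partial
  adapters on short linear fragments — the classic false 5' RO — fail all
  three; the ends of genuine circular reads pass (possibly piecewise when
  they straddle the back-splice point).
* **GT/AG adjustment.** Every junction between adjacent segments may shift
  by up to ±10 read bases (absorbing unaligned bases between segments;
  re-assigned bases must match the genome exactly) so that the intron- or
  backsplice-side dinucleotides read `GT…AG`; the nearest feasible
  canonical shift wins, which also makes boundary choices consistent across
  reads at ambiguous (repeat-containing) splice sites. If no shift is
  canonical the read is discarded — this single rule also removes lariat
  artefacts, whose wrap junction has no `AG` upstream / `GT` downstream.
  Finally the 5 read bases on each side of every junction must match the
  genome exactly.
* **Classification.** Two distinct terminal segments overlapping on the
  genome → full length by 3' RO. Ends disjoint but the read crosses a BSJ
  and both ends sit in one splice-certified cirexon → full length with the
  interior filled from the genome. Everything else is reserved for combined
  assembly. A single colinear segment is never full length.

### Ragged read ends

Exact-match extension runs past a true splice boundary whenever the next
genomic base happens to equal the next read base (microhomology), so a
read's two outermost alignment ends carry up to a few bases of false
overhang. Interior boundaries are junction-adjusted ("hard"); terminal ends
are "soft". Chains snap soft merged boundaries to a hard one within 10
bases, and the cirexon-exclusivity check grants terminal segments 10 bases
of grace. Ten bases bounds the chance-extension length at these genome
sizes (probability (1/4)^11 per end beyond it) while staying far below a
real exon or intron length.

## 3. BSJs, cirexons, assembly

A read pair supports a BSJ when one mate's adjusted split alignment
contains two segments in inverted genomic order with canonical back-splice
flanks; the acceptor start and donor end are the circle boundaries and name
it (`chrom:start|end`). The other mate contributes coverage and
forward-splice evidence but cannot re-assign the pair. A verified RO-merged
read registers its BSJ the same way — one read pair is enough to call a
circle, which is the point of the RO feature. The default minimum support
is therefore 1 read.

Within a BSJ, forward-splice junctions from the supporting reads define
donor/acceptor sites; each acceptor (plus the BSJ start) pairs with the
nearest donor-or-BSJ-end at or beyond it to form a cirexon. A cirexon must
be contiguously covered by supporting reads: uncovered interiors up to
50 bases are filled from the genome (the interval is splice-bounded, the
same inference as the same-cirexon fill), but a longer hole means a splice
event was missed — an intron may be hiding inside — so the interval is only
*provisional*: it still appears in the output but cannot certify a complete
reconstruction, back a same-cirexon fill, or count as a known cirexon in
the exclusivity check. With an annotation, cirexons matching no annotated
exon are flagged (intronic/intergenic circular fragments).

Assembly per BSJ: full-length RO chains are collected (all distinct chains
kept as isoform evidence); if every BSJ read pair falls exclusively on the
known cirexons the circle is the cirexons linearly connected; otherwise
RO-derived cirexons (interior segments, both boundaries splice-defined) are
merged in and the check re-runs. Failure leaves a *partial* record carrying
the known cirexons. *Nearly complete* is not a standard term; here it means
the full cirexon chain is determined but at least one internal junction has
no direct read support (it was inferred from the chain, the annotation or a
single evidence class). Circle sequences are reported from the BSJ acceptor
on the plus strand; minus-strand circles are handled by reverse-
complementing any read whose anchor maps to the minus strand, so all
downstream logic is plus-strand.

## 4. Isoform quantification on the forward splice graph

Quantification runs for reconstructed (complete or nearly complete)
circRNAs. The FSG has the cirexons as nodes (carrying mean per-base depth
over the BSJ read pairs, an RO pair contributing through its merged read)
and the observed forward-splice junctions plus the closing BSJ edge as
edges (carrying distinct-pair support; a junction counts for a read when
its alignment spans it with 5 intact bases each side). Forward edges go
strictly left to right in genomic order, so the graph restricted to them is
a DAG and the simple circular paths through the BSJ edge are exactly the
simple 0→last paths — these are enumerated by DFS (capped at 1000), with
open fragments reported separately when the graph is broken.

Screening keeps all phased paths — those containing an edge used by exactly
one path, or a complete co-occurring edge set observed on a single RO
read — and fills up to 10 paths total by length-weighted mean node depth,
ties to the lexicographically smallest node sequence.

**Insert-length model.** The library insert is modelled Normal(μ, σ) left-
truncated at the read length (shorter fragments are never sequenced as
proper pairs). In a circle-only library the usual proper-pair mapping
distances are unavailable, so the pipeline measures `L = chain_len + v`
exactly on every full-length 3' RO read and fits (μ, σ) by maximum
likelihood with per-observation truncation bounds `[chain_len + 13,
chain_len + R]` (the window where a 5' RO is detectable), initialised from
median/MAD. With fewer than 100 usable observations the configured values
(default 350/200) are used instead.

**Monte-Carlo profiles.** Per path, 10,000 virtual BSJ pairs are placed
uniformly on the circularised path with inserts from the model, *retaining
only pairs that cross the BSJ with intact 5-base flanks* — observed
abundances come from BSJ reads, so the expectation must condition on the
same event. The profile gives each node's expected per-read depth and each
junction's crossing probability.

**Approximate exhaustive search.** Path abundances are positive integers
summing to the total BSJ read count. The objective is the L1 distance
between observed node/edge abundances and the profile-weighted accumulated
putative abundances (L1 chosen for robustness and integer-friendliness; the
method description fixes only "distance"). From a random composition,
the single transfer between two paths (step sizes halving from total/4 down
to 1) that most reduces the distance is applied greedily; a local minimum
triggers a fresh random restart (up to 50), and search stops after 20
restarts without improvement. On every instance with ≤ 3 paths and ≤ 50
reads that the test suite enumerates exhaustively, this attains the global
minimum. Relative abundance is the integer count over the total.

## 5. The simulator

The simulator *is* the study-condition generator, not a convenience
fixture. Insert lengths use the Box–Muller form
`L = sqrt(−2 ln x1)·cos(2π x2)·σ + μ` (the sign under the root follows from
the transform; a positive sign is undefined on (0,1)), resampled above the
read length when generating fragments and unconstrained when characterising
the generator itself. Per-transcript coverage is
`C = ((D − 0.5)·3 + 1)·(1 − sqrt(x))`, whose mean is `D − 1/6` — `D` is the
average depth — and whose density decreases from zero, so most transcripts
are lowly covered, as in real circRNA libraries; a cap (default 500×)
bounds pathological draws. Circle lengths are Normal(300, 150) truncated at
100. Pair count per transcript is `round(C·n / 2R)`.

Synthetic genomes place one locus per chromosome: random sequence, exons
split from the circle length (target exon ≈ 120 bp, minimum 30 bp, at most
8 exons — around the human median exon length, with enough internal exons
to support the requested isoform count), introns uniform 100–500 bp, 500 bp
flanks, and `GT…AG` implanted at every forward-splice boundary plus
`AG`/`GT` at the back-splice acceptor/donor. One locus per chromosome keeps
the ±100 kb verification window equal to the locus and the DP windows
small; nothing in the pipeline depends on it. Multi-isoform circRNAs share
the BSJ and skip distinct non-empty subsets of internal exons; per-isoform
abundances are independent coverage draws (or a fixed ratio split when
`isoform_ratios` is set). Reads are exact walks with optional uniform
substitution errors; qualities are constant `I`; truth tables record every
read's transcript, start offset and insert length.

What the simulator does **not** emulate: real-genome mappability (repeats,
homologous gene families, paralogues), annotation-derived exon structures
including micro-exons, kilobase introns, quality-dependent error profiles,
RNase R efficiency, or linear-transcript contamination beyond an optional
fraction of plain linear fragments. Passing benchmarks on this generator
therefore demonstrates the correctness of the algorithmic chain on faithful
rolling-circle data, not performance on a real genome — on clean synthetic
loci the pipeline reconstructs a somewhat *larger* fraction of isoforms
(around 90% of three-isoform circRNAs at depth 50× in the bundled
benchmark) than the mid-70s percentages reported for comparable designs on
real-genome simulations, whose extra hardness comes precisely from the
features listed above.

## 6. Benchmark problem sizes

The bundled benchmark and reproduction script use 200 three-isoform
circRNAs (≈ 25,000 read pairs) with the internal aligner, 100,000 draws for
the insert-length statistics, 25-circle round-trip and ratio-recovery
designs, and random graphs of ≤ 8 nodes against the brute-force cycle
oracle. These sizes give stable percentages (the two headline rates move by
well under a point between seeds) while keeping a full run in tens of
seconds on one CPU.

## 7. Known limitations

* Single-pair circles whose junction crossings all fall within 19 bases of
  the merged walk's ends are undetectable in principle at score floor 19;
  the round-trip benchmark's eligibility criterion states this exactly.
* Alternative 5'/3' splice sites and intron retention are represented only
  implicitly through cirexon boundaries; overlapping cirexons within one
  BSJ are not modelled.
* The BSJ caller is deliberately minimal (inverted split order + canonical
  flanks + support threshold); it has no statistical multiple-seed model
  and no homologous-gene/repeat filters, which synthetic genomes do not
  need.
* Insert-length inference relies on full-length 3' RO reads; libraries
  whose circles are all much longer than the insert fall back to the
  configured values.
* `estimate_abundance` is a heuristic search; optimality is verified
  exhaustively only on small instances, and with ≥ 4 paths the attained
  minimum may occasionally be local despite the restarts.
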