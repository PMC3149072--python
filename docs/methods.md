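# Methods

This note documents the models and procedures implemented in `protrp`,
the parameters that matter, the numerical and design choices made where
the design was genuinely open, and what the synthetic benchmarks do and
do not demonstrate.

## Tandem-repeat model and detection

A tandem-repeat (TR) domain on a protein is a window `[start, end)` read
as consecutive copies of length `period` (the trailing copy may be
partial), summarized by a column-majority consensus (ties break to the
symbol occurring first reading copies top to bottom). A window
*qualifies* when

* its length is at least `minD` (default 12 residues) and its copy
  number `(end − start)/period` is at least `minC` (default 2),
* every copy matches the consensus in at least `⌈i·len(copy)⌉`
  positions (`i` = 0.7), and
* total matches reach `⌈I·(end − start)⌉` (`I` = 0.8).

Emitted domains are maximal (extending one residue either way breaks a
threshold) and non-overlapping: overlaps are resolved greedily by score
`copy_number × aggregate_identity`, ties going to the longer, then
leftmost, then shortest-period window. These defaults are the standard
parameterization for secretome-scale repeat screens and are exposed in
`TRParams`.

**Search strategy.** Exhaustive window enumeration is cubic and
intractable beyond toy lengths. In any qualifying window, two adjacent
full copies each match the consensus in `≥ ⌈i·p⌉` positions, hence
match each other in `≥ 2⌈i·p⌉ − p` positions. Detection therefore
enumerates *anchors* — positions where `seq[a..a+p)` and
`seq[a+p..a+2p)` reach that bound — groups them into phase-consistent
runs, and evaluates exactly (with an incremental column-count update)
only windows whose copy boundaries lie on a run. This is lossless: the
qualifying-window set equals the brute-force set, which the test suite
verifies against an independently written exhaustive oracle on
thousands of seeded strings.

**Boundary slack.** A re-phased window that absorbs `k ≤ ⌊(1−i)·p⌋`
flanking residues trades `k` mismatches for `k` extra matched positions,
leaving the score unchanged; the longer-window tie-break then prefers
it. Detected boundaries can therefore sit up to that many residues
outside a planted domain while period and coverage remain exact.

**Gaps.** Gap handling is an extension pass: maximal ungapped domains
are extended across insertions/deletions by aligning flanking copies to
the consensus (match-counting alignment, small gap penalty, at most `g`
= 3 consecutive gaps). Insertion columns where the majority of copies
carry a gap appear in the consensus as `-`, so a 10-mer repeat with one
inserted residue models as period 11; `model_period(..., gap_free=True)`
drops gap columns and returns 10, the convention used for periodicity
histograms. The gapped model is adopted only when it scores above the
ungapped one, so clean repeats are never degraded; domains whose
consensus contains a gap are excluded from clustering along with `X`,
stops, and degenerate periods (≤ 3).

## Dipeptide vectors and cyclic frame

Each domain sequence is converted to a 400-entry vector of ordered
adjacent residue-pair counts (no wraparound) divided by the domain
length `L` (entries sum to `(L−1)/L`). Dipeptides capture
adjacent-residue context that single-residue composition misses —
essential for low-complexity repeats — and are nearly phase-invariant,
since rotating a repeat changes at most the boundary pair.

Repeat motifs are equivalence classes under rotation (PVYK = VYKP =
YKPV = KPVY); the lexicographically smallest rotation is the canonical
form used to de-duplicate motifs. Cyclic alignment scores a motif
against every rotation of another (ties to the smallest rotation
index); unequal lengths are compared over the shorter length at every
rotation × offset, a convention chosen because no principled rule
exists for aligning consensus motifs of different periods.

## Ensemble clustering engine

The engine must deliver a flat partition plus a per-pair co-clustering
confidence, deterministically under a fixed seed. It is implemented as
consensus clustering: per iteration it subsamples 80 % of rows (never
fewer than three — a two-row column permutation preserves the pair's
distance and voids the null), links pairs whose distance is at or below
the `p_value` (0.01) quantile of a pooled column-permutation null
(5 replicates), and takes connected components. Confidence(i, j) is the
fraction of co-sampled iterations in which i and j co-clustered; the
final partition connects pairs with confidence ≥ 0.5. The permutation
null is what gives the engine its p-value semantics: identical inputs
collapse to one cluster (null distances are zero), and unstructured
inputs stay apart. Self-organizing-map grid, topology, and cartogram
settings are accepted in `EngineParams` for configuration compatibility
but do not influence this engine.

Distances are Euclidean on the raw length-normalized dipeptide vectors.
Unit-variance column normalization is available as config but off by
default for stage-one clustering: dipeptide count matrices are sparse,
and columns touched only by isolated point mutations have near-zero
variance, so normalizing inflates them by one to two orders of
magnitude — measured on the five-family benchmark, it pushes
within-family distances *above* between-family ones and destroys
recovery.

## Recursive quality control

Compositional clusters are validated at the sequence level. Members are
rotated (and offset) into the cyclic frame maximizing total agreement
with the best-agreeing reference member; the master consensus is the
column majority of that frame; the *consensus error* is the mean
mismatch fraction of members against the master over compared
positions. Members whose individual mismatch fraction exceeds `2E` are
flagged as outliers and removed, the error is recomputed, and the lower
of the two errors decides acceptance (the outlier rule and factor are
this package's choice; only the acceptance thresholds are fixed).

A cluster is emitted when its error meets the applicable threshold:
`E` = 0.4 at the top level, the stricter 0.3 for clusters produced by
recursive re-clustering. Failing clusters are re-clustered (members plus
flagged outliers) with stage-two engine settings; groups that fall
below the minimum size (10) without meeting their threshold disband
into singletons, and a no-progress recursion falls back to a
deterministic bisection before disbanding. Every emitted cluster
therefore satisfies its depth's error bound, and every input motif ends
in exactly one cluster, its removed list, or the singleton list.

## Fuzzy cluster network

Clusters with ≥ 3 members are compared by composition with prolines
removed — Pro dominates every Pro-rich motif and would swamp the
similarity structure. Member consensus motifs are P-stripped,
vectorized, and averaged into one vector per cluster; columns are
unit-variance normalized (constant columns dropped with a warning —
here normalization is part of the published procedure, applied to dense
mean vectors rather than sparse counts); and the ensemble engine runs
with Pearson-correlation distance (all-against-all `1 − r`), 500
iterations, p = 0.01. Edge weights are the engine's confidences
verbatim; edges with confidence below 0.04 are removed (exactly 0.04 is
retained), and nodes isolated by the filter are dropped. Nodes carry
member/protein/species counts, a prominence tier (*large*: ≥ 10 species
and ≥ 20 proteins; *intermediate*: exactly one criterion; *small*:
neither), and the taxonomy retention rate (fraction of members matched
by any class definition). Exports: GraphML, Cytoscape SIF, and a node
attribute TSV.

## Taxonomy, periodicity, backbones

Class definitions use a compact pattern syntax — residue literals,
`[ST]` alternation, `[^P]` negation, `.` wildcard, bounded repetition
`{m,n}`, multi-motif alternation `[AP|ST]`, and a trailing
`and not [HY]` exclusion list that vetoes a match if any listed residue
occurs anywhere in the motif. Patterns compile to standard regular
expressions and are matched inside the doubled consensus (`s + s`
truncated to `2·len − 1`), which exposes every cyclic phase without
enumerating rotations; a config switch matches the stored string only.
Parsing round-trips through a canonical form. The shipped definition
file contains the published T/S-P₃-A expression verbatim plus
definitions for the bundled generator's families, keyed on conserved
proline backbones with wildcarded spacers (multi-class hits are
reported, not suppressed).

Periodicity classes partition the positive integers by `period mod 3`:
0 → *n*, 1 → *n*+1, 2 → *n*−1. On an extended polyproline-II helix,
whose symmetry is trilateral, class-*n* repeats stack side groups in
register while *n*±1 repeats spiral them by 120° per copy — the reason
periodicity is a conserved structural signature of extensin-type
repeats. Histograms are computed on gap-free remodeled periods by
default.

Backbone categories (SPₙ, TPₙ, interspersed P₁, regular P₂,
interspersed P₂/P₁, regular P₂/P₃, interspersed P₂/P₃/P₁, other) are
assigned from the *linear* proline run-length profile and the residues
immediately preceding runs: SPₙ/TPₙ require ≥ 80 % of runs of length
≥ 2 to follow Ser (resp. Thr); otherwise the set of run lengths decides.
Linear (not cyclic) runs are used so an isolated leading and trailing
proline do not fuse into a spurious P₂ block; the 80 % flank threshold
is exposed as a parameter. These rules are this package's own — only the
category inventory is fixed.

## Synthetic data

The generator plants protein families from a base motif: `M` + a
19-residue hydrophobic-core leader (emulating a signal peptide) +
tandem motif copies with i.i.d. per-residue substitutions (default 5 %,
never introducing `X`/`*`) + a background-composition tail. Copy
numbers are drawn from 6–12; the five default motifs (period 8–11,
33–44 % Pro) span extensin-like SPₙ, PRP-like, PELPK-like, and
hybrid-domain architectures, two of them sharing PVYK-type content so
their clusters are compositional neighbours. An optional
`variant_rate` gives each member its own motif variant (proline
backbone conserved), emulating corpora in which nearly every sequence
carries a distinct consensus — without it, de-duplication collapses
each family to one canonical motif and the cluster stage has nothing to
cluster; the end-to-end scenario and the acceptance script use 0.1.
Proteins can be reverse-translated into EST-like nucleotide records
(random synonymous codons, optional stop, per-base error) to exercise
translation and ORF extraction. Decoys are repeat-free background
proteins annotated as non-secreted.

What the benchmarks show: detection agrees exactly with brute force on
small instances; clustering recovers well-separated planted families
(adjusted Rand ≥ 0.9 at 5 % substitution) deterministically. What they
do not show: behaviour on real EST noise (frameshifts, chimeras),
fragmentary ORFs, genuinely ambiguous repeat families, or corpus-scale
cluster counts — those require real sequence corpora. Problem sizes
throughout (150–165 proteins, ~70–150 motifs) were chosen as the
smallest at which every stage, including the network, has non-trivial
structure.

## Numerical and degenerate-input conventions

* Coordinates are 0-based half-open everywhere.
* All "at least"/"minimum" thresholds are inclusive; identity
  thresholds use exact integer ceilings, avoiding float comparisons.
* Stochastic steps derive from a single integer seed via
  `numpy.random.SeedSequence`; reruns are byte-identical.
* Length-1 dipeptide input yields a zero vector (logged); all-proline
  motifs contribute zero vectors to the network (logged); correlation
  distance for constant rows is treated as maximal.
* Outlier removal never empties a cluster below two members; empty
  clusters have no defined retention rate (reported as missing rather
  than zero).
* EST translation renders any `N`-containing codon as `X`, which later
  disqualifies the motif from clustering rather than silently guessing
  a residue.
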