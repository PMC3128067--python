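# Methods

## Problem

Oligonucleotide (probe) design pipelines must discard candidate regions that
could cross-hybridise with sequences similar to the target.  The fast way to
find "similar" is seed-and-filter: index hashed windows of the target and
flag any database position sharing a hash.  The quality of that filter is
set by the seed — which positions of a window are constrained, and how.
`oligoseeds` evaluates seed families (contiguous/BLAST-like, spaced,
transition-constrained, multiple spaced) for this task: it computes seed
sensitivity exactly, detects hits by hashing, generates labelled synthetic
datasets, and scores each seed's accuracy (F-score) and efficiency.

## Seeds and hashing

A seed is a pattern over `{1, *, @}`; its *weight* w is the number of 1s and
its *span* ℓ the pattern length.  The hash of a DNA window keeps the base at
every 1-position and only the purine/pyrimidine class (A,G → R; C,T → Y) at
every @-position.  Key equality is then exactly "match at every 1, match or
transition at every @", so transition-constrained lookups cost a single
probe of one hash table.  Patterns are normalised to start and end with 1.
Windows containing ambiguity codes at constrained positions are skipped
rather than raising.  Note the weight of a transition seed counts only its
1s; programs that count @ as half a match would quote, e.g., the pattern
`1@1**11**1*11@1` as weight 9 where this package reports 8.

## Sensitivity

Alignments are modelled as i.i.d. Bernoulli symbols over N positions: match
with probability p (the *similarity*), else mismatch.  When any seed carries
`@`, the mismatch mass splits into transition (probability q) and
transversion (1 − p − q).  Defaults: q = (1 − p)/2, i.e. half the mismatch
mass, since no canonical split is implied by the model; q is a free
parameter of `AlignmentModel` (transitions are biologically more common
than each single transversion, so callers may want q > (1−p)/2).

`sensitivity_exact` iterates positions 1..N maintaining the probability
distribution of the last (max-span − 1) symbols conditioned on "no hit
yet"; the sensitivity is one minus the surviving mass.  The state space is
2^(ℓ−1) (binary) or 3^(ℓ−1) (ternary, transition seeds); a configurable cap
(default 2^24 states) raises an explicit error rather than approximating
silently — `sensitivity_mc`, a seeded Monte-Carlo with binomial standard
error, is the documented fallback and doubles as the independent oracle in
tests.  Probabilities are accumulated in double precision and rounded only
for presentation (3 decimals in reports).

The expected number of hits of a single seed in the region is
(N − ℓ + 1)·p^w — the quantity that explains why doubling the seed count
(×2 expected hits) beats lowering the weight by one (×1/p ≈ ×4 at p=0.25
per-base coincidence) as a way of buying sensitivity.

## Hit detection

Hits are counted within a group: index every hash of the main sequence per
seed, then count (seed, position) pairs in each secondary whose hash occurs
in the index.  Multiple occurrences of the same hash in the main count
once — the unit is the secondary-side lookup, which is what the efficiency
measure prices.  Only the given strand is scanned by default (the generator
emits same-strand variants); `both_strands=True` additionally scans the
reverse complement, for external FASTA input.

## Synthetic datasets

Each group has a uniform random main (target) sequence of 50 or 70 nt and
n secondaries, each a substitution-only variant at a target identity drawn
uniformly from `identity_range` (default 0.60–0.98).  The substitution
count is round((1 − identity)·L) with round-half-even (computed after
rounding the product to 9 decimals to kill binary-float noise).  No indels:
the hit model, identity and stretch measures are positional, and nothing in
the emulated workflow specifies an indel process.

A secondary is labelled **oligo** (similar; a cross-hybridisation risk)
when ANY of three criteria fires, following the common probe-screening
logic where each criterion alone flags risk:

| criterion | 50-mer | 70-mer |
|---|---|---|
| identity ≥ | 0.85 | 0.85 |
| longest contiguous match run ≥ | 15 bp | 20 bp |
| duplex ΔG°37 ≤ | −30 kcal/mol | −40 kcal/mol |

Duplex stability uses the unified Watson–Crick nearest-neighbour ΔG°37
stack table (10 unique dinucleotide steps, reverse-complement symmetric,
packaged as `data/nn_dG37.json`) plus per-terminus initiation terms.
Mismatches contribute no stacking; each *internal* mismatched position pays
a flat +3.0 kcal/mol loop-opening/strain penalty (terminal mismatches act
as dangling ends).  The penalty magnitude is the scale of internal-loop
initiation in standard nearest-neighbour models, and it places the −30/−40
thresholds at the ~0.85–0.87 identity level in both regimes — concordant
with the identity criterion, as a screening rule should be.  Without it
(pure stack-sum), duplexes with 30% scattered mismatches still score −30
kcal/mol because every two-base matched island is credited with full
cooperative stacking; that variant makes the free-energy criterion subsume
the other two and is not physically defensible.  Sequence-specific mismatch
stacks, salt/temperature corrections, melting temperature and hairpin
screening are out of scope; the thresholds are configurable to absorb
residual model bias.

Groups are rejection-balanced (regenerated until both labels occur;
capped).  Per-group RNG streams derive from (master seed, dataset index,
group index), so generation is reproducible and order-independent.
Defaults: 3 datasets × 50 groups × 20 secondaries per regime — desk-scale
replicates of the original six-dataset (three per regime) design.

What the generator does **not** emulate: real transcript/genome targets
(composition bias, repeats), indels, transition/transversion bias
(substitutions are uniform over the three alternatives), and cross-group
similarity.  Passing ranking tests therefore show that the evaluation
framework discriminates seed families under controlled similarity
structure, not that the absolute F-scores transfer to any particular
organism's sequence set.

## Accuracy and efficiency

Over all secondaries of a dataset, with "positive" = hit by the seed set:
TP (oligos hit), FP (non-oligos hit), TN, FN; precision P = TP/(TP+FP),
recall R = TP/(TP+FN); **accuracy** is the F-score 2PR/(P+R), and
**efficiency** E = TP/H where H is the total hit count over all
secondaries (E ≤ P always).  Zero denominators yield *undefined* (None/NaN)
rather than 0, and such rows are excluded from rankings, so degenerate
seeds cannot win sweeps spuriously.

`sweep` evaluates a catalogue of seed sets over datasets;
`best_accuracy` reports, per seed type, the weight maximising the mean F
across datasets with the sample standard deviation over datasets (the
replication axis) — ties break toward the lower weight, which is the
cheaper hash.  `bounded_recall` re-ranks under recall ≥ x for
x ∈ {0.86, …, 0.99}: probe screening wants to miss almost no similar
sequence, so accuracy at bounded recall is the operationally relevant
ranking.

## Seed design and the packaged catalogues

Optimal single seeds are found exhaustively (all patterns of a weight up to
a span cap; ties to the lexicographically smallest).  Multiple seeds are
designed by hill-climbing on *overlap complexity* — the sum over ordered
seed pairs and relative shifts of 2^(#coinciding 1s), a cheap surrogate for
redundant coverage; lower is better — with random restarts scored by exact
DP sensitivity; the best-scoring set is kept.  Transition-constrained
single seeds place 2 `@` characters exhaustively on the winning 1-skeleton,
scored by the ternary DP where feasible and by seeded Monte-Carlo beyond
the state cap.  Sets of transition seeds are deliberately not designed.

The shipped catalogues (`data/catalog/{50mer,70mer}/`) hold, for each
weight 7–20: the contiguous seed (generated on demand), a transition seed
(w 1s + 2 @), and 1-, 2-, 4-, 8- and 16-seeds, designed once at N = oligo
length, p = 0.85 (the identity screening level), span ≤ min(w+7, 22), with
restarts 16/10/6/4/3 for k = 1/2/4/8/16 and a fixed seed;
`scripts/build_catalog.py` regenerates them bit-identically.  Evaluation
sweeps only load these files; they never design seeds on the fly.

## Numerical and degenerate-input choices

* DP state cap 2^24 with an explicit error naming `sensitivity_mc`.
* Regions shorter than the longest span are an error, not sensitivity 0.
* Seeds longer than the main sequence contribute an empty index (logged).
* Confusion-count invariants (H ≥ TP+FP, non-negativity) are enforced at
  construction.
* Evaluation tables carry NaN for undefined metrics; aggregations drop
  them with a log note.

## A structural property of substitution-only benchmarks

Because variants are indel-free and positional, the stretch criterion and
the contiguous seed of weight equal to the stretch threshold are two views
of the same event: a secondary labelled oligo for its ≥ 15 bp (or 20 bp)
run of matches necessarily shares an exact 15-mer (20-mer) with its
target, and a non-oligo never does.  That contiguous seed therefore
classifies the stretch-labelled subclass with precision ≈ 1, and since few
substitutions leave long clean gaps with high probability (at identity
0.9, a 50-mer variant carries a ≥ 15 bp stretch ~80% of the time), the
subclass is large whenever the identity distribution has mass well above
the identity threshold.  On such data, raw best-accuracy rankings flatter
contiguous seeds relative to evaluations on data whose variation process
(indels, clustered or spread mutations) breaks long exact matches.  The
bounded-recall ranking and the efficiency comparison are less affected:
spaced and transition seeds remain more efficient than contiguous ones at
their best weights on the default datasets.  Conclusions about seed
*types* drawn from this generator should be read with that coupling in
mind.

## Known limitations

* The ternary DP state space limits exact transition-seed sensitivity to
  spans ≤ ~16; longer transition seeds fall back to Monte-Carlo in design.
* The duplex model is a screening heuristic, not a hybridisation
  predictor; absolute ΔG values should not be quoted outside the
  classifier.
* Hill-climbed catalogues are good, not provably optimal (k ≥ 2 optimality
  is out of reach by design); rankings across seed *types* are robust to
  this, per-weight values less so.
* Accuracy differences between large seed sets (8- vs 16-seed) are small
  and can invert between regenerated replicates, matching their shrinking
  gaps in the underlying sensitivity curves.
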