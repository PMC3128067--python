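# oligoseeds

Seed-quality evaluation for oligonucleotide design.

Probe-design pipelines filter out candidate oligos that risk
cross-hybridisation by a seed-and-filter scan: hash the constrained
positions of every window of the target, and flag any other sequence
sharing a hash.  How good that filter is depends entirely on the seed.
`oligoseeds` is a framework for measuring seed quality for this task.  It
implements:

* **Seeds** over `{1, *, @}` — contiguous (BLAST-like, e.g. `11111111111`),
  spaced (e.g. `111*1**1*1**11*111`), transition-constrained (`@` = match
  or A↔G / C↔T transition, hashed via the purine/pyrimidine classes R/Y),
  and multiple spaced seeds (k-seeds, one hash table per member).
* **Exact sensitivity** under the Bernoulli alignment model: the
  probability that a seed set hits a random region of length N with
  per-position match probability p, by dynamic programming over the last
  (span−1) alignment symbols, plus a seeded Monte-Carlo estimator and the
  expected-hit-count formula (N − ℓ + 1)·p^w.
* **Hit detection** between a group's main (target) sequence and its
  secondary sequences via per-seed hash indexes.
* **Synthetic datasets** emulating probe-screening benchmarks: groups of
  one random target plus substitution variants, labelled oligo /
  non-oligo by identity (≥ 0.85), contiguous-match stretch (≥ 15 bp /
  20 bp) and nearest-neighbour duplex free energy (≤ −30 / −40 kcal/mol)
  for the 50-mer / 70-mer regimes.
* **Evaluation**: precision P = TP/(TP+FP), recall R = TP/(TP+FN),
  accuracy = F-score 2PR/(P+R), efficiency E = TP/H (H = all hits in all
  secondaries); weight sweeps, per-type best accuracy with across-dataset
  standard deviations, and rankings under lower bounds on recall.
* **Seed design**: exhaustive optimal single seeds, and
  overlap-complexity hill climbing with DP-sensitivity selection for
  multiple seeds; pre-designed catalogues for both regimes (weights 7–20,
  k ∈ {1, 2, 4, 8, 16} and transition seeds) ship with the package.

See `docs/methods.md` for the model details and design choices.

## Worked example

Sensitivity of the classic weight-11 seeds on a random region of length 64
at similarity 0.7:

```sh
$ printf '11111111111\n' > blast.seeds
$ printf '111*1**1*1**11*111\n' > ph.seeds
$ oligoseeds sensitivity --seeds blast.seeds --n 64 --p 0.7
0.300
$ oligoseeds sensitivity --seeds ph.seeds --n 64 --p 0.7
0.467
```

Eleven consecutive matches are found in only 30% of such regions; spacing
the same eleven constrained positions optimally raises that to 46.7%
without any extra hashing cost — the reason spaced seeds displaced
contiguous ones in similarity search.

End-to-end evaluation on generated data (scaled down here for speed):

```sh
$ oligoseeds generate --length 50 --n-groups 10 --n-secondaries 10 \
      --n-datasets 2 --rng-seed 7 --out data
wrote data/50mer-d0
wrote data/50mer-d1
$ oligoseeds evaluate --dataset data/50mer-d0 --dataset data/50mer-d1 \
      --regime 50mer --weights 10:12 --max-k 4 --out sweep.tsv
wrote sweep.tsv (30 rows)
```

`sweep.tsv` has one row per (seed type, weight, dataset) with the
confusion counts and all four metrics; e.g. (columns abridged, values to 3
decimals)

```
seed_type  weight  dataset   precision  recall  fscore  efficiency
1-seed     11      50mer-d0  0.609      0.975   0.750   0.083
```

— at weight 11 the spaced seed still finds 97.5% of the truly similar
sequences while 61% of everything it flags is truly similar, and it spends
about 12 hash hits per detected oligo (E = 0.083).  `oligoseeds rank`
turns a sweep into the per-type best-accuracy table and the
accuracy-under-bounded-recall table.  At realistic scale (3 datasets of
50 groups × 20 secondaries per regime, weights 9–18) the spaced and
transition-constrained single seeds beat contiguous seeds on efficiency at
their best weights, and within the multiple-seed family accuracy grows
with k over most of the weight range.  One caveat is inherent to this
generator and discussed in `docs/methods.md`: because variants are
substitution-only, every sequence labelled similar by the
contiguous-stretch criterion shares an exact threshold-length word with
its target, which the contiguous seed of exactly that weight detects with
precision ≈ 1 — so on these synthetic datasets contiguous seeds rank far
better on raw accuracy than they do on data whose variation process also
breaks long exact matches.

Designing a 4-seed of weight 10 for 50-mers at the 0.85 identity level:

```sh
$ oligoseeds design --k 4 --weight 10 --n 50 --p 0.85 --rng-seed 1 --out my4.seeds
sensitivity 0.997
```

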