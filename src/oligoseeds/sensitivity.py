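"""Seed sensitivity under the Bernoulli alignment model.

An alignment of length N is a random string of per-position outcomes: with
probability p a match, otherwise a mismatch.  When transition-constrained
seeds are involved the mismatch mass is split into transitions (probability q)
and transversions (1 - p - q).  A seed hits at a position when every 1 aligns
to a match and every @ to a match or transition; a k-seed hits when any
member hits anywhere in the region.  *Sensitivity* is the probability of at
least one hit.

``sensitivity_exact`` runs a dynamic program over the distribution of the
last (max_span - 1) alignment symbols conditioned on "no hit yet"; the answer
is one minus the surviving mass.  ``sensitivity_mc`` is the Monte-Carlo
fallback/oracle for state spaces the DP cannot hold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .seeds import Seed, SeedSet

#: Largest DP state count attempted before demanding Monte-Carlo.
DEFAULT_STATE_CAP = 2**24


class StateSpaceError(ValueError):
    """DP state space exceeds the cap; use sensitivity_mc instead."""


@dataclass(frozen=True)
class AlignmentModel:
    """Bernoulli model of a random alignment region.

    Parameters
    ----------
    region_length : int
        N, the number of alignment positions.
    similarity : float
        p, per-position match probability.
    transition_prob : float or None
        q, per-position transition probability; only consulted when a seed
        contains ``@``.  ``None`` means the default split q = (1 - p) / 2
        (one transition partner vs two transversion partners is *not*
        assumed; half the mismatch mass is a neutral default).
    """

    region_length: int
    similarity: float
    transition_prob: float | None = None

    def __post_init__(self) -> None:
        if self.region_length < 1:
            raise ValueError("region_length must be >= 1")
        if not 0.0 <= self.similarity <= 1.0:
            raise ValueError("similarity p must be in [0, 1]")
        q = self.q
        if not 0.0 <= q <= 1.0 - self.similarity + 1e-12:
            raise ValueError("transition_prob q must satisfy 0 <= q <= 1 - p")

    @property
    def p(self) -> float:
        return self.similarity

    @property
    def q(self) -> float:
        if self.transition_prob is None:
            return (1.0 - self.similarity) / 2.0
        return self.transition_prob


def _as_set(seeds: Seed | SeedSet) -> SeedSet:
    if isinstance(seeds, Seed):
        return SeedSet((seeds,))
    return seeds


def _seed_requirements(seed: Seed, alphabet: int) -> list[tuple[int, int]]:
    """(offset-from-newest, minimum symbol) pairs a hit must satisfy.

    Symbols are ordered by stringency: binary 0=mismatch, 1=match; ternary
    0=transversion, 1=transition, 2=match.  A ``1`` needs the top symbol, an
    ``@`` needs at least a transition.
    """
    reqs = []
    for j, ch in enumerate(seed.pattern):
        off = seed.span - 1 - j
        if ch == "1":
            reqs.append((off, alphabet - 1))
        elif ch == "@":
            reqs.append((off, 1))
    return reqs


def _hit_masks(seedset: SeedSet, alphabet: int, span: int) -> list[np.ndarray]:
    """For each incoming symbol b, boolean over states: does appending b to
    the state's suffix complete a hit of any seed at the current position?

    A state encodes the last (span - 1) symbols in base ``alphabet``, most
    significant symbol oldest; zero-padding at the start of the region is
    safe because symbol 0 satisfies no constraint.
    """
    n_states = alphabet ** (span - 1)
    states = np.arange(n_states, dtype=np.int64)
    masks = []
    for b in range(alphabet):
        word = states * alphabet + b  # last `span` symbols
        hit = np.zeros(n_states, dtype=bool)
        for seed in seedset:
            ok = np.ones(n_states, dtype=bool)
            for off, need in _seed_requirements(seed, alphabet):
                digit = (word // alphabet**off) % alphabet
                ok &= digit >= need
            hit |= ok
        masks.append(hit)
    return masks


def sensitivity_exact(
    seeds: Seed | SeedSet,
    model: AlignmentModel,
    state_cap: int = DEFAULT_STATE_CAP,
) -> float:
    """Exact probability that the seed set hits the random region.

    Dynamic program over positions 1..N whose state is the suffix of the last
    (max_span - 1) alignment symbols, conditioned on no hit so far.  Binary
    alphabet {mismatch, match} without ``@`` seeds; ternary {transversion,
    transition, match} with them.

    Raises
    ------
    ValueError
        If the region is shorter than the longest span.
    StateSpaceError
        If the state space exceeds ``state_cap``.
    """
    seedset = _as_set(seeds)
    span = seedset.max_span
    N = model.region_length
    if N < span:
        raise ValueError(f"region length {N} shorter than max seed span {span}")
    alphabet = 3 if seedset.has_transitions else 2
    n_states = alphabet ** (span - 1)
    if n_states > state_cap:
        raise StateSpaceError(
            f"{alphabet}^{span - 1} = {n_states} DP states exceed cap {state_cap}; "
            "use sensitivity_mc"
        )
    p = model.p
    if alphabet == 2:
        probs = [1.0 - p, p]
    else:
        q = model.q
        probs = [1.0 - p - q, q, p]

    masks = _hit_masks(seedset, alphabet, span)
    # next state after appending symbol b: drop the oldest symbol
    states = np.arange(n_states, dtype=np.int64)
    nexts = [(states * alphabet + b) % n_states for b in range(alphabet)]

    v = np.zeros(n_states)
    v[0] = 1.0
    for _ in range(N):
        new = np.zeros(n_states)
        for b in range(alphabet):
            if probs[b] == 0.0:
                continue
            surv = v * probs[b]
            surv[masks[b]] = 0.0
            new += np.bincount(nexts[b], weights=surv, minlength=n_states)
        v = new
    return float(min(1.0, max(0.0, 1.0 - v.sum())))


@dataclass(frozen=True)
class MCEstimate:
    """Monte-Carlo sensitivity estimate with its binomial standard error."""

    value: float
    stderr: float
    trials: int

    def __float__(self) -> float:  # pragma: no cover - convenience
        return self.value


def _simulate_regions(model: AlignmentModel, ternary: bool, trials: int,
                      rng: np.random.Generator) -> np.ndarray:
    N = model.region_length
    if ternary:
        q = model.q
        probs = [1.0 - model.p - q, q, model.p]
        return rng.choice(3, size=(trials, N), p=probs).astype(np.int8)
    return (rng.random((trials, N)) < model.p).astype(np.int8) * 2  # 0 or 2 = match


def _hits_per_region(seedset: SeedSet, regions: np.ndarray) -> np.ndarray:
    """Number of (seed, position) hits in each simulated region.

    Regions use the ternary symbol scale (0 transversion, 1 transition,
    2 match) regardless of how they were simulated.
    """
    trials, N = regions.shape
    counts = np.zeros(trials, dtype=np.int64)
    for seed in seedset:
        reqs = [(j, 2 if ch == "1" else 1)
                for j, ch in enumerate(seed.pattern) if ch != "*"]
        for i in range(N - seed.span + 1):
            ok = np.ones(trials, dtype=bool)
            for j, need in reqs:
                ok &= regions[:, i + j] >= need
            counts += ok
    return counts


def sensitivity_mc(
    seeds: Seed | SeedSet,
    model: AlignmentModel,
    trials: int = 100_000,
    rng_seed: int = 0,
) -> MCEstimate:
    """Monte-Carlo sensitivity: fraction of simulated regions hit."""
    if trials < 1:
        raise ValueError("trials must be >= 1")
    seedset = _as_set(seeds)
    if model.region_length < seedset.max_span:
        raise ValueError("region shorter than max seed span")
    rng = np.random.default_rng(rng_seed)
    regions = _simulate_regions(model, seedset.has_transitions, trials, rng)
    hit_frac = float((_hits_per_region(seedset, regions) > 0).mean())
    stderr = math.sqrt(hit_frac * (1.0 - hit_frac) / trials)
    return MCEstimate(hit_frac, stderr, trials)


def expected_hits(seed: Seed, model: AlignmentModel) -> float:
    """Expected number of hits of a single seed in the random region:
    (N - l + 1) * p^w, since each of the N - l + 1 placements hits with
    probability p^w."""
    N, span = model.region_length, seed.span
    if N < span:
        raise ValueError(f"region length {N} shorter than seed span {span}")
    return (N - span + 1) * model.p**seed.weight
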