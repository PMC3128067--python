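"""Seed construction.

Single seeds of usable weight can be optimised exhaustively: enumerate every
pattern of the given weight (first/last character 1) up to a span cap and
keep the sensitivity-maximising one.  For multiple seeds even k = 2 is
infeasible exhaustively, so ``design_multi`` hill-climbs on *overlap
complexity* — a cheap surrogate for how redundantly a set of seeds covers
alignments (sum over ordered seed pairs and relative shifts of
2^(#coinciding 1s)); lower is better — and keeps, over random restarts, the
candidate set with the highest dynamic-programming sensitivity.

Transition-constrained single seeds (patterns with ``@``) are designed by
augmenting the 1-skeleton search with exhaustive placement of the @
characters; sets of transition seeds are deliberately not designed here.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .seeds import Seed, SeedSet
from .sensitivity import (DEFAULT_STATE_CAP, AlignmentModel, StateSpaceError,
                          sensitivity_exact, sensitivity_mc)

logger = logging.getLogger(__name__)

#: Spans above this make the exhaustive search / binary DP unreasonable.
SPAN_CAP = 22


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of a multiple-seed design run."""

    k: int
    weight: int
    max_span: int
    model: AlignmentModel
    rng_seed: int = 0
    restarts: int = 20
    n_transitions: int = 0
    mc_trials: int = 30_000
    state_cap: int = DEFAULT_STATE_CAP

    def __post_init__(self) -> None:
        if self.k < 1 or self.weight < 1:
            raise ValueError("k and weight must be >= 1")
        if self.weight > self.max_span:
            raise ValueError("weight exceeds max_span")
        if self.max_span > SPAN_CAP:
            raise ValueError(f"max_span {self.max_span} exceeds cap {SPAN_CAP}")
        if self.n_transitions and self.k != 1:
            raise ValueError(
                "transition-constrained design is supported for single seeds only"
            )


def _ones_mask(pattern: str) -> int:
    mask = 0
    for i, ch in enumerate(pattern):
        if ch == "1":
            mask |= 1 << i
    return mask


def _oc_pair(ma: int, la: int, mb: int, lb: int) -> int:
    """Overlap-complexity contribution of the ordered pair (a, b): over every
    relative shift with at least one overlapping position, 2^(#coinciding 1s)."""
    total = 0
    for t in range(0, la):
        total += 1 << ((ma & (mb << t)).bit_count())
    for t in range(1, lb):
        total += 1 << (((ma << t) & mb).bit_count())
    return total


def overlap_complexity(seeds: SeedSet) -> int:
    """Sum over ordered seed pairs and all overlapping shifts of
    2^(#positions where two 1s coincide); only 1s count, ``@`` and ``*`` do
    not."""
    reps = [(_ones_mask(s.pattern), s.span) for s in seeds]
    return sum(_oc_pair(ma, la, mb, lb) for ma, la in reps for mb, lb in reps)


def _set_sensitivity(seedset: SeedSet, spec: DesignSpec) -> float:
    """Exact DP sensitivity, falling back to seeded Monte-Carlo when the
    state space is out of reach (long transition seeds)."""
    try:
        return sensitivity_exact(seedset, spec.model, state_cap=spec.state_cap)
    except StateSpaceError:
        est = sensitivity_mc(seedset, spec.model, trials=spec.mc_trials,
                             rng_seed=spec.rng_seed + 987_654)
        return est.value


def _candidate_patterns(weight: int, span: int):
    """All patterns of given weight and exact span, first/last char 1."""
    if weight > span:
        return
    if weight == 1:
        if span == 1:
            yield "1"
        return
    interior = span - 2
    for ones in itertools.combinations(range(interior), weight - 2):
        mid = ["*"] * interior
        for i in ones:
            mid[i] = "1"
        yield "1" + "".join(mid) + "1"


def optimal_single_seed(
    weight: int,
    max_span: int,
    model: AlignmentModel,
    n_transitions: int = 0,
) -> tuple[Seed, float]:
    """Exhaustively optimal single seed for the model.

    Enumerates every pattern of the given weight with span in
    [weight, max_span]; with ``n_transitions`` > 0, additionally places that
    many ``@`` characters at don't-care positions.  Ties break to the
    lexicographically smallest pattern.  Returns (seed, sensitivity).
    """
    if max_span > SPAN_CAP:
        raise ValueError(f"max_span {max_span} exceeds cap {SPAN_CAP}")
    if model.region_length < max_span:
        raise ValueError("model region shorter than max_span")
    best: tuple[float, str] | None = None
    for span in range(weight, max_span + 1):
        for pat in _candidate_patterns(weight, span):
            for full in _place_transitions(pat, n_transitions):
                sens = sensitivity_exact(Seed(full), model)
                key = (-sens, full)
                if best is None or key < best:
                    best = key
    if best is None:
        raise ValueError("no candidate pattern exists for this weight/span")
    return Seed(best[1]), -best[0]


def _place_transitions(pattern: str, n_at: int):
    if n_at == 0:
        yield pattern
        return
    stars = [i for i, c in enumerate(pattern) if c == "*"]
    for combo in itertools.combinations(stars, n_at):
        chars = list(pattern)
        for i in combo:
            chars[i] = "@"
        yield "".join(chars)


def _random_pattern(weight: int, span: int, rng: np.random.Generator) -> str:
    if weight == span:
        return "1" * weight
    interior = span - 2
    ones = rng.choice(interior, size=weight - 2, replace=False)
    mid = ["*"] * interior
    for i in ones:
        mid[i] = "1"
    return "1" + "".join(mid) + "1"


def _hill_climb(patterns: list[str], rng: np.random.Generator,
                stall_limit: int = 400) -> list[str]:
    """Swap an interior 1 with an interior * inside one seed while the swap
    strictly lowers the set's overlap complexity; stop after ``stall_limit``
    consecutive failed proposals.  Works on 1-position bitmasks and only
    re-evaluates pairs involving the mutated seed."""
    k = len(patterns)
    spans = [len(p) for p in patterns]
    masks = [_ones_mask(p) for p in patterns]

    def seed_cost(i: int, mi: int) -> int:
        # ordered pairs touching seed i, with seed i's mask replaced by mi
        cost = _oc_pair(mi, spans[i], mi, spans[i])
        for j in range(k):
            if j != i:
                cost += _oc_pair(mi, spans[i], masks[j], spans[j])
                cost += _oc_pair(masks[j], spans[j], mi, spans[i])
        return cost

    stall = 0
    while stall < stall_limit:
        i = int(rng.integers(k))
        m, span = masks[i], spans[i]
        interior = range(1, span - 1)
        ones = [j for j in interior if m >> j & 1]
        stars = [j for j in interior if not (m >> j & 1) and patterns[i][j] == "*"]
        if not ones or not stars:
            break
        a = ones[int(rng.integers(len(ones)))]
        b = stars[int(rng.integers(len(stars)))]
        new_m = (m & ~(1 << a)) | (1 << b)
        if any(new_m == masks[j] and spans[j] == span for j in range(k) if j != i):
            stall += 1
            continue
        if seed_cost(i, new_m) < seed_cost(i, m):
            masks[i] = new_m
            chars = list(patterns[i])
            chars[a], chars[b] = "*", "1"
            patterns[i] = "".join(chars)
            stall = 0
        else:
            stall += 1
    return patterns


def design_multi(spec: DesignSpec) -> tuple[SeedSet, float]:
    """Overlap-complexity hill-climbing design of a k-seed.

    Each restart draws k random patterns of the spec'd weight and span,
    hill-climbs to a local overlap-complexity minimum, and scores the set by
    DP sensitivity; the best-scoring set over all restarts wins.
    Reproducible from ``rng_seed``.  Returns (seed set, sensitivity).
    """
    rng = np.random.default_rng(spec.rng_seed)
    span = spec.max_span
    best_set: SeedSet | None = None
    best_sens = -1.0
    for _ in range(spec.restarts):
        patterns: list[str] = []
        attempts = 0
        while len(patterns) < spec.k:
            pat = _random_pattern(spec.weight, span, rng)
            if pat not in patterns:
                patterns.append(pat)
            attempts += 1
            if attempts > 100 * spec.k:
                raise RuntimeError(
                    f"cannot draw {spec.k} distinct patterns of weight "
                    f"{spec.weight}, span {span}"
                )
        patterns = _hill_climb(patterns, rng)
        candidate = SeedSet(tuple(Seed(p) for p in patterns))
        sens = _set_sensitivity(candidate, spec)
        if sens > best_sens:
            best_set, best_sens = candidate, sens
    assert best_set is not None
    if spec.n_transitions:
        # place the @ characters on the winning 1-skeleton
        best_set, best_sens = _best_transition_placement(
            best_set.seeds[0].pattern, spec
        )
    return best_set, best_sens


def _best_transition_placement(pattern: str, spec: DesignSpec) -> tuple[SeedSet, float]:
    best_set, best_sens = None, -1.0
    for full in _place_transitions(pattern, spec.n_transitions):
        cand = SeedSet((Seed(full),))
        sens = _set_sensitivity(cand, spec)
        if sens > best_sens:
            best_set, best_sens = cand, sens
    if best_set is None:
        raise ValueError(
            f"pattern {pattern!r} has fewer than {spec.n_transitions} don't-care "
            "positions to convert to '@'"
        )
    return best_set, best_sens
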