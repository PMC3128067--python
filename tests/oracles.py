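"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's DP / hash-index code paths: the
sensitivity oracle enumerates every binary (or ternary) region outright, and
the hit oracle compares raw windows character by character.
"""

from __future__ import annotations

import itertools

import numpy as np

from oligoseeds.seeds import Seed, SeedSet

_TRANSITION = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def sensitivity_brute_binary(seeds: SeedSet, N: int, p: float) -> float:
    """Sum p^m (1-p)^(N-m) over every binary region that any seed hits."""
    regions = np.arange(1 << N, dtype=np.uint64)
    hit = np.zeros(regions.shape, dtype=bool)
    for seed in seeds:
        mask = 0
        for j, ch in enumerate(seed.pattern):
            if ch == "1":
                mask |= 1 << j
        for i in range(N - seed.span + 1):
            m = np.uint64(mask << i)
            hit |= (regions & m) == m
    matches = np.bitwise_count(regions[hit])
    return float(np.sum(p ** matches.astype(float) * (1 - p) ** (N - matches.astype(float))))


def sensitivity_brute_ternary(seeds: SeedSet, N: int, p: float, q: float) -> float:
    """Enumerate all 3^N regions (0 transversion, 1 transition, 2 match)."""
    probs = {0: 1 - p - q, 1: q, 2: p}
    total = 0.0
    for region in itertools.product((0, 1, 2), repeat=N):
        hit = False
        for seed in seeds:
            for i in range(N - seed.span + 1):
                ok = True
                for j, ch in enumerate(seed.pattern):
                    sym = region[i + j]
                    if ch == "1" and sym != 2:
                        ok = False
                        break
                    if ch == "@" and sym == 0:
                        ok = False
                        break
                if ok:
                    hit = True
                    break
            if hit:
                break
        if hit:
            prob = 1.0
            for sym in region:
                prob *= probs[sym]
            total += prob
    return total


def window_compatible(seed: Seed, wa: str, wb: str) -> bool:
    """Would the two windows produce equal hashes under the seed?"""
    for ch, a, b in zip(seed.pattern, wa.upper(), wb.upper()):
        if ch == "*":
            continue
        if a not in "ACGT" or b not in "ACGT":
            return False
        if ch == "1" and a != b:
            return False
        if ch == "@" and a != b and (a, b) not in _TRANSITION:
            return False
    return True


def count_hits_brute(seeds: SeedSet, main: str, secondary: str) -> int:
    """All (seed, j) pairs where some window of main is hash-equal to the
    secondary's window at j (multiple main positions count once)."""
    total = 0
    for seed in seeds:
        for j in range(len(secondary) - seed.span + 1):
            wb = secondary[j : j + seed.span]
            if any(
                window_compatible(seed, main[i : i + seed.span], wb)
                for i in range(len(main) - seed.span + 1)
            ):
                total += 1
    return total


def expected_hits_mc(seed: Seed, N: int, p: float, trials: int, seed_rng: int) -> float:
    """Monte-Carlo mean hit count of a single seed in binary regions."""
    rng = np.random.default_rng(seed_rng)
    mask = [j for j, ch in enumerate(seed.pattern) if ch == "1"]
    regions = rng.random((trials, N)) < p
    count = 0
    for i in range(N - seed.span + 1):
        count += regions[:, [i + j for j in mask]].all(axis=1).sum()
    return count / trials
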