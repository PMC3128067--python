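"""Hash-table hit detection between a main sequence and its secondaries.

A *hit* of a seed in a secondary sequence is a position j such that the
seed's hash at j also occurs at some position of the main sequence.  The
counting unit is the (seed, secondary-position) pair: multiple occurrences of
the same hash in the main sequence count once, matching the lookup-cost
semantics the efficiency measure captures.

Groups mirror the evaluation substrate: one main (target) sequence and a
list of labelled secondaries (oligo = similar, non-oligo = not similar), all
of the same length.  Hits are computed within a group only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .seeds import Seed, SeedSet, encode_dna, packed_keys

logger = logging.getLogger(__name__)

Label = Literal["oligo", "non-oligo"]
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class OligoGroup:
    """One main (target) sequence plus labelled secondary sequences."""

    main: str
    secondaries: tuple[tuple[str, Label], ...]

    def __post_init__(self) -> None:
        if not self.main:
            raise ValueError("main sequence is empty")
        if not self.secondaries:
            raise ValueError("a group needs at least one secondary sequence")
        object.__setattr__(self, "secondaries", tuple(self.secondaries))
        for i, (seq, label) in enumerate(self.secondaries):
            if len(seq) != len(self.main):
                raise ValueError(
                    f"secondary {i} length {len(seq)} != main length {len(self.main)}"
                )
            if label not in ("oligo", "non-oligo"):
                raise ValueError(f"secondary {i}: unknown label {label!r}")

    @property
    def labels(self) -> tuple[Label, ...]:
        return tuple(lab for _, lab in self.secondaries)


@dataclass(frozen=True)
class HitReport:
    """Per-secondary hit flags/counts and the group's total hit count H."""

    per_secondary: tuple[tuple[bool, int], ...]

    @property
    def total_hits(self) -> int:
        return sum(c for _, c in self.per_secondary)

    @property
    def hit_flags(self) -> tuple[bool, ...]:
        return tuple(h for h, _ in self.per_secondary)


class SeedIndex:
    """Per-seed sets of hash keys occurring anywhere in the main sequence."""

    def __init__(self, seeds: SeedSet, key_sets: list[set[int]]):
        self.seeds = seeds
        self.key_sets = key_sets


def build_index(seeds: SeedSet, main: str) -> SeedIndex:
    """Index the main sequence: for each seed, the set of packed hash keys at
    every hashable window position.  Seeds longer than the main sequence
    contribute an empty key set (warning logged)."""
    if not main:
        raise ValueError("main sequence is empty")
    codes = encode_dna(main)
    key_sets: list[set[int]] = []
    any_window = False
    for seed in seeds:
        keys, valid = packed_keys(seed, codes)
        key_sets.append(set(keys[valid].tolist()))
        any_window = any_window or keys.size > 0
    if not any_window:
        logger.warning(
            "main sequence (length %d) shorter than every seed span; empty index",
            len(main),
        )
    return SeedIndex(seeds, key_sets)


def count_hits(
    index: SeedIndex, seeds: SeedSet, secondary: str, both_strands: bool = False
) -> tuple[bool, int]:
    """Count (seed, position) hits of the indexed main in ``secondary``.

    ``both_strands`` additionally scans the reverse complement of the
    secondary (off by default: the generator emits same-strand variants).
    """
    if seeds is not index.seeds:
        # allow equal-by-value sets built separately
        if [s.pattern for s in seeds] != [s.pattern for s in index.seeds]:
            raise ValueError("index was built from a different seed set")
    strands = [secondary]
    if both_strands:
        strands.append(reverse_complement(secondary))
    total = 0
    for strand in strands:
        codes = encode_dna(strand)
        for seed, key_set in zip(seeds, index.key_sets):
            if not key_set:
                continue
            keys, valid = packed_keys(seed, codes)
            for k, ok in zip(keys.tolist(), valid.tolist()):
                if ok and k in key_set:
                    total += 1
    return total >= 1, total


def group_hits(seeds: SeedSet, group: OligoGroup, both_strands: bool = False) -> HitReport:
    """Hit flags and counts for every secondary of a group, order preserved."""
    index = build_index(seeds, group.main)
    per = tuple(
        count_hits(index, seeds, seq, both_strands=both_strands)
        for seq, _ in group.secondaries
    )
    return HitReport(per)
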