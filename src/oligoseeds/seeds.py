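"""Seed patterns and hashing.

A *seed* is a pattern over ``{1, *, @}``: a ``1`` requires a base match, a
``*`` is a don't-care, and a ``@`` (transition-constrained position) requires
the aligned bases to be equal or to differ by a transition (A<->G, C<->T).
The number of 1s is the seed's *weight* w and the total character count its
*span* (length) l.  A *k-seed* is an ordered set of k such patterns; it hits
wherever any member hits.

The *hash* of a DNA window under a seed is the projection of the window onto
the seed's constrained positions: 1-positions keep the base, @-positions keep
only the purine/pyrimidine class (A,G -> R; C,T -> Y).  Two windows have equal
hashes exactly when every 1-position matches and every @-position matches or
is a transition pair — so transition-constrained hits cost a single hash
lookup, no neighbour enumeration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

SEED_ALPHABET = frozenset("1*@")

#: Base encoding used throughout: A=0, C=1, G=2, T=3; 4 marks anything else
#: (ambiguity codes), which makes a window unhashable at constrained positions.
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_CODE_BASE = "ACGT"
#: Purine/pyrimidine class: A,G (codes 0,2) -> R; C,T (codes 1,3) -> Y.
_CLASS_CHAR = "RY"


class SeedError(ValueError):
    """Invalid seed pattern or seed file."""


@dataclass(frozen=True)
class Seed:
    """A single seed pattern over ``{1, *, @}``.

    Attributes
    ----------
    pattern : str
        The pattern, normalised to start and end with ``1``.
    weight : int
        Number of ``1`` characters.
    span : int
        Total number of characters (the seed length l).
    """

    pattern: str
    weight: int = field(default=-1)
    span: int = field(default=-1)

    def __post_init__(self) -> None:
        pat = self.pattern
        if not pat:
            raise SeedError("empty seed pattern")
        for i, ch in enumerate(pat):
            if ch not in SEED_ALPHABET:
                raise SeedError(
                    f"illegal character {ch!r} at position {i + 1} in seed {pat!r}"
                )
        if "1" not in pat:
            raise SeedError(f"seed {pat!r} has zero 1s (weight must be >= 1)")
        if pat[0] != "1" or pat[-1] != "1":
            raise SeedError(
                f"seed {pat!r} must start and end with '1' (use parse_seed to normalise)"
            )
        w = pat.count("1")
        if self.weight == -1:
            object.__setattr__(self, "weight", w)
        elif self.weight != w:
            raise SeedError(f"stored weight {self.weight} != {w} recomputed from {pat!r}")
        if self.span == -1:
            object.__setattr__(self, "span", len(pat))
        elif self.span != len(pat):
            raise SeedError(f"stored span {self.span} != {len(pat)} recomputed from {pat!r}")

    @property
    def match_positions(self) -> tuple[int, ...]:
        """0-based offsets of the 1-positions."""
        return tuple(i for i, c in enumerate(self.pattern) if c == "1")

    @property
    def transition_positions(self) -> tuple[int, ...]:
        """0-based offsets of the @-positions."""
        return tuple(i for i, c in enumerate(self.pattern) if c == "@")

    @property
    def has_transitions(self) -> bool:
        return "@" in self.pattern

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.pattern


@dataclass(frozen=True)
class SeedSet:
    """An ordered multiple spaced seed (k-seed)."""

    seeds: tuple[Seed, ...]

    def __post_init__(self) -> None:
        if not self.seeds:
            raise SeedError("a seed set needs at least one seed")
        object.__setattr__(self, "seeds", tuple(self.seeds))
        patterns = [s.pattern for s in self.seeds]
        if len(set(patterns)) != len(patterns):
            dupes = sorted({p for p in patterns if patterns.count(p) > 1})
            raise SeedError(f"duplicate seed pattern(s): {', '.join(dupes)}")

    @property
    def k(self) -> int:
        return len(self.seeds)

    @property
    def max_span(self) -> int:
        return max(s.span for s in self.seeds)

    @property
    def min_span(self) -> int:
        return min(s.span for s in self.seeds)

    @property
    def has_transitions(self) -> bool:
        return any(s.has_transitions for s in self.seeds)

    def __iter__(self):
        return iter(self.seeds)

    def __len__(self) -> int:
        return self.k


def parse_seed(text: str) -> Seed:
    """Parse and validate one seed pattern.

    Leading/trailing ``*`` or ``@`` characters are stripped (they pad the span
    without constraining interior hits) with a logged warning.

    >>> parse_seed("111*1**1*1**11*111").weight
    11
    """
    pat = text.strip()
    if not pat:
        raise SeedError("empty seed pattern")
    for i, ch in enumerate(pat):
        if ch not in SEED_ALPHABET:
            raise SeedError(f"illegal character {ch!r} at position {i + 1} in seed {pat!r}")
    if "1" not in pat:
        raise SeedError(f"seed {pat!r} has zero 1s (weight must be >= 1)")
    stripped = pat.strip("*@")
    if stripped != pat:
        logger.warning("seed %r normalised to %r (leading/trailing non-1 stripped)", pat, stripped)
        pat = stripped
    return Seed(pat)


def parse_seeds(patterns: Iterable[str]) -> SeedSet:
    """Build a SeedSet from an iterable of pattern strings."""
    return SeedSet(tuple(parse_seed(p) for p in patterns))


def parse_seed_file(path: str | Path) -> SeedSet:
    """Read a seed file: one pattern per line, ``#`` comments, blanks ignored.

    A file with k seed lines is a k-seed.
    """
    path = Path(path)
    seeds: list[Seed] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                seeds.append(parse_seed(line))
            except SeedError as exc:
                raise SeedError(f"{path}:{lineno}: {exc}") from exc
    if not seeds:
        raise SeedError(f"{path}: no seed lines found")
    try:
        return SeedSet(tuple(seeds))
    except SeedError as exc:
        raise SeedError(f"{path}: {exc}") from exc


def write_seed_file(path: str | Path, seeds: SeedSet, header: str | None = None) -> None:
    """Write a SeedSet in the one-pattern-per-line format."""
    path = Path(path)
    lines = []
    if header:
        lines.extend(f"# {h}" for h in header.splitlines())
    lines.extend(s.pattern for s in seeds)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def encode_dna(seq: str) -> np.ndarray:
    """Encode DNA to int8 codes A=0 C=1 G=2 T=3 (case-insensitive, U->T).

    Any other letter becomes 4; windows touching such a code at a constrained
    position are unhashable and are skipped by callers.
    """
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        out[arr == ord(base)] = code
    return out


class UnhashableWindow(ValueError):
    """The window contains an ambiguity letter at a constrained position."""


def hash_key(seed: Seed, window: str) -> tuple[str, ...]:
    """Project a DNA window of length ``seed.span`` onto the seed.

    Returns a tuple with, in pattern order, the base at each 1-position and
    the purine/pyrimidine class (``R``/``Y``) at each @-position.  Two windows
    get equal keys iff every 1-position matches exactly and every @-position
    matches or is a transition pair.
    """
    if len(window) != seed.span:
        raise ValueError(
            f"window length {len(window)} != seed span {seed.span} for {seed.pattern!r}"
        )
    codes = encode_dna(window)
    key: list[str] = []
    for i, ch in enumerate(seed.pattern):
        if ch == "*":
            continue
        c = int(codes[i])
        if c >= 4:
            raise UnhashableWindow(
                f"ambiguous base {window[i]!r} at constrained position {i + 1}"
            )
        key.append(_CODE_BASE[c] if ch == "1" else _CLASS_CHAR[c & 1])
    return tuple(key)


def packed_keys(seed: Seed, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer-packed hash keys at every window start of an encoded sequence.

    Vectorised counterpart of :func:`hash_key`: 1-positions contribute 2 bits
    (the base code), @-positions 1 bit (the purine/pyrimidine class).  Returns
    ``(keys, valid)`` where ``valid[i]`` is False for unhashable windows; key
    values of invalid windows are meaningless.  Empty arrays if the sequence
    is shorter than the span.
    """
    n = len(codes) - seed.span + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    keys = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    shift = 0
    idx = np.arange(n)
    for off, ch in enumerate(seed.pattern):
        if ch == "*":
            continue
        col = codes[idx + off].astype(np.int64)
        bad = col >= 4
        if bad.any():
            valid &= ~bad
            col = np.where(bad, 0, col)
        if ch == "1":
            keys |= col << shift
            shift += 2
        else:  # '@' : purine/pyrimidine class bit
            keys |= (col & 1) << shift
            shift += 1
    return keys, valid


def contiguous_seed(weight: int) -> Seed:
    """The BLAST-style seed of ``weight`` consecutive 1s."""
    if weight < 1:
        raise SeedError("weight must be >= 1")
    return Seed("1" * weight)
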