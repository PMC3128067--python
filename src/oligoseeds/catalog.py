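"""Packaged seed catalogues.

One catalogue per probe regime (50-mer, 70-mer), holding for each weight the
contiguous seed, a transition-constrained single seed (two ``@`` positions),
and hill-climbing-designed 1-, 2-, 4-, 8- and 16-seeds.  The spaced and
multiple seeds were designed once at the regime's conditions (region length
N = oligo length, similarity p = 0.85, the identity screening level) with a
fixed seed and are shipped as plain-text seed files; evaluation sweeps never
design seeds on the fly.  ``scripts/build_catalog.py`` regenerates them
bit-identically.
"""

from __future__ import annotations

from importlib import resources
from io import StringIO

from .seeds import Seed, SeedSet, contiguous_seed, parse_seed

#: Seed-type names, in the expected increasing order of accuracy.
SEED_TYPE_ORDER = (
    "contiguous", "transition", "1-seed", "2-seed", "4-seed", "8-seed", "16-seed",
)

_TYPE_TO_STEM = {
    "transition": "transition",
    "1-seed": "seed01",
    "2-seed": "seed02",
    "4-seed": "seed04",
    "8-seed": "seed08",
    "16-seed": "seed16",
}
_TYPE_TO_K = {"contiguous": 1, "transition": 1, "1-seed": 1, "2-seed": 2,
              "4-seed": 4, "8-seed": 8, "16-seed": 16}

DEFAULT_WEIGHTS = range(7, 21)


def _read_packaged(regime: str, stem: str, weight: int) -> SeedSet:
    name = f"{stem}_w{weight:02d}.seeds"
    text = resources.files("oligoseeds").joinpath(
        "data", "catalog", regime, name).read_text()
    seeds = [parse_seed(line) for line in text.splitlines()
             if line.strip() and not line.startswith("#")]
    return SeedSet(tuple(seeds))


def load_catalog(
    regime: str = "50mer",
    weights=DEFAULT_WEIGHTS,
    seed_types=SEED_TYPE_ORDER,
) -> dict[tuple[str, int, int], SeedSet]:
    """Load the packaged catalogue as {(seed_type, k, weight): SeedSet}.

    ``regime`` is ``"50mer"`` or ``"70mer"``.  Missing (type, weight) files
    are skipped silently only if outside DEFAULT_WEIGHTS; inside it they
    raise, as the packaged catalogue is complete there.
    """
    if regime not in ("50mer", "70mer"):
        raise ValueError("regime must be '50mer' or '70mer'")
    catalog: dict[tuple[str, int, int], SeedSet] = {}
    for seed_type in seed_types:
        k = _TYPE_TO_K[seed_type]
        for w in weights:
            if seed_type == "contiguous":
                catalog[(seed_type, 1, w)] = SeedSet((contiguous_seed(w),))
            else:
                catalog[(seed_type, k, w)] = _read_packaged(
                    regime, _TYPE_TO_STEM[seed_type], w
                )
    return catalog
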