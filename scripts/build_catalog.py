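"""Regenerate the packaged seed catalogues.

One catalogue per probe regime: seeds designed at region length N = oligo
length and similarity p = 0.85 (the identity screening level).  For every
weight 7..20 this emits a transition-constrained single seed (two @) and
1-, 2-, 4-, 8- and 16-seeds, as plain-text seed files under
src/oligoseeds/data/catalog/{50mer,70mer}/.  Deterministic for a given
--rng-seed; the shipped files were produced with the default 20260920.

Usage: python scripts/build_catalog.py [--rng-seed INT] [--weights LO:HI]
"""

from __future__ import annotations

import argparse
import sys
import time
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from oligoseeds.design import DesignSpec, design_multi  # noqa: E402
from oligoseeds.seeds import write_seed_file  # noqa: E402
from oligoseeds.sensitivity import AlignmentModel  # noqa: E402

RESTARTS = {1: 16, 2: 10, 4: 6, 8: 4, 16: 3}


def build_regime(regime: str, N: int, weights: range, rng_seed: int) -> None:
    outdir = ROOT / "src" / "oligoseeds" / "data" / "catalog" / regime
    outdir.mkdir(parents=True, exist_ok=True)
    model = AlignmentModel(region_length=N, similarity=0.85)
    for w in weights:
        span = min(w + 7, 22)
        for k in (1, 2, 4, 8, 16):
            t0 = time.time()
            spec = DesignSpec(
                k=k, weight=w, max_span=span, model=model,
                rng_seed=rng_seed + 1000 * w + k, restarts=RESTARTS[k],
                state_cap=2**21,
            )
            seedset, sens = design_multi(spec)
            name = f"seed{k:02d}_w{w:02d}.seeds"
            write_seed_file(
                outdir / name, seedset,
                header=f"{regime} k={k} weight={w} span<={span} N={N} p=0.85 "
                       f"sensitivity={sens:.4f}",
            )
            print(f"{regime} k={k:2d} w={w:2d} sens={sens:.4f} "
                  f"({time.time() - t0:.1f}s)", flush=True)
        # transition-constrained single seed: same weight of 1s plus two @
        t0 = time.time()
        spec = DesignSpec(
            k=1, weight=w, max_span=span, model=model,
            rng_seed=rng_seed + 1000 * w + 17, restarts=RESTARTS[1],
            n_transitions=2, state_cap=2**21,
        )
        seedset, sens = design_multi(spec)
        write_seed_file(
            outdir / f"transition_w{w:02d}.seeds", seedset,
            header=f"{regime} transition weight={w}+2@ span<={span} N={N} "
                   f"p=0.85 sensitivity~={sens:.4f}",
        )
        print(f"{regime} trans w={w:2d} sens~{sens:.4f} "
              f"({time.time() - t0:.1f}s)", flush=True)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--rng-seed", type=int, default=20260920)
    ap.add_argument("--weights", default="7:20")
    args = ap.parse_args()
    lo, hi = (int(x) for x in args.weights.split(":"))
    for regime, N in (("50mer", 50), ("70mer", 70)):
        build_regime(regime, N, range(lo, hi + 1), args.rng_seed)


if __name__ == "__main__":
    main()
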