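"""Seed quality: accuracy (F-score) and efficiency, sweeps and rankings.

With the seed's hits as the detector of similarity, over all secondary
sequences of a dataset:

* TP = oligos hit, FP = non-oligos hit, TN = non-oligos not hit,
  FN = oligos not hit;
* precision P = TP/(TP+FP), recall R = TP/(TP+FN), accuracy = F-score
  F = 2PR/(P+R);
* efficiency E = TP/H where H is the total number of hits in all secondary
  sequences — the reciprocal of hashes spent per detected oligo (E <= P
  always, since every hit sequence has at least one hit).

``sweep`` evaluates a catalogue of seed sets (type, k, weight) across
datasets; ``best_accuracy`` reports the per-type weight maximising mean F,
with the standard deviation across datasets; ``bounded_recall`` re-ranks
under a lower bound on recall, as probe screening wants recall near 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datagen import Dataset
from .hits import group_hits
from .seeds import SeedSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int
    total_hits: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN", "total_hits"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total_hits < self.TP + self.FP:
            raise ValueError("total hits H cannot be below TP + FP")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(seeds: SeedSet, dataset: Dataset) -> ConfusionCounts:
    """Aggregate hit-based confusion counts over all groups of a dataset."""
    if not dataset.groups:
        raise ValueError("empty dataset")
    tp = fp = tn = fn = hits = 0
    for group in dataset.groups:
        report = group_hits(seeds, group)
        for (hit, count), (_, label) in zip(report.per_secondary, group.secondaries):
            hits += count
            if label == "oligo":
                tp += hit
                fn += not hit
            else:
                fp += hit
                tn += not hit
    return ConfusionCounts(tp, fp, tn, fn, hits)


def precision(c: ConfusionCounts) -> float | None:
    """TP/(TP+FP); None (undefined) when nothing is hit."""
    denom = c.TP + c.FP
    if denom == 0:
        logger.info("precision undefined: no sequence hit")
        return None
    return c.TP / denom


def recall(c: ConfusionCounts) -> float | None:
    """TP/(TP+FN); None (undefined) when the dataset has no oligos."""
    denom = c.TP + c.FN
    if denom == 0:
        logger.info("recall undefined: no oligos in dataset")
        return None
    return c.TP / denom


def fscore(c: ConfusionCounts) -> float | None:
    """Harmonic mean of precision and recall; 0 when P + R = 0."""
    p, r = precision(c), recall(c)
    if p is None or r is None:
        return None
    if p + r == 0:
        return 0.0
    return 2 * p * r / (p + r)


def efficiency(c: ConfusionCounts) -> float | None:
    """TP divided by the total number of hits H; None when H = 0."""
    if c.total_hits == 0:
        logger.info("efficiency undefined: zero hits")
        return None
    return c.TP / c.total_hits


SWEEP_COLUMNS = [
    "seed_type", "k", "weight", "dataset",
    "TP", "FP", "TN", "FN", "H",
    "precision", "recall", "fscore", "efficiency",
]


def sweep(
    catalog: Mapping[tuple[str, int, int], SeedSet],
    datasets: Sequence[Dataset] | Dataset,
    weights: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Evaluate every catalogue entry (optionally restricted to ``weights``)
    on every dataset.  One row per (seed set, dataset); rows with undefined
    metrics carry NaN and are excluded from rankings."""
    if isinstance(datasets, Dataset):
        datasets = [datasets]
    if not catalog:
        raise ValueError("empty seed catalogue")
    wanted = None if weights is None else set(weights)
    rows = []
    requested_missing = set() if wanted is None else set(wanted)
    for (seed_type, k, weight), seedset in sorted(catalog.items()):
        if wanted is not None and weight not in wanted:
            continue
        requested_missing.discard(weight)
        for ds in datasets:
            c = confusion(seedset, ds)
            rows.append({
                "seed_type": seed_type, "k": k, "weight": weight, "dataset": ds.id,
                "TP": c.TP, "FP": c.FP, "TN": c.TN, "FN": c.FN, "H": c.total_hits,
                "precision": precision(c), "recall": recall(c),
                "fscore": fscore(c), "efficiency": efficiency(c),
            })
    if requested_missing:
        logger.warning("catalogue has no entry for weight(s) %s; skipped",
                       sorted(requested_missing))
    if not rows:
        raise ValueError("no catalogue entry matched the requested weights")
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def best_accuracy(table: pd.DataFrame) -> pd.DataFrame:
    """Per seed type: the weight maximising mean F across datasets.

    Returns columns seed_type, weight, mean_fscore, std_fscore,
    mean_efficiency (at that weight).  Ties in mean F break toward the lower
    weight (cheaper hashing).  Rows with undefined F are ignored.
    """
    t = table.dropna(subset=["fscore"])
    agg = (
        t.groupby(["seed_type", "weight"], as_index=False)
        .agg(mean_fscore=("fscore", "mean"),
             std_fscore=("fscore", lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0),
             mean_recall=("recall", "mean"),
             mean_efficiency=("efficiency", "mean"))
    )
    out = []
    for seed_type, sub in agg.groupby("seed_type"):
        sub = sub.sort_values(["mean_fscore", "weight"], ascending=[False, True])
        best = sub.iloc[0]
        out.append({
            "seed_type": seed_type,
            "weight": int(best["weight"]),
            "mean_fscore": float(best["mean_fscore"]),
            "std_fscore": float(best["std_fscore"]),
            "mean_efficiency": float(best["mean_efficiency"]),
        })
    return pd.DataFrame(out)


def bounded_recall(
    table: pd.DataFrame,
    bounds: Sequence[float] = tuple(round(0.86 + 0.01 * i, 2) for i in range(14)),
) -> pd.DataFrame:
    """Best mean accuracy (and its efficiency) per type among seed sets whose
    mean recall meets each lower bound.  Empty restrictions yield NaN rows."""
    for b in bounds:
        if not 0.0 <= b <= 1.0:
            raise ValueError(f"recall bound {b} outside [0, 1]")
    t = table.dropna(subset=["fscore", "recall"])
    agg = (
        t.groupby(["seed_type", "weight"], as_index=False)
        .agg(mean_fscore=("fscore", "mean"),
             mean_recall=("recall", "mean"),
             mean_efficiency=("efficiency", "mean"))
    )
    out = []
    for bound in bounds:
        eligible = agg[agg["mean_recall"] >= bound]
        for seed_type in sorted(agg["seed_type"].unique()):
            sub = eligible[eligible["seed_type"] == seed_type]
            if sub.empty:
                out.append({"bound": bound, "seed_type": seed_type, "weight": None,
                            "mean_fscore": float("nan"),
                            "mean_efficiency": float("nan")})
                continue
            sub = sub.sort_values(["mean_fscore", "weight"], ascending=[False, True])
            best = sub.iloc[0]
            out.append({"bound": bound, "seed_type": seed_type,
                        "weight": int(best["weight"]),
                        "mean_fscore": float(best["mean_fscore"]),
                        "mean_efficiency": float(best["mean_efficiency"])})
    return pd.DataFrame(out)
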