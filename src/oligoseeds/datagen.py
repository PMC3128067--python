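"""Synthetic oligo-design datasets.

Emulates an oligo-generator workflow: each group has one random main
(target) sequence; secondaries are substitution-only variants of the main at
a sampled identity level.  A secondary is labelled *oligo* (similar — a
cross-hybridisation risk for probes elsewhere, and the thing a good seed
should detect) when ANY of three screening criteria fires:

* identity with the target >= identity threshold (default 85%),
* longest stretch of contiguous matches >= stretch threshold
  (default 15 bp for 50-mers, 20 bp for 70-mers),
* duplex hybridisation free energy <= dG threshold
  (default -30 kcal/mol for 50-mers, -40 kcal/mol for 70-mers);

otherwise *non-oligo*.  The free energy uses nearest-neighbour Watson-Crick
stack parameters (dG37): every dinucleotide step whose both positions match
contributes its tabulated stack term; internal mismatches pay a flat
loop-opening penalty instead of sequence-specific mismatch stacks; plus
per-terminus initiation terms.  A deliberately simple duplex model (no
mismatch tables, no salt/temperature correction) whose -30/-40 kcal/mol
screening thresholds land at the ~85% identity level the datasets embody.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .hits import Label, OligoGroup

logger = logging.getLogger(__name__)

_BASES = "ACGT"


# --------------------------------------------------------------------------
# thermodynamics


@dataclass(frozen=True)
class ThermoParams:
    """Nearest-neighbour duplex free-energy parameters (dG37, kcal/mol).

    ``stack_dG`` maps the 10 unique Watson-Crick dinucleotide steps (probe
    strand, 5'->3') to stack free energies; the other 6 steps are derived by
    reverse-complement symmetry.  ``initiation_dG`` maps the terminal
    base-pair class ('GC' or 'AT') to the per-terminus initiation penalty.
    """

    stack_dG: dict[str, float]
    initiation_dG: dict[str, float]
    internal_mismatch_dG: float = 3.0
    version: str = "unified-1998"

    _UNIQUE = ("AA", "AT", "TA", "CA", "GT", "CT", "GA", "CG", "GC", "GG")

    def __post_init__(self) -> None:
        missing = [s for s in self._UNIQUE if s not in self.stack_dG]
        if missing:
            raise ValueError(f"stack table missing steps: {missing}")
        nonneg = [s for s in self._UNIQUE if self.stack_dG[s] >= 0]
        if nonneg:
            raise ValueError(f"stack dG must be negative; offending: {nonneg}")
        for cls in ("GC", "AT"):
            if cls not in self.initiation_dG:
                raise ValueError(f"initiation term for terminal class {cls!r} missing")
        if self.internal_mismatch_dG < 0:
            raise ValueError("internal mismatch penalty must destabilise (>= 0)")

    def full_table(self) -> dict[str, float]:
        """All 16 dinucleotide steps, completed by reverse-complement symmetry."""
        comp = str.maketrans("ACGT", "TGCA")
        table = dict(self.stack_dG)
        for a in _BASES:
            for b in _BASES:
                step = a + b
                if step not in table:
                    table[step] = table[(a + b).translate(comp)[::-1]]
        return table

    def initiation(self, terminal_base: str) -> float:
        return self.initiation_dG["GC" if terminal_base in "GC" else "AT"]


def load_thermo_params() -> ThermoParams:
    """Load the packaged unified nearest-neighbour dG37 table."""
    text = resources.files("oligoseeds").joinpath("data", "nn_dG37.json").read_text()
    raw = json.loads(text)
    return ThermoParams(
        stack_dG=raw["stack_dG37"],
        initiation_dG=raw["initiation_dG37"],
        internal_mismatch_dG=raw.get("internal_mismatch_dG37", 3.0),
        version=raw.get("version", "unknown"),
    )


def duplex_dG(a: str, b: str, thermo: ThermoParams | None = None) -> float:
    """dG37 (kcal/mol) of the positional duplex of probe ``a`` vs target ``b``.

    Sums the stack term of every dinucleotide step of ``a`` whose two
    positions both match ``b``; steps touching a mismatch contribute no
    stacking.  Each INTERNAL mismatched position additionally pays the
    loop-opening/strain penalty ``thermo.internal_mismatch_dG`` (terminal
    mismatches act as dangling ends and pay nothing beyond their lost
    stacks).  Per-terminus initiation terms (class of a's first/last base)
    are always added.  More negative = more stable; adding a mismatch never
    stabilises.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("empty sequences")
    a, b = a.upper(), b.upper()
    for seq in (a, b):
        bad = set(seq) - set(_BASES)
        if bad:
            raise ValueError(f"non-ACGT base(s) {sorted(bad)}")
    if thermo is None:
        thermo = load_thermo_params()
    table = thermo.full_table()
    dg = thermo.initiation(a[0]) + thermo.initiation(a[-1])
    for i in range(len(a) - 1):
        if a[i] == b[i] and a[i + 1] == b[i + 1]:
            dg += table[a[i : i + 2]]
    for i in range(1, len(a) - 1):
        if a[i] != b[i]:
            dg += thermo.internal_mismatch_dG
    return dg


# --------------------------------------------------------------------------
# sequence-level measures


def identity(a: str, b: str) -> float:
    """Fraction of positions where a and b carry the same base."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("empty sequences")
    a, b = a.upper(), b.upper()
    return sum(x == y for x, y in zip(a, b)) / len(a)


def longest_match_stretch(a: str, b: str) -> int:
    """Length of the longest run of consecutive matching positions."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    best = cur = 0
    for x, y in zip(a.upper(), b.upper()):
        cur = cur + 1 if x == y else 0
        best = max(best, cur)
    return best


# --------------------------------------------------------------------------
# generation


@dataclass(frozen=True)
class GenConfig:
    """Generator configuration.

    Defaults follow the two standard probe regimes: 50-mers screened at
    (85% identity, 15 bp stretch, -30 kcal/mol) and 70-mers at
    (85%, 20 bp, -40 kcal/mol).  ``identity_range`` is the sampling range of
    the per-secondary target identity; it straddles the screening boundary so
    that both labels occur.
    """

    oligo_length: int = 50
    n_groups: int = 50
    n_secondaries: int = 20
    n_datasets: int = 3
    identity_threshold: float = 0.85
    stretch_threshold: int | None = None
    dG_threshold: float | None = None
    identity_range: tuple[float, float] = (0.60, 0.98)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.stretch_threshold is None:
            object.__setattr__(
                self, "stretch_threshold", 20 if self.oligo_length >= 70 else 15
            )
        if self.dG_threshold is None:
            object.__setattr__(
                self, "dG_threshold", -40.0 if self.oligo_length >= 70 else -30.0
            )
        if not 0.0 < self.identity_threshold < 1.0:
            raise ValueError("identity_threshold must be in (0, 1)")
        if self.stretch_threshold > self.oligo_length:
            raise ValueError("stretch_threshold exceeds oligo_length")
        if self.dG_threshold >= 0:
            raise ValueError("dG_threshold must be negative")
        lo, hi = self.identity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("identity_range must be within (0, 1]")


def generate_main(length: int, rng: np.random.Generator) -> str:
    """An i.i.d. uniform random DNA sequence."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def mutate(main: str, target_identity: float, rng: np.random.Generator) -> str:
    """Substitution-only variant of ``main``.

    Exactly ``round((1 - target_identity) * len(main))`` positions (round
    half to even, Python's round) are substituted, sampled without
    replacement; each substitute base is uniform over the three alternatives.
    """
    if not 0.0 < target_identity <= 1.0:
        raise ValueError("target_identity must be in (0, 1]")
    L = len(main)
    # kill float noise before the half-to-even rounding: (1-0.85)*70 is
    # 10.500000000000002 in binary and must still round to 10
    n_sub = round(round((1.0 - target_identity) * L, 9))
    if n_sub == 0:
        return main
    positions = rng.choice(L, size=n_sub, replace=False)
    out = list(main)
    for pos in positions:
        alternatives = [b for b in _BASES if b != out[pos]]
        out[pos] = alternatives[rng.integers(0, 3)]
    return "".join(out)


def classify(
    main: str,
    secondary: str,
    cfg: GenConfig,
    thermo: ThermoParams | None = None,
) -> Label:
    """Screen a secondary against its target: oligo if ANY criterion fires."""
    if thermo is None:
        thermo = load_thermo_params()
    if identity(main, secondary) >= cfg.identity_threshold:
        return "oligo"
    if longest_match_stretch(main, secondary) >= cfg.stretch_threshold:
        return "oligo"
    if duplex_dG(main, secondary, thermo) <= cfg.dG_threshold:
        return "oligo"
    return "non-oligo"


@dataclass(frozen=True)
class Dataset:
    """A generated dataset: labelled groups plus the config that produced it."""

    groups: tuple[OligoGroup, ...]
    config: GenConfig
    dataset_index: int = 0

    @property
    def n_secondaries(self) -> int:
        return sum(len(g.secondaries) for g in self.groups)

    @property
    def id(self) -> str:
        return f"{self.config.oligo_length}mer-d{self.dataset_index}"


_BALANCE_RETRY_CAP = 200


def _generate_group(
    cfg: GenConfig, thermo: ThermoParams, rng: np.random.Generator
) -> OligoGroup:
    lo, hi = cfg.identity_range
    for _ in range(_BALANCE_RETRY_CAP):
        main = generate_main(cfg.oligo_length, rng)
        secondaries = []
        for _ in range(cfg.n_secondaries):
            t = rng.uniform(lo, hi)
            var = mutate(main, t, rng)
            secondaries.append((var, classify(main, var, cfg, thermo)))
        labels = {lab for _, lab in secondaries}
        if labels == {"oligo", "non-oligo"}:
            return OligoGroup(main, tuple(secondaries))
    raise RuntimeError(
        f"could not generate a group with both labels in {_BALANCE_RETRY_CAP} "
        f"attempts; widen identity_range (currently {cfg.identity_range})"
    )


def generate_dataset(
    cfg: GenConfig,
    dataset_index: int = 0,
    thermo: ThermoParams | None = None,
) -> Dataset:
    """Generate one dataset of ``cfg.n_groups`` balanced groups.

    Each group's RNG stream derives from (rng_seed, dataset_index,
    group_index), so groups are independent and the whole dataset is
    reproducible group-by-group.
    """
    if thermo is None:
        thermo = load_thermo_params()
    groups = []
    for g in range(cfg.n_groups):
        rng = np.random.default_rng([cfg.rng_seed, dataset_index, g])
        groups.append(_generate_group(cfg, thermo, rng))
    return Dataset(tuple(groups), cfg, dataset_index)


def generate_datasets(cfg: GenConfig, thermo: ThermoParams | None = None) -> list[Dataset]:
    """The study's replicates: ``cfg.n_datasets`` datasets from one master seed."""
    if thermo is None:
        thermo = load_thermo_params()
    return [generate_dataset(cfg, d, thermo) for d in range(cfg.n_datasets)]


# --------------------------------------------------------------------------
# on-disk round trip: FASTA + TSV manifest + JSON config echo


def write_dataset(dataset: Dataset, outdir: str | Path,
                  thermo: ThermoParams | None = None) -> Path:
    """Write FASTA + manifest + config echo for one dataset; returns its dir."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if thermo is None:
        thermo = load_thermo_params()
    outdir = Path(outdir) / dataset.id
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    manifest_rows = ["id\tgroup\trole\tlabel\tidentity\tstretch\tdG"]
    for g, group in enumerate(dataset.groups):
        main_id = f"g{g:03d}_main"
        records.append(SeqRecord(Seq(group.main), id=main_id, description=""))
        manifest_rows.append(f"{main_id}\t{g}\tmain\t.\t.\t.\t.")
        for s, (seq, label) in enumerate(group.secondaries):
            sid = f"g{g:03d}_sec{s:03d}"
            records.append(SeqRecord(Seq(seq), id=sid, description=""))
            ident = identity(group.main, seq)
            stretch = longest_match_stretch(group.main, seq)
            dg = duplex_dG(group.main, seq, thermo)
            manifest_rows.append(
                f"{sid}\t{g}\tsecondary\t{label}\t{ident:.4f}\t{stretch}\t{dg:.2f}"
            )
    SeqIO.write(records, outdir / "sequences.fasta", "fasta")
    (outdir / "manifest.tsv").write_text("\n".join(manifest_rows) + "\n")
    (outdir / "config.json").write_text(
        json.dumps({**asdict(dataset.config), "dataset_index": dataset.dataset_index},
                   indent=2) + "\n"
    )
    return outdir


def read_dataset(path: str | Path) -> Dataset:
    """Read back a dataset directory written by :func:`write_dataset`."""
    from Bio import SeqIO

    path = Path(path)
    cfg_raw = json.loads((path / "config.json").read_text())
    dataset_index = cfg_raw.pop("dataset_index", 0)
    cfg_raw["identity_range"] = tuple(cfg_raw["identity_range"])
    cfg = GenConfig(**cfg_raw)
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(path / "sequences.fasta", "fasta")}
    groups: dict[int, dict] = {}
    lines = (path / "manifest.tsv").read_text().splitlines()
    for line in lines[1:]:
        sid, g, role, label = line.split("\t")[:4]
        entry = groups.setdefault(int(g), {"main": None, "secondaries": []})
        if role == "main":
            entry["main"] = seqs[sid]
        else:
            entry["secondaries"].append((seqs[sid], label))
    built = tuple(
        OligoGroup(groups[g]["main"], tuple(groups[g]["secondaries"]))
        for g in sorted(groups)
    )
    return Dataset(built, cfg, dataset_index)
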