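import numpy as np
import pytest

from oligoseeds import OligoGroup, parse_seeds

# Synthetic reconstruction of the published worked example: one group, the
# seed 11*1**111, four oligos and six non-oligos with per-secondary hit
# counts (2,1,1,0) and (1,1,0,0,0,0) — so TP=3, FP=2, FN=1, TN=4 and six
# hits in total.  The sequences are synthetic (found by randomized search);
# only the counts match the published figure.
WORKED_SEED = "11*1**111"
_WORKED_MAIN = "ATGCCTAGAAGTGTGTGATCGCAT"
_WORKED_SECONDARIES = [
    ("TAGTACCTAGCAGTGAACGGAGCG", "oligo"),      # hit twice
    ("TGTATTCGATTCGCAGGTTCTGGG", "oligo"),      # hit once
    ("GGGAATTGATACCATGCGACGCTA", "oligo"),      # hit once
    ("AGTCATCAGCTCGGACAGTTCCGG", "oligo"),      # not hit
    ("GCATTGCGTGCCGCGAATCCGCTA", "non-oligo"),  # hit once
    ("CCCGGGGATGGTTGTCGCGATAGA", "non-oligo"),  # hit once
    ("ATTAATTAGCGCACGTATGTTAAT", "non-oligo"),
    ("AACTTGACGAGACAGTATGTTAGG", "non-oligo"),
    ("ACTGCCTCAGTACCAGCACTTGCT", "non-oligo"),
    ("AGGGAGGTAGTCGAGGAAGACATG", "non-oligo"),
]


@pytest.fixture(scope="session")
def worked_example_group() -> OligoGroup:
    return OligoGroup(_WORKED_MAIN, tuple(_WORKED_SECONDARIES))


@pytest.fixture(scope="session")
def worked_example_seed():
    return parse_seeds([WORKED_SEED])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def random_seed_pattern(rng: np.random.Generator, weight: int, span: int) -> str:
    assert 2 <= weight <= span
    mid = ["*"] * (span - 2)
    for i in rng.choice(span - 2, size=weight - 2, replace=False):
        mid[i] = "1"
    return "1" + "".join(mid) + "1"
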