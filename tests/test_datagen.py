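"""Synthetic dataset generator: mutation, screening criteria, round trips."""

import itertools

import numpy as np
import pytest

from oligoseeds import (GenConfig, classify, duplex_dG, generate_dataset,
                        generate_main, identity, load_thermo_params,
                        longest_match_stretch, mutate, read_dataset,
                        write_dataset)

THERMO = load_thermo_params()


def test_generate_main_uniform_composition():
    rng = np.random.default_rng(5)
    seq = generate_main(100_000, rng)
    counts = {b: seq.count(b) for b in "ACGT"}
    assert set(seq) <= set("ACGT")
    # chi-square against uniform: 3 dof, 1e-4 quantile ~ 21
    chi2 = sum((c - 25_000) ** 2 / 25_000 for c in counts.values())
    assert chi2 < 21


def test_generate_main_reproducible():
    a = generate_main(50, np.random.default_rng(9))
    b = generate_main(50, np.random.default_rng(9))
    assert a == b


@pytest.mark.parametrize(
    "L, t, n_sub",
    [(50, 1.0, 0), (50, 0.85, 8), (50, 0.9, 5), (70, 0.85, 10), (40, 0.8125, 8)],
)
def test_mutate_substitution_count_with_bankers_rounding(L, t, n_sub):
    # round-half-even on the noise-free product: round(7.5) = 8, round(10.5) = 10
    assert round(round((1 - t) * L, 9)) == n_sub
    rng = np.random.default_rng(1)
    main = generate_main(L, rng)
    var = mutate(main, t, rng)
    assert len(var) == L
    diffs = sum(a != b for a, b in zip(main, var))
    assert diffs == n_sub
    assert identity(main, var) == pytest.approx(1 - n_sub / L)


def test_identity_and_stretch_basics():
    assert identity("AAAA", "AAAA") == 1.0
    assert identity("AAAA", "AAAT") == 0.75
    assert longest_match_stretch("AATAA", "AAAAA") == 2
    assert longest_match_stretch("ACGT", "ACGT") == 4
    with pytest.raises(ValueError):
        identity("AA", "AAA")
    with pytest.raises(ValueError):
        longest_match_stretch("AA", "AAA")


def test_stretch_matches_brute_scan(rng):
    from .conftest import random_dna
    for _ in range(20):
        L = int(rng.integers(5, 40))
        a, b = random_dna(rng, L), random_dna(rng, L)
        runs, cur = [0], 0
        for x, y in zip(a, b):
            cur = cur + 1 if x == y else 0
            runs.append(cur)
        assert longest_match_stretch(a, b) == max(runs)


# -------------------------------------------------------------- duplex dG


def test_duplex_full_match_hand_sum():
    a = "ACGTT"
    # stacks AC, CG, GT, TT + initiation for terminal A and T (both AT class)
    table = THERMO.full_table()
    expected = (table["AC"] + table["CG"] + table["GT"] + table["TT"]
                + 2 * THERMO.initiation_dG["AT"])
    assert duplex_dG(a, a, THERMO) == pytest.approx(expected)


def test_duplex_complement_symmetry_of_table():
    table = THERMO.full_table()
    comp = str.maketrans("ACGT", "TGCA")
    for step, dg in table.items():
        rc = step.translate(comp)[::-1]
        assert table[rc] == pytest.approx(dg)


def test_duplex_no_consecutive_matches_has_no_stacking():
    a = "ACGTA"
    b = "AGGAA"  # matches at positions 0, 2, 4 only -> no matched step;
    # internal mismatches at 1 and 3 pay the loop penalty
    expected = (THERMO.initiation_dG["AT"] * 2
                + 2 * THERMO.internal_mismatch_dG)
    assert duplex_dG(a, b, THERMO) == pytest.approx(expected)
    assert duplex_dG(a, b, THERMO) > 0  # nowhere near a stable duplex


def test_duplex_monotone_in_mismatches_exhaustive():
    """Adding one mismatch anywhere never stabilises the duplex."""
    a = "GCGTAC"
    for positions in itertools.combinations(range(6), 2):
        b = list(a)
        b[positions[0]] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[positions[0]]]
        one = duplex_dG(a, "".join(b), THERMO)
        b[positions[1]] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[positions[1]]]
        two = duplex_dG(a, "".join(b), THERMO)
        assert duplex_dG(a, a, THERMO) <= one <= two


def test_duplex_errors():
    with pytest.raises(ValueError):
        duplex_dG("ACG", "AC", THERMO)
    with pytest.raises(ValueError):
        duplex_dG("ACN", "ACG", THERMO)


# ------------------------------------------------------------ classifier


def test_classify_identical_is_oligo():
    cfg = GenConfig(oligo_length=50)
    main = generate_main(50, np.random.default_rng(2))
    assert classify(main, main, cfg, THERMO) == "oligo"


def test_classify_all_criteria_below_threshold_is_non_oligo():
    cfg = GenConfig(oligo_length=50)
    rng = np.random.default_rng(3)
    # heavily mutated variant: low identity, short stretches, weak duplex
    main = generate_main(50, rng)
    var = mutate(main, 0.5, rng)
    assert identity(main, var) < cfg.identity_threshold
    assert longest_match_stretch(main, var) < cfg.stretch_threshold
    assert duplex_dG(main, var, THERMO) > cfg.dG_threshold
    assert classify(main, var, cfg, THERMO) == "non-oligo"


def test_classify_stretch_criterion_alone_fires():
    cfg = GenConfig(oligo_length=50)
    main = generate_main(50, np.random.default_rng(4))
    # keep a 15bp window intact, mutate enough elsewhere to sink identity
    var = list(mutate(main, 0.5, np.random.default_rng(5)))
    var[10:25] = main[10:25]
    var = "".join(var)
    if identity(main, var) < cfg.identity_threshold:
        assert longest_match_stretch(main, var) >= 15
        assert classify(main, var, cfg, THERMO) == "oligo"


def test_default_thresholds_per_regime():
    assert GenConfig(oligo_length=50).stretch_threshold == 15
    assert GenConfig(oligo_length=50).dG_threshold == -30.0
    assert GenConfig(oligo_length=70).stretch_threshold == 20
    assert GenConfig(oligo_length=70).dG_threshold == -40.0


def test_classify_monotone_along_mutation_chain():
    """Along a chain that only destroys matches, identity falls, the longest
    stretch shrinks and the duplex destabilises — so the label can flip
    oligo -> non-oligo once and never back."""
    cfg = GenConfig(oligo_length=50)
    rng = np.random.default_rng(6)
    main = generate_main(50, rng)
    chain_labels = []
    var = main
    for _ in range(30):
        chain_labels.append(classify(main, var, cfg, THERMO))
        matching = [i for i in range(50) if var[i] == main[i]]
        if not matching:
            break
        pos = int(rng.choice(matching))
        alt = [b for b in "ACGT" if b != var[pos]]
        var = var[:pos] + alt[int(rng.integers(3))] + var[pos + 1:]
    assert chain_labels[0] == "oligo"
    assert "non-oligo" in chain_labels
    first_non = chain_labels.index("non-oligo")
    assert "oligo" not in chain_labels[first_non:]


# ------------------------------------------------------------ datasets


def test_generate_dataset_structure_and_balance():
    cfg = GenConfig(oligo_length=50, n_groups=4, n_secondaries=8, rng_seed=11)
    ds = generate_dataset(cfg)
    assert len(ds.groups) == 4
    for g in ds.groups:
        assert len(g.secondaries) == 8
        labels = {lab for _, lab in g.secondaries}
        assert labels == {"oligo", "non-oligo"}


def test_generate_dataset_reproducible_and_labels_verify():
    cfg = GenConfig(oligo_length=50, n_groups=3, n_secondaries=6, rng_seed=12)
    a = generate_dataset(cfg)
    b = generate_dataset(cfg)
    assert [g.main for g in a.groups] == [g.main for g in b.groups]
    for g in a.groups:
        for seq, label in g.secondaries:
            assert classify(g.main, seq, cfg, THERMO) == label


def test_dataset_round_trip(tmp_path):
    cfg = GenConfig(oligo_length=50, n_groups=2, n_secondaries=5, rng_seed=13)
    ds = generate_dataset(cfg, dataset_index=1)
    outdir = write_dataset(ds, tmp_path)
    back = read_dataset(outdir)
    assert back.dataset_index == 1
    assert [g.main for g in back.groups] == [g.main for g in ds.groups]
    assert [g.secondaries for g in back.groups] == [g.secondaries for g in ds.groups]
    for g in back.groups:
        for seq, label in g.secondaries:
            assert classify(g.main, seq, back.config, THERMO) == label


def test_both_labels_occur_with_straddling_identity_range():
    cfg = GenConfig(oligo_length=50, n_groups=5, n_secondaries=10, rng_seed=14)
    ds = generate_dataset(cfg)
    labels = [lab for g in ds.groups for _, lab in g.secondaries]
    assert 0 < labels.count("oligo") < len(labels)


def test_config_validation():
    with pytest.raises(ValueError):
        GenConfig(identity_threshold=1.5)
    with pytest.raises(ValueError):
        GenConfig(oligo_length=10, stretch_threshold=15)
    with pytest.raises(ValueError):
        GenConfig(dG_threshold=5.0)
    with pytest.raises(ValueError):
        GenConfig(identity_range=(0.0, 0.5))
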