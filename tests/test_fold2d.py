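"""Ensemble sums vs explicit enumeration; probability and structure calls."""

import math
import random

import numpy as np
import pytest

from rnamelt.entropy import default_table
from rnamelt.fold2d import (
    FeasibilityError,
    FoldResult,
    dominant_and_alternatives,
    enumerate_mismatch_variants,
    enumerate_structures,
    exhaustive_oracle,
    fold,
    helix_probabilities,
    partition_function,
    structure_free_energy,
)
from rnamelt.fixtures import bistable, hairpin
from rnamelt.params import (
    LoopType,
    Temperature,
    get_params,
    loop_free_energy,
    stack_free_energy,
    stack_key,
)
from rnamelt.sequence import RnaSequence
from rnamelt.structures import PseudoknotMode, SecondaryStructure

MODES = list(PseudoknotMode)


def test_unpairable_sequence_is_open_chain():
    r = partition_function("AAAAAAAA")
    assert r.Q == 1.0 and r.lnQ == 0.0
    assert not r.bpp.any()


def test_known_hairpin_structure_count():
    """GGGAAAACCC admits exactly 6 structures (hand-enumerated: the open
    chain plus five helices, with no admissible intra-loop mismatch)."""
    structures = list(enumerate_structures("GGGAAAACCC"))
    assert len(structures) == 6
    runs = sorted(tuple(s.runs()) for s in structures if s.pairs)
    assert runs == [
        ((0, 8, 2),), ((0, 9, 2),), ((0, 9, 3),), ((1, 8, 2),), ((1, 9, 2),)
    ]


def test_partition_function_matches_oracle_example():
    o = exhaustive_oracle("GGGAAAACCC")
    d = partition_function("GGGAAAACCC")
    assert d.Q == pytest.approx(o.Q, rel=1e-9)
    assert np.abs(d.bpp - o.bpp).max() < 1e-9


@pytest.mark.parametrize("mode", MODES)
def test_random_sequences_match_oracle(mode, dialect_params):
    rng = random.Random(f"{mode.value}-{dialect_params.dialect.value}")
    table = default_table()
    for _ in range(8):
        n = rng.randint(8, 16)
        s = "".join(rng.choice("ACGU") for _ in range(n))
        o = exhaustive_oracle(s, params=dialect_params, entropies=table, pk=mode)
        d = partition_function(s, params=dialect_params, entropies=table, pk=mode)
        assert d.Q == pytest.approx(o.Q, rel=1e-9), s
        assert np.abs(d.bpp - o.bpp).max() < 1e-9, s


def test_oracle_normalization_sums_to_one():
    result, scored = exhaustive_oracle("GGCAAAAGCC", return_structures=True)
    total = sum(w for _, w in scored)
    assert 1.0 - total / result.Q < 1e-9


def test_single_pairing_bound():
    rng = random.Random(42)
    for _ in range(5):
        s = "".join(rng.choice("ACGU") for _ in range(20))
        r = partition_function(s)
        assert r.bpp.sum(axis=1).max() <= 1.0 + 1e-12


def test_mode_monotonicity():
    for s in ["GGGAAAGGGACCCAAAACCC", "GCGCAAAGCGC", "GGGAAAACCC"]:
        qs = [partition_function(s, pk=m, compute_bpp=False).Q for m in MODES]
        assert qs[0] <= qs[1] + 1e-12 <= qs[2] + 1e-12


def test_pk_free_sequence_identical_in_all_modes():
    f = hairpin(3, 4)  # GGGAAAACCC cannot form crossing helices
    qs = [partition_function(str(f.sequence), pk=m).Q for m in MODES]
    assert qs[0] == pytest.approx(qs[1], rel=1e-12) == pytest.approx(qs[2], rel=1e-12)


def test_empty_structure_is_reference_state():
    seq = RnaSequence("GGGAAAACCC")
    assert structure_free_energy(seq, SecondaryStructure(()), Temperature(37)) == 0.0


def test_structure_energy_matches_per_motif_sum():
    """One helix + hairpin loop: term-by-term independent summation."""
    seq = RnaSequence("GGGAAAACCC")
    s = SecondaryStructure([(0, 9), (1, 8), (2, 7)])
    T = Temperature(37)
    p = get_params()
    table = default_table()
    expected = 0.0
    for t in range(2):
        expected += stack_free_energy(
            stack_key(seq[t], seq[t + 1], seq[9 - t], seq[8 - t]), T, p
        )
    expected += loop_free_energy(LoopType.HAIRPIN, (4,), [], T, p, table)
    assert structure_free_energy(seq, s, T, p, table) == pytest.approx(expected, abs=1e-9)


def test_structure_energy_linear_in_temperature_without_variants():
    """For a variant-free structure, dG(T1) - dG(T2) = -(T1-T2) * dS_total."""
    seq = RnaSequence("GGGAAAACCC")
    s = SecondaryStructure([(0, 9), (1, 8), (2, 7)])
    g25 = structure_free_energy(seq, s, Temperature(25))
    g37 = structure_free_energy(seq, s, Temperature(37))
    g49 = structure_free_energy(seq, s, Temperature(49))
    assert g37 - g25 == pytest.approx(g49 - g37, abs=1e-9)


def test_disallowed_pair_raises():
    seq = RnaSequence("GGGAAAACCC")
    # structurally fine (lonely-pair check relaxed) but A-C is not a pair type
    s = SecondaryStructure([(0, 9), (1, 8), (3, 7)], validate_runs=False)
    with pytest.raises(Exception, match="disallowed pair"):
        structure_free_energy(seq, s, Temperature(37))


def test_mismatch_variants_polyA_loop_is_plain_only():
    """Under the canonical mismatch alphabet, A.A cannot form."""
    seq = RnaSequence("GGAAAAAACC")
    vs = enumerate_mismatch_variants(
        seq, ("hairpin", (1, 8)), Temperature(37), get_params(), default_table()
    )
    assert len(vs) == 1 and vs[0].mismatch is None


def test_mismatch_variants_include_admissible_pairs():
    # loop AAAAUA: the A1-U5 mismatch is admissible (not a helix extension)
    seq = RnaSequence("GGGAAAAUACCC")
    vs = enumerate_mismatch_variants(
        seq, ("hairpin", (2, 9)), Temperature(37), get_params(), default_table()
    )
    assert vs[0].mismatch is None
    assert any(v.mismatch is not None for v in vs)
    # Boltzmann-weighted variant sum is at least the plain-loop weight
    beta = 1.0 / (get_params().gas_constant * 310.15)
    total = sum(math.exp(-beta * v.dG) for v in vs)
    assert total >= math.exp(-beta * vs[0].dG)


def test_bistable_symmetry_equal_probabilities():
    """Palindromic two-helix sequence: both helix sets equally probable."""
    f = bistable()  # GGGGAAACCCCAAAGGGG
    r = fold(str(f.sequence))
    h1, h2 = r.helices[0], r.helices[1]
    assert h1.length == h2.length == f.spec.stem
    assert abs(h1.probability - h2.probability) < 1e-6
    assert h1.probability + h2.probability <= 1.0


def test_high_temperature_melts_all_pairs():
    """Beyond the last transition, P_ij decays monotonically toward 0."""
    f = hairpin(4, 4)
    pmax = [partition_function(str(f.sequence), T=t).bpp.max() for t in (100, 110, 120)]
    assert pmax[0] > pmax[1] > pmax[2]
    assert pmax[2] < 0.1


def test_helix_probabilities_empty_for_zero_bpp():
    r = partition_function("AAAAAAAA")
    assert helix_probabilities(r) == []


def test_helix_probability_is_mean_over_run():
    r = partition_function("GGGGAAAACCCC")
    hs = helix_probabilities(r)
    h = hs[0]
    mean = np.mean([r.bpp[i, j] for (i, j) in h.pairs()])
    assert h.probability == pytest.approx(float(mean))


def test_dominant_strict_threshold():
    """P_ij = 0.5 exactly is excluded from the dominant structure."""
    r = partition_function("AAAAAAAA")
    r.bpp = np.zeros((8, 8))
    for (i, j) in [(0, 7), (1, 6)]:
        r.bpp[i, j] = r.bpp[j, i] = 0.5
    (dom, prob), alts = dominant_and_alternatives(r)
    assert len(dom.pairs) == 0 and prob == 0.0


def test_dominant_and_single_alternative_two_level_pattern():
    """Two exclusive helix sets at levels p and 1-p: dominant at p, one
    alternative at 1-p."""
    f = bistable(stem=4, loop=3, loop2=6)  # loop asymmetry biases helix 1
    r = fold(str(f.sequence))
    dom, prob = r.dominant
    assert prob > 0.5
    assert set(f.structure.pairs) <= set(dom.pairs)
    strong_alts = [a for a in r.alternatives if a[1] > 0.1]
    assert len(strong_alts) == 1
    assert strong_alts[0][1] < 0.5
    assert prob + strong_alts[0][1] <= 1.0 + 1e-9


def test_oracle_refuses_long_sequences():
    with pytest.raises(FeasibilityError):
        list(enumerate_structures("A" * 26))


def test_any_junction_mode_length_cap():
    with pytest.raises(FeasibilityError):
        partition_function("A" * 61, pk=PseudoknotMode.ANY_JUNCTION)


def test_fold_returns_complete_result():
    r = fold("GGGGAAAACCCC")
    assert isinstance(r, FoldResult)
    assert r.Q > 1 and r.helices and r.dominant is not None
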