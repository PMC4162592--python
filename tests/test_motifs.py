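"""Motif decomposition and template eligibility."""

import pytest

from rnamelt.fixtures import pseudoknot
from rnamelt.motifs import (
    Motif,
    MotifKind,
    decompose,
    eligibility,
)
from rnamelt.sequence import RnaSequence
from rnamelt.structures import SecondaryStructure


def kinds(motifs):
    return sorted(m.kind.value for m in motifs)


def test_single_hairpin_decomposition():
    seq = RnaSequence("GGGAAAACCC")
    s = SecondaryStructure([(0, 9), (1, 8), (2, 7)])
    motifs = decompose(seq, s)
    assert kinds(motifs) == ["hairpin_loop", "helix"]
    report = eligibility(motifs, n=10)
    assert report.overall_supported


def test_two_hairpins_with_linker_has_open_motif():
    """Two stem-loops joined by a single strand: the linker has no
    template, so the whole structure is ineligible."""
    seq = RnaSequence("GGGAAAACCC" + "UUCG" + "GGGAAAACCC")
    pairs = [(0, 9), (1, 8), (2, 7), (14, 23), (15, 22), (16, 21)]
    motifs = decompose(seq, SecondaryStructure(pairs))
    assert kinds(motifs) == ["hairpin_loop", "hairpin_loop", "helix", "helix", "open_motif"]
    report = eligibility(motifs, n=len(seq))
    assert not report.overall_supported
    assert any("single strand" in note for note in report.notes)


def test_three_way_cloverleaf_junction():
    # closing helix + two inner hairpins, manually drawn
    seq = RnaSequence("GG" + "GGGAAAACCC" + "A" + "GGGAAAACCC" + "ACC")
    pairs = [(0, 25), (1, 24)]
    pairs += [(2, 11), (3, 10), (4, 9)]
    pairs += [(13, 22), (14, 21), (15, 20)]
    motifs = decompose(seq, SecondaryStructure(pairs))
    junctions = [m for m in motifs if m.kind is MotifKind.NWAY_JUNCTION]
    assert len(junctions) == 1
    assert junctions[0].branch_count == 3
    assert eligibility(motifs, n=len(seq)).overall_supported


def test_five_prime_tail_unsupported_with_recommendation():
    seq = RnaSequence("AAAA" + "GGGAAAACCC")
    pairs = [(4, 13), (5, 12), (6, 11)]
    motifs = decompose(seq, SecondaryStructure(pairs))
    report = eligibility(motifs, n=len(seq))
    assert not report.overall_supported
    assert any("tail" in note for note in report.notes)


def test_eight_way_junction_unsupported():
    motifs = [
        Motif(MotifKind.NWAY_JUNCTION, strands=((0, 0),), branch_count=8),
        Motif(MotifKind.HELIX, strands=((1, 2), (3, 4))),
    ]
    report = eligibility(motifs)
    assert report.supported == [False, True]
    assert not report.overall_supported
    seven = eligibility([Motif(MotifKind.NWAY_JUNCTION, strands=((0, 0),), branch_count=7)])
    assert seven.overall_supported


def test_internal_and_bulge_typing():
    seq = RnaSequence("GGGCGGGAAAACCCACCC")
    # outer helix (0..2 with 15..17), bulge A at 14? construct:
    pairs = [(0, 17), (1, 16), (2, 15), (4, 13), (5, 12), (6, 11)]
    motifs = decompose(seq, SecondaryStructure(pairs))
    loop_kinds = [m.kind for m in motifs if "loop" in m.kind.value or m.kind is MotifKind.BULGE]
    assert MotifKind.INTERNAL_LOOP in loop_kinds or MotifKind.BULGE in loop_kinds


def test_pseudoknot_motif_supported():
    f = pseudoknot()
    motifs = decompose(f.sequence, f.structure)
    assert MotifKind.PSEUDOKNOT in {m.kind for m in motifs}
    assert eligibility(motifs, n=len(f.sequence)).overall_supported


def test_every_nucleotide_covered():
    """Round trip: helix + loop memberships cover 1..N."""
    seq = RnaSequence("AAGGGAAAACCCAGGGAAAACCCAA")
    pairs = [(2, 11), (3, 10), (4, 9), (13, 22), (14, 21), (15, 20)]
    motifs = decompose(seq, SecondaryStructure(pairs))
    covered = set()
    for m in motifs:
        covered.update(m.positions())
    assert covered == set(range(len(seq)))


def test_palindrome_decomposition_symmetric():
    """Relabeling 5'<->3' of a palindromic fixture permutes but does not
    change the motif-kind multiset."""
    seq = "GGGGAAACCCCAAAGGGG"
    pairs1 = [(0, 10), (1, 9), (2, 8), (3, 7)]
    n = len(seq)
    pairs2 = [(n - 1 - j, n - 1 - i) for (i, j) in pairs1]
    m1 = decompose(RnaSequence(seq), SecondaryStructure(pairs1))
    m2 = decompose(RnaSequence(seq[::-1]), SecondaryStructure(pairs2))
    assert kinds(m1) == kinds(m2)


def test_nested_tail_free_structures_use_closed_vocabulary():
    """Without tails, every motif is a helix or a closed loop type."""
    seq = RnaSequence("GGGGGAAAACCCAACCGGCC")
    pairs = [(0, 19), (1, 18), (2, 11), (3, 10), (4, 9)]
    motifs = decompose(seq, SecondaryStructure(pairs))
    allowed = {
        MotifKind.HELIX,
        MotifKind.HAIRPIN_LOOP,
        MotifKind.INTERNAL_LOOP,
        MotifKind.BULGE,
        MotifKind.NWAY_JUNCTION,
    }
    assert {m.kind for m in motifs} <= allowed
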