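"""Fixture generators and text I/O round trips."""

import numpy as np
import pytest

from rnamelt import io as rio
from rnamelt.fixtures import (
    FixtureError,
    FixtureKind,
    FixtureSpec,
    bistable,
    hairpin,
    make_fixture,
    pseudoknot,
    random_sequence,
)
from rnamelt.fold2d import fold
from rnamelt.sequence import RnaSequence, SequenceError
from rnamelt.structures import SecondaryStructure
from rnamelt.thermal import heat_capacity, melting_curve, partition_over_temperature


def test_hairpin_fixture_direct_construction():
    f = hairpin(3, 4)
    assert str(f.sequence) == "GGGAAAACCC"
    assert sorted(f.structure.pairs) == [(0, 9), (1, 8), (2, 7)]


def test_fixture_structures_are_valid_for_their_sequences():
    for f in (hairpin(), bistable(), pseudoknot()):
        f.structure.check_sequence(f.sequence)  # must not raise


def test_random_fixture_is_seed_deterministic():
    a = random_sequence(30, seed=11)
    b = random_sequence(30, seed=11)
    c = random_sequence(30, seed=12)
    assert str(a.sequence) == str(b.sequence)
    assert str(a.sequence) != str(c.sequence)


def test_impossible_sizes_raise_generation_error():
    with pytest.raises(FixtureError):
        hairpin(stem=1)
    with pytest.raises(FixtureError):
        make_fixture(FixtureSpec(FixtureKind.BISTABLE, stem=4, loop=2))
    with pytest.raises(FixtureError):
        pseudoknot(stem=1)


def test_sequence_normalization():
    assert str(rio.read_sequence("acgu")) == "ACGU"
    assert str(rio.read_sequence("ACGT")) == "ACGU"  # DNA alphabet folded in
    assert str(rio.read_sequence(">x\nGGG\nCCC\n")) == "GGGCCC"
    with pytest.raises(SequenceError, match="position 3"):
        rio.read_sequence("GGXCC")


def test_fasta_file_round_trip(tmp_path):
    p = tmp_path / "seq.fa"
    p.write_text(rio.write_fasta(RnaSequence("GGGAAAACCC"), "hairpin"))
    assert str(rio.read_sequence(p)) == "GGGAAAACCC"


def test_ct_round_trip_reproduces_pairs(tmp_path):
    f = bistable()
    text = rio.write_ct(f.sequence, f.structure)
    seq, s = rio.read_ct(text)
    assert str(seq) == str(f.sequence)
    assert s.pairs == f.structure.pairs
    assert rio.write_ct(seq, s) == text  # byte-identical rewrite


def test_dotbracket_round_trip_with_pseudoknot_layers():
    f = pseudoknot()
    db = rio.structure_to_dotbracket(len(f.sequence), f.structure)
    assert "[" in db  # the crossing stem goes to the second layer
    back = rio.parse_dotbracket(db)
    assert back.pairs == f.structure.pairs


def test_dotbracket_rejects_unbalanced():
    with pytest.raises(ValueError):
        rio.parse_dotbracket("((..)")
    with pytest.raises(ValueError):
        rio.parse_dotbracket("..a..")


def test_output_files_round_trip_byte_identically():
    r = fold("GGGGAAAACCCC")
    bpp_text = rio.write_bpp(r)
    entries = rio.read_bpp(bpp_text)
    rewritten = "\n".join(
        ["# i\tj\tP_ij"] + [f"{i}\t{j}\t{p:.4f}" for (i, j, p) in entries]
    ) + "\n"
    assert rewritten == bpp_text

    hel_text = rio.write_helices(r.helices)
    hel = rio.read_helices(hel_text)
    rewritten = "\n".join(
        ["# i\tj\tlength\tP"] + [f"{i}\t{j}\t{k}\t{p:.4f}" for (i, j, k, p) in hel]
    ) + "\n"
    assert rewritten == hel_text


def test_melting_text_round_trip():
    curve = partition_over_temperature("GGGGAAAACCCC", 20, 30, 1)
    heat_capacity(curve)
    text = rio.write_melting(curve)
    ts, cs = rio.read_melting(text)
    assert len(ts) == len(curve.inner_grid)
    rewritten = "\n".join(
        ["# T_celsius\tC_kcal_mol_K"] + [f"{t:.2f}\t{c:.6f}" for t, c in zip(ts, cs)]
    ) + "\n"
    assert rewritten == text
    qt = rio.write_lnq(curve)
    t2, q2 = rio.read_melting(qt)
    assert np.allclose(q2, curve.lnQ, atol=1e-6)


def test_writers_are_deterministic():
    r1 = fold("GGGGAAAACCCC")
    r2 = fold("GGGGAAAACCCC")
    assert rio.write_bpp(r1) == rio.write_bpp(r2)
    assert rio.write_structures(r1) == rio.write_structures(r2)


def test_structures_file_contains_dominant_dotbracket():
    r = fold("GGGGAAAACCCC")
    text = rio.write_structures(r)
    assert "((((....))))" in text


def test_cli_smoke(tmp_path):
    from click.testing import CliRunner

    from rnamelt.cli import main

    runner = CliRunner()
    out = runner.invoke(main, ["fold2d", "--seq", "GGGAAAACCC",
                               "--out-prefix", str(tmp_path / "hp")])
    assert out.exit_code == 0, out.output
    assert (tmp_path / "hp.bpp.txt").exists()
    out = runner.invoke(main, ["motifs", "--seq", "GGGAAAACCC",
                               "--structure", "(((....)))"])
    assert out.exit_code == 0, out.output
    assert "overall_supported: True" in out.output
    out = runner.invoke(main, ["thermal", "--seq", "GGGAAAACCC",
                               "--tmin", "80", "--tmax", "90", "--tstep", "1"])
    assert out.exit_code == 0, out.output
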