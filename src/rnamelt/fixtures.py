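"""Deterministic sequence generators for tests and demos.

The designed fixtures emulate the classes of molecules the ensemble
model is meant to resolve: single stem-loops, bistable sequences with
two mutually exclusive helices built from overlapping complementary
blocks, and toy H-type pseudoknots.  Identical spec (and seed, for
RANDOM) always yields the identical sequence.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from enum import Enum

from rnamelt.params import MIN_HAIRPIN_LOOP
from rnamelt.sequence import RnaSequence
from rnamelt.structures import SecondaryStructure


class FixtureError(ValueError):
    """Impossible size combination for a fixture."""


class FixtureKind(str, Enum):
    HAIRPIN = "hairpin"
    BISTABLE = "bistable"
    PSEUDOKNOT = "pseudoknot"
    RANDOM = "random"


@dataclass(frozen=True)
class FixtureSpec:
    """Sizes and (for RANDOM) the seed of one generated fixture."""

    kind: FixtureKind
    stem: int = 4
    loop: int = 4
    stem2: int | None = None  #: second stem (bistable/pseudoknot); default = stem
    junction: int = 1  #: pseudoknot inter-helix junction length
    loop2: int | None = None  #: second loop; default = loop
    anchor_stem: int = 0  #: bistable only: independent GC hairpin prepended
    length: int = 20  #: RANDOM only
    seed: int = 0  #: RANDOM only


@dataclass(frozen=True)
class Fixture:
    spec: FixtureSpec
    sequence: RnaSequence
    structure: SecondaryStructure | None  #: the intended (annotated) structure
    note: str = ""


def _check(cond, msg):
    if not cond:
        raise FixtureError(msg)


def _rc(s: str) -> str:
    return s[::-1].translate(str.maketrans("ACGU", "UGCA"))


def _cycle(pattern: str, k: int) -> str:
    return (pattern * (k // len(pattern) + 1))[:k]


#: sizes of the bistable melting-study fixture: GC anchor (high-Tm peak),
#: 6-bp AU arms with asymmetric loops (one dominant + one alternative helix,
#: low-Tm peak)
STUDY_BISTABLE = dict(stem=6, loop=3, loop2=5, anchor_stem=5)


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Build the sequence (and intended structure) for a fixture spec."""
    k = FixtureKind(spec.kind)
    if k is FixtureKind.HAIRPIN:
        _check(spec.stem >= 2, "hairpin stem must be >= 2 bp")
        _check(spec.loop >= MIN_HAIRPIN_LOOP, "hairpin loop must be >= 3 nt")
        seq = "G" * spec.stem + "A" * spec.loop + "C" * spec.stem
        n = len(seq)
        pairs = [(i, n - 1 - i) for i in range(spec.stem)]
        return Fixture(spec, RnaSequence(seq), SecondaryStructure(pairs),
                       note="GC stem-loop")

    if k is FixtureKind.BISTABLE:
        stem2 = spec.stem2 if spec.stem2 is not None else spec.stem
        loop2 = spec.loop2 if spec.loop2 is not None else spec.loop
        _check(spec.stem >= 2 and stem2 >= 2, "bistable stems must be >= 2 bp")
        _check(stem2 <= spec.stem, "second stem cannot exceed the shared block")
        _check(min(spec.loop, loop2) >= MIN_HAIRPIN_LOOP, "loops must be >= 3 nt")
        _check(spec.anchor_stem == 0 or spec.anchor_stem >= 2,
               "anchor stem must be 0 or >= 2 bp")
        prefix = ""
        pairs = []
        if spec.anchor_stem:
            # an independent GC-rich hairpin whose melting sits high in the
            # 0-100 C window; the AU-rich arms below melt much lower, so the
            # two transitions resolve as separate heat-capacity peaks
            a = spec.anchor_stem
            arm = ("G" * max(a - 3, 1) + "CAU")[:a]
            prefix = arm + "A" * MIN_HAIRPIN_LOOP + _rc(arm) + "AA"
            pairs += [(i, 2 * a + MIN_HAIRPIN_LOOP - 1 - i) for i in range(a)]
            shared = _cycle("AAUUAU", spec.stem)  # AU-rich: melts inside window
        else:
            shared = "C" * spec.stem  # GC arms; palindromic when symmetric
        off = len(prefix)
        # helix 1: rc(shared) vs the shared block; helix 2: shared vs its
        # (possibly truncated) reverse complement further 3'
        seq = (
            prefix
            + _rc(shared)
            + "A" * spec.loop
            + shared
            + "A" * loop2
            + _rc(shared)[:stem2]
        )
        top = off + 2 * spec.stem + spec.loop - 1  # last nt of the shared block
        pairs += [(off + i, top - i) for i in range(spec.stem)]
        return Fixture(
            spec,
            RnaSequence(seq),
            SecondaryStructure(pairs),
            note="two mutually exclusive helices sharing one block; the "
            "annotated structure uses the first (more stable) helix",
        )

    if k is FixtureKind.PSEUDOKNOT:
        s1 = spec.stem
        s2 = spec.stem2 if spec.stem2 is not None else spec.stem
        l1 = spec.loop
        l2 = spec.junction
        l3 = spec.loop2 if spec.loop2 is not None else spec.loop + 1
        _check(s1 >= 2 and s2 >= 2, "pseudoknot stems must be >= 2 bp")
        _check(l1 >= 1 and l3 >= 1 and l2 >= 0, "pseudoknot loops must be >= 1 nt")
        seq = "G" * s1 + "A" * l1 + "G" * s2 + "A" * l2 + "C" * s1 + "A" * l3 + "C" * s2
        n = len(seq)
        qa = s1 + l1 + s2 + l2 + s1 - 1  # 3' end of stem-1's C block
        pairs = [(i, qa - i) for i in range(s1)]
        pb = s1 + l1
        pairs += [(pb + i, n - 1 - i) for i in range(s2)]
        return Fixture(spec, RnaSequence(seq), SecondaryStructure(pairs),
                       note="toy H-type pseudoknot (two crossing GC stems)")

    if k is FixtureKind.RANDOM:
        _check(spec.length >= 1, "length must be positive")
        rng = random.Random(spec.seed)
        seq = "".join(rng.choice("ACGU") for _ in range(spec.length))
        return Fixture(spec, RnaSequence(seq), None, note=f"seed={spec.seed}")

    raise FixtureError(f"unknown fixture kind {spec.kind}")


def hairpin(stem=4, loop=4) -> Fixture:
    return make_fixture(FixtureSpec(FixtureKind.HAIRPIN, stem=stem, loop=loop))


def bistable(stem=4, loop=3, stem2=None, loop2=None, anchor_stem=0) -> Fixture:
    return make_fixture(
        FixtureSpec(
            FixtureKind.BISTABLE,
            stem=stem, loop=loop, stem2=stem2, loop2=loop2, anchor_stem=anchor_stem,
        )
    )


def pseudoknot(stem=3, loop=3, junction=1, stem2=None, loop2=None) -> Fixture:
    return make_fixture(
        FixtureSpec(
            FixtureKind.PSEUDOKNOT,
            stem=stem, loop=loop, junction=junction, stem2=stem2, loop2=loop2,
        )
    )


def random_sequence(length=20, seed=0) -> Fixture:
    return make_fixture(FixtureSpec(FixtureKind.RANDOM, length=length, seed=seed))


__all__ = [
    "FixtureError",
    "FixtureKind",
    "FixtureSpec",
    "Fixture",
    "make_fixture",
    "hairpin",
    "bistable",
    "pseudoknot",
    "random_sequence",
]
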