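"""Secondary structures: base-pair sets, helix runs, validity, pseudoknots.

A secondary structure is a set of base pairs (i, j), i < j, 0-based.
Structural rules enforced here:

* each position pairs at most once;
* hairpin loops contain at least 3 unpaired nucleotides (j - i >= 4);
* every pair belongs to a helix run of >= 2 consecutive stacked pairs
  (isolated pairs carry no stack energy in this model and are treated as
  intra-loop mismatches instead);
* pairs either nest, or form a single H-type pseudoknot: exactly two
  crossing helix runs with all three connecting loops unpaired and all
  other helices strictly outside the pseudoknotted span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from rnamelt.params import MIN_HAIRPIN_LOOP, pair_ok
from rnamelt.sequence import RnaSequence


class InvalidStructureError(ValueError):
    """Pair set violates the structural rules."""


class PseudoknotMode(str, Enum):
    """Which structures enter the ensemble."""

    NONE = "none"  #: nested structures only
    JUNCTION_LE_1 = "junction1"  #: + H-type pseudoknots, inter-helix junction <= 1 nt
    ANY_JUNCTION = "any"  #: + H-type pseudoknots with any junction length

    @property
    def max_junction(self):
        if self is PseudoknotMode.NONE:
            return -1
        if self is PseudoknotMode.JUNCTION_LE_1:
            return 1
        return None


def helix_runs(pairs) -> list[tuple[int, int, int]]:
    """Maximal runs (p, q, k): pairs (p+t, q-t) for t = 0..k-1, sorted by p."""
    ps = set(map(tuple, pairs))
    runs = []
    for (i, j) in sorted(ps):
        if (i - 1, j + 1) in ps:
            continue  # not the outer pair of its run
        k = 1
        while (i + k, j - k) in ps:
            k += 1
        runs.append((i, j, k))
    return runs


def crossing(a: tuple[int, int], b: tuple[int, int]) -> bool:
    (i, j), (ip, jp) = sorted((tuple(a), tuple(b)))
    return i < ip < j < jp


def runs_cross(r1, r2) -> bool:
    return crossing((r1[0], r1[1]), (r2[0], r2[1]))


@dataclass(frozen=True)
class HTypeGeometry:
    """The two crossing stems and three loops of an H-type pseudoknot."""

    stem1: tuple[int, int, int]  # (p, q, k), 5'-most stem
    stem2: tuple[int, int, int]
    loop1: int  # 5' loop, bridges stem2
    junction: int  # inter-helix junction
    loop3: int  # 3' loop, bridges stem1

    @property
    def span(self) -> tuple[int, int]:
        return self.stem1[0], self.stem2[1]


def classify_h_type(run1, run2) -> HTypeGeometry | None:
    """H-type geometry of two crossing runs, or None if not H-type."""
    (pa, qa, ka), (pb, qb, kb) = sorted((tuple(run1), tuple(run2)))
    if not crossing((pa, qa), (pb, qb)):
        return None
    l1 = pb - (pa + ka - 1) - 1
    l2 = (qa - ka + 1) - (pb + kb - 1) - 1
    l3 = (qb - kb + 1) - qa - 1
    if min(l1, l2, l3) < 0:
        return None
    return HTypeGeometry((pa, qa, ka), (pb, qb, kb), l1, l2, l3)


@dataclass(frozen=True)
class SecondaryStructure:
    """An immutable base-pair set with derived helix/pseudoknot structure."""

    pairs: frozenset
    pseudoknotted: bool = field(init=False)

    def __init__(self, pairs, validate_runs: bool = True):
        norm = frozenset((int(i), int(j)) if i < j else (int(j), int(i)) for i, j in pairs)
        object.__setattr__(self, "pairs", norm)
        seen: dict[int, tuple] = {}
        for i, j in norm:
            for x in (i, j):
                if x in seen:
                    raise InvalidStructureError(f"position {x + 1} pairs more than once")
                seen[x] = (i, j)
        for i, j in norm:
            if j - i - 1 < MIN_HAIRPIN_LOOP and not any(
                i < x < j for x in seen if x not in (i, j)
            ):
                raise InvalidStructureError(
                    f"pair ({i + 1},{j + 1}) closes a hairpin of "
                    f"{j - i - 1} < {MIN_HAIRPIN_LOOP} nt"
                )
        runs = helix_runs(norm)
        if validate_runs:
            for p, q, k in runs:
                if k < 2:
                    raise InvalidStructureError(
                        f"isolated pair ({p + 1},{q + 1}): helices need >= 2 stacked pairs"
                    )
        cross_pairs = [
            (r1, r2) for a, r1 in enumerate(runs) for r2 in runs[a + 1:] if runs_cross(r1, r2)
        ]
        object.__setattr__(self, "pseudoknotted", bool(cross_pairs))
        if cross_pairs:
            if len(cross_pairs) > 1:
                raise InvalidStructureError("more than one crossing helix pair (not H-type)")
            geo = classify_h_type(*cross_pairs[0])
            if geo is None:
                raise InvalidStructureError("crossing helices do not form an H-type geometry")
            lo, hi = geo.span
            for p, q, k in runs:
                if (p, q, k) in (geo.stem1, geo.stem2):
                    continue
                inside = lo <= p <= hi or lo <= q <= hi
                enclosing = p < lo and q > hi
                if inside or enclosing:
                    raise InvalidStructureError(
                        "additional helices inside or enclosing the pseudoknot span"
                    )

    # -- derived views ------------------------------------------------------

    def runs(self) -> list[tuple[int, int, int]]:
        return helix_runs(self.pairs)

    def h_type(self) -> HTypeGeometry | None:
        if not self.pseudoknotted:
            return None
        runs = self.runs()
        for a, r1 in enumerate(runs):
            for r2 in runs[a + 1:]:
                if runs_cross(r1, r2):
                    return classify_h_type(r1, r2)
        return None  # pragma: no cover

    def partner(self) -> dict[int, int]:
        out = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out

    def check_sequence(self, seq: RnaSequence) -> None:
        """Validate that every pair is an allowed pair type for this sequence."""
        n = len(seq)
        for i, j in self.pairs:
            if not (0 <= i < j < n):
                raise InvalidStructureError(f"pair ({i + 1},{j + 1}) outside 1..{n}")
            if not pair_ok(seq[i], seq[j]):
                raise InvalidStructureError(
                    f"disallowed pair {seq[i]}{i + 1}-{seq[j]}{j + 1}"
                )

    def __len__(self) -> int:
        return len(self.pairs)


__all__ = [
    "InvalidStructureError",
    "PseudoknotMode",
    "SecondaryStructure",
    "HTypeGeometry",
    "helix_runs",
    "crossing",
    "runs_cross",
    "classify_h_type",
]
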