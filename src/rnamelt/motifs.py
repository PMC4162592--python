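"""Motif decomposition of a 2D structure and template eligibility.

Template-based 3D assembly works at the granularity of structural
motifs: helices, hairpin loops, internal/bulge loops, N-way junctions
and pseudoknots.  Single-stranded tails and strands connecting helices
that share no closing pair are *open motifs*, for which no structural
templates exist; a structure containing one is flagged ineligible, and
removing the tails is recommended before any template lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from rnamelt.sequence import RnaSequence
from rnamelt.structures import SecondaryStructure


class MotifKind(str, Enum):
    HELIX = "helix"
    HAIRPIN_LOOP = "hairpin_loop"
    INTERNAL_LOOP = "internal_loop"
    BULGE = "bulge"
    NWAY_JUNCTION = "nway_junction"
    PSEUDOKNOT = "pseudoknot"
    OPEN_MOTIF = "open_motif"


@dataclass(frozen=True)
class Motif:
    """A structural unit: its kind, strand intervals and closing pairs.

    ``strands`` are 0-based inclusive (start, end) intervals; an empty
    strand (zero-length junction/linker) is stored as (start, start - 1).
    ``branch_count`` counts helices meeting at a junction (closing helix
    included).
    """

    kind: MotifKind
    strands: tuple
    closing_pairs: tuple = ()
    branch_count: int | None = None

    def positions(self):
        out = []
        for (a, b) in self.strands:
            out.extend(range(a, b + 1))
        return out


def decompose(seq: RnaSequence, s: SecondaryStructure) -> list[Motif]:
    """Unique motif decomposition of a structure.

    Every nucleotide lands in at least one motif: helix nucleotides in
    their helix, loop nucleotides in exactly one loop motif, exterior
    single strands (tails, inter-helix linkers) in open motifs.
    """
    seq = seq if isinstance(seq, RnaSequence) else RnaSequence.parse(seq)
    s.check_sequence(seq)
    n = len(seq)
    runs = s.runs()
    partner = s.partner()
    motifs: list[Motif] = []

    geo = s.h_type()
    pk_stems = set()
    if geo is not None:
        pk_stems = {geo.stem1, geo.stem2}
        (pa, qa, ka), (pb, qb, kb) = geo.stem1, geo.stem2
        loops = (
            (pa + ka, pb - 1),
            (pb + kb, qa - ka),
            (qa + 1, qb - kb),
        )
        motifs.append(
            Motif(
                MotifKind.PSEUDOKNOT,
                strands=tuple(loops),
                closing_pairs=((pa, qa), (pb, qb)),
            )
        )

    for (p, q, k) in runs:
        motifs.append(
            Motif(
                MotifKind.HELIX,
                strands=((p, p + k - 1), (q - k + 1, q)),
                closing_pairs=((p, q),),
            )
        )

    # loops enclosed by each nested helix
    for (p, q, k) in runs:
        if (p, q, k) in pk_stems:
            continue
        P, Q = p + k - 1, q - k + 1
        children = []
        x = P + 1
        while x < Q:
            if x in partner and partner[x] > x:
                children.append((x, partner[x]))
                x = partner[x] + 1
            else:
                x += 1
        if not children:
            motifs.append(
                Motif(
                    MotifKind.HAIRPIN_LOOP,
                    strands=((P + 1, Q - 1),),
                    closing_pairs=((P, Q),),
                )
            )
        elif len(children) == 1:
            (a, b) = children[0]
            s1, s2 = a - P - 1, q - k + 1 - b - 1
            kind = MotifKind.INTERNAL_LOOP if (s1 > 0 and s2 > 0) else MotifKind.BULGE
            motifs.append(
                Motif(
                    kind,
                    strands=((P + 1, a - 1), (b + 1, Q - 1)),
                    closing_pairs=((P, Q), (a, b)),
                )
            )
        else:
            strands = []
            prev = P
            for (a, b) in children:
                strands.append((prev + 1, a - 1))
                prev = b
            strands.append((prev + 1, Q - 1))
            motifs.append(
                Motif(
                    MotifKind.NWAY_JUNCTION,
                    strands=tuple(strands),
                    closing_pairs=((P, Q),) + tuple(children),
                    branch_count=len(children) + 1,
                )
            )

    # exterior: tails and linkers between top-level elements
    top = []
    if geo is not None:
        top.append(geo.span)
    for (p, q, k) in runs:
        if (p, q, k) in pk_stems:
            continue
        enclosed = any(
            (a < p and q < b) for (a, b, kk) in runs if (a, b, kk) != (p, q, k)
        ) or (geo is not None and geo.span[0] < p and q < geo.span[1])
        if not enclosed:
            top.append((p, q))
    top.sort()
    prev_end = -1
    boundaries = top + [(n, n)]
    for (a, b) in boundaries:
        start, end = prev_end + 1, a - 1
        is_tail = prev_end == -1 or a == n
        # nonempty tail/linker, or a zero-length strand between tandem
        # helices (which share no closing pair, so no template either)
        if end >= start or not is_tail:
            motifs.append(Motif(MotifKind.OPEN_MOTIF, strands=((start, end),)))
        prev_end = max(prev_end, b)
    return motifs


@dataclass
class EligibilityReport:
    """Per-motif template support and the overall verdict."""

    motifs: list
    supported: list  # parallel booleans
    overall_supported: bool
    notes: list = field(default_factory=list)


#: junction arities with known templates: 2 < N < 8
MIN_JUNCTION_BRANCHES = 3
MAX_JUNCTION_BRANCHES = 7


def eligibility(motifs: list[Motif], n: int | None = None) -> EligibilityReport:
    """Which motifs have structural templates; overall = all supported."""
    supported = []
    notes = []
    for m in motifs:
        ok = m.kind is not MotifKind.OPEN_MOTIF
        if m.kind is MotifKind.NWAY_JUNCTION:
            ok = MIN_JUNCTION_BRANCHES <= m.branch_count <= MAX_JUNCTION_BRANCHES
            if not ok:
                notes.append(
                    f"{m.branch_count}-way junction outside the templated "
                    f"range {MIN_JUNCTION_BRANCHES}..{MAX_JUNCTION_BRANCHES}"
                )
        supported.append(ok)
    tails = [
        m
        for m in motifs
        if m.kind is MotifKind.OPEN_MOTIF
        and m.strands
        and (m.strands[0][0] == 0 or (n is not None and m.strands[0][1] == n - 1))
    ]
    if tails:
        notes.append("remove the single-stranded tails before template assembly")
    linkers = [m for m in motifs if m.kind is MotifKind.OPEN_MOTIF and m not in tails]
    if linkers:
        notes.append("no templates for single strands connecting independent helices")
    return EligibilityReport(
        motifs=list(motifs),
        supported=supported,
        overall_supported=all(supported) if motifs else True,
        notes=notes,
    )


__all__ = [
    "MotifKind",
    "Motif",
    "decompose",
    "EligibilityReport",
    "eligibility",
    "MIN_JUNCTION_BRANCHES",
    "MAX_JUNCTION_BRANCHES",
]
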