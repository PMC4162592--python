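"""Loop-entropy tables: exact enumeration, extrapolation, mismatch splitting.

Entropies are stored dimensionless, in units of the gas constant R:

    dS_loop / R = ln( Omega_closed / Omega_open )

where the Omegas are the lattice conformation counts from
:mod:`rnamelt.lattice`.  They are multiplied by R only when converted to
free energies.  A loop whose closure cannot be realized on the lattice
(Omega_closed = 0) is recorded as unformable and reported as
``-inf`` (weight zero, dG = +inf).

Loops larger than the exact-enumeration cap are extrapolated with the
polymer-theory closure form dS(L) = a - c * ln L (Jacobson-Stockmayer),
fitted to the enumerated series of the same loop type.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from rnamelt.lattice import (
    DEFAULT_ENUMERATION_CAP,
    ConformationCount,
    EnumerationCapError,
    Provenance,
    UnformableLoopError,
    enumerate_loop,
)
from rnamelt.params import LoopType

log = logging.getLogger(__name__)

UNFORMABLE = float("-inf")


def loop_entropy(count: ConformationCount) -> float:
    """dS_loop in units of R from exact conformation counts.

    Raises :class:`UnformableLoopError` when no closed conformation exists
    (callers treat that loop as dG = +inf).
    """
    if count.omega_closed == 0:
        raise UnformableLoopError(
            f"{count.loop_type.value} loop {count.sizes} has no closed conformation"
        )
    return math.log(count.omega_closed / count.omega_open)


class FitError(ValueError):
    """Too few enumerated entries to fit the extrapolation form."""


def _norm_key(loop_type: LoopType, sizes) -> tuple[LoopType, tuple[int, ...]]:
    loop_type = LoopType(loop_type)
    sizes = tuple(int(s) for s in sizes)
    if loop_type is LoopType.BULGE:
        loop_type = LoopType.INTERNAL
        if len(sizes) == 1:
            sizes = (0, sizes[0])
    if loop_type is LoopType.INTERNAL:
        sizes = tuple(sorted(sizes))
    return loop_type, sizes


@dataclass
class LoopEntropyTable:
    """Map (loop_type, sizes) -> dS/R with per-entry provenance.

    Enumerated entries always take precedence; sizes outside the table are
    extrapolated on demand (and cached with EXTRAPOLATED provenance).
    """

    entries: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)  # optional raw counts for audit
    _fits: dict = field(default_factory=dict, repr=False)

    # -- construction -------------------------------------------------------

    def add_count(self, count: ConformationCount) -> None:
        key = _norm_key(count.loop_type, count.sizes)
        ds = UNFORMABLE if count.omega_closed == 0 else math.log(
            count.omega_closed / count.omega_open
        )
        self.entries[key] = (ds, Provenance.ENUMERATED)
        self.counts[key] = (count.omega_closed, count.omega_open)
        self._fits.clear()

    # -- lookup -------------------------------------------------------------

    def lookup(self, loop_type: LoopType, sizes):
        """(dS/R, provenance) for an exact or previously cached entry, or None."""
        return self.entries.get(_norm_key(loop_type, sizes))

    def entropy(self, loop_type: LoopType, sizes) -> float:
        """dS/R for any size: enumerated entry if present, else extrapolated."""
        hit = self.lookup(loop_type, sizes)
        if hit is not None:
            return hit[0]
        return extrapolate_entropy(self, loop_type, sizes)

    def hairpin_fit(self) -> tuple[float, float]:
        """(a, c) of the hairpin closure fit dS/R = a - c*ln(L)."""
        return _get_fit(self, "hairpin")

    def enumerated_items(self, loop_type: LoopType):
        lt = LoopType(loop_type)
        if lt is LoopType.BULGE:
            lt = LoopType.INTERNAL
        return sorted(
            (sizes, ds)
            for (t, sizes), (ds, prov) in self.entries.items()
            if t is lt and prov is Provenance.ENUMERATED and ds != UNFORMABLE
        )

    # -- serialization ------------------------------------------------------

    HEADER = "# loop_type\tsizes\tomega_closed\tomega_open\tdS_over_R\tprovenance"

    def to_tsv(self) -> str:
        buf = io.StringIO()
        print(self.HEADER, file=buf)
        for key in sorted(self.entries, key=lambda k: (k[0].value, k[1])):
            ds, prov = self.entries[key]
            oc, oo = self.counts.get(key, ("", ""))
            dss = "unformable" if ds == UNFORMABLE else repr(ds)
            sizes = ",".join(str(s) for s in key[1])
            print(f"{key[0].value}\t{sizes}\t{oc}\t{oo}\t{dss}\t{prov.value}", file=buf)
        return buf.getvalue()

    @classmethod
    def from_tsv(cls, text: str) -> "LoopEntropyTable":
        table = cls()
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            lt, sizes, oc, oo, ds, prov = line.split("\t")
            key = (LoopType(lt), tuple(int(s) for s in sizes.split(",")))
            dsv = UNFORMABLE if ds == "unformable" else float(ds)
            table.entries[key] = (dsv, Provenance(prov))
            if oc and oo:
                table.counts[key] = (int(oc), int(oo))
        return table


# ---------------------------------------------------------------------------
# extrapolation
# ---------------------------------------------------------------------------


def _js_fit(points) -> tuple[float, float]:
    """Fit dS = a - c * ln(x) to (x, dS) pairs; returns (a, c)."""
    if len(points) < 4:
        raise FitError(f"need >= 4 enumerated sizes to fit, got {len(points)}")
    x = np.log([p[0] for p in points])
    y = np.array([p[1] for p in points])
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept), float(-slope)


def _get_fit(table: LoopEntropyTable, kind: str):
    if kind in table._fits:
        return table._fits[kind]
    if kind == "hairpin":
        pts = [(L, ds) for (L,), ds in table.enumerated_items(LoopType.HAIRPIN) if L >= 3]
        fit = _js_fit(pts)
    elif kind == "internal":
        pts = [
            (sum(sizes), ds)
            for sizes, ds in table.enumerated_items(LoopType.INTERNAL)
            if sum(sizes) >= 1
        ]
        fit = _js_fit(pts)
    elif kind == "pk":
        # global surface dS ~ b0 + b1*ln(l+1) + b2*span over formable entries
        pts = [(l, span, ds) for (l, span), ds in table.enumerated_items(LoopType.PK_LOOP)]
        if len(pts) < 4:
            raise FitError("need >= 4 enumerated pseudoknot-loop entries")
        A = np.array([[1.0, math.log(l + 1), span] for l, span, _ in pts])
        y = np.array([ds for _, _, ds in pts])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        fit = tuple(float(c) for c in coef)
    else:  # pragma: no cover
        raise ValueError(kind)
    table._fits[kind] = fit
    return fit


def extrapolate_entropy(table: LoopEntropyTable, loop_type: LoopType, sizes) -> float:
    """Jacobson-Stockmayer-form extrapolation beyond the enumerated range."""
    loop_type, sizes = _norm_key(loop_type, sizes)
    hit = table.entries.get((loop_type, sizes))
    if hit is not None:  # enumerated entries take precedence, always
        return hit[0]

    if loop_type is LoopType.HAIRPIN:
        a, c = _get_fit(table, "hairpin")
        ds = a - c * math.log(sizes[0]) if sizes[0] >= 3 else UNFORMABLE
    elif loop_type is LoopType.INTERNAL:
        total = sum(sizes)
        if total < 1:
            raise FitError("internal loop of total size 0 cannot be extrapolated")
        a, c = _get_fit(table, "internal")
        ds = a - c * math.log(total)
    elif loop_type is LoopType.PK_LOOP:
        l, span = sizes
        if l < span:  # the bridge cannot clear the helix's excluded volume
            ds = UNFORMABLE
        else:
            b0, b1, b2 = _get_fit(table, "pk")
            ds = b0 + b1 * math.log(l + 1) + b2 * span
            spans = {s for (_, s), _ in table.enumerated_items(LoopType.PK_LOOP)}
            if not spans or span > max(spans):
                log.warning(
                    "pseudoknot loop (l=%d, span=%d) beyond enumerated spans; "
                    "using independent-strand surface fit", l, span,
                )
        ds = min(ds, 0.0)
    else:  # pragma: no cover
        raise ValueError(loop_type)

    table.entries[(loop_type, sizes)] = (ds, Provenance.EXTRAPOLATED)
    return ds


# ---------------------------------------------------------------------------
# intra-loop mismatches
# ---------------------------------------------------------------------------


def mismatch_loop_entropy(
    loop_type: LoopType,
    sizes,
    mismatch_positions,
    table: LoopEntropyTable,
) -> float:
    """Entropy (dS/R) of a loop constrained by one intra-loop mismatch pair.

    The mismatched nucleotides are pinned to the lattice base-pair template,
    which factorizes the constrained enumeration into the two sub-loops the
    mismatch creates; the returned entropy is the sum of their entropies.
    Cross-sub-loop excluded volume is neglected (loop additivity at the
    constraint).  Never larger than the unconstrained loop entropy.

    Positions are 1-based within the loop:

    * hairpin ``(L,)``: one pair ``(u, v)`` of loop positions, ``u < v``;
      the enclosed segment ``v - u - 1`` must obey the minimum hairpin size.
    * internal ``(s1, s2)``: one pair ``(u, v)`` with ``u`` on strand 1 and
      ``v`` on strand 2, both counted from the outer closing pair.
    """
    loop_type = LoopType(loop_type)
    sizes = tuple(int(s) for s in sizes)
    if loop_type is LoopType.BULGE:
        loop_type = LoopType.INTERNAL
        if len(sizes) == 1:
            sizes = (0, sizes[0])
    # note: internal sizes keep their given strand order here, because the
    # mismatch positions refer to it (the table itself is orientation-free)
    mismatch_positions = list(mismatch_positions)
    if not mismatch_positions:
        return table.entropy(loop_type, sizes)
    if len(mismatch_positions) > 1:
        raise NotImplementedError("only single intra-loop mismatches are modelled")
    (u, v) = mismatch_positions[0]

    if loop_type is LoopType.HAIRPIN:
        (L,) = sizes
        if not (1 <= u < v <= L):
            raise ValueError(f"mismatch positions ({u},{v}) outside hairpin loop of {L}")
        enclosed = v - u - 1
        if enclosed < 3:
            raise UnformableLoopError(
                f"mismatch ({u},{v}) encloses {enclosed} nt < minimum hairpin size"
            )
        return table.entropy(LoopType.HAIRPIN, (enclosed,)) + table.entropy(
            LoopType.INTERNAL, (u - 1, L - v)
        )

    if loop_type is LoopType.INTERNAL:
        s1, s2 = sizes
        if not (1 <= u <= s1 and 1 <= v <= s2):
            raise ValueError(f"mismatch ({u},{v}) outside internal loop {sizes}")
        return table.entropy(LoopType.INTERNAL, (u - 1, v - 1)) + table.entropy(
            LoopType.INTERNAL, (s1 - u, s2 - v)
        )

    raise ValueError(f"mismatches are modelled for hairpin and internal loops, not {loop_type}")


# ---------------------------------------------------------------------------
# default table
# ---------------------------------------------------------------------------


def build_table(
    hairpin_max: int = DEFAULT_ENUMERATION_CAP,
    internal_total_max: int = 8,
    pk_span_max: int = 4,
    pk_l_max: int = 8,
) -> LoopEntropyTable:
    """Regenerate the loop-entropy table by exact enumeration (deterministic)."""
    table = LoopEntropyTable()
    table.add_count(
        ConformationCount(LoopType.INTERNAL, (0, 0), *_internal00())
    )
    for L in range(3, hairpin_max + 1):
        table.add_count(enumerate_loop(LoopType.HAIRPIN, (L,), max_size_cap=hairpin_max))
    for s1 in range(0, internal_total_max + 1):
        for s2 in range(s1, internal_total_max + 1 - s1):
            if s1 + s2 < 1:
                continue
            table.add_count(
                enumerate_loop(
                    LoopType.INTERNAL, (s1, s2), max_size_cap=internal_total_max
                )
            )
    for span in range(1, pk_span_max + 1):
        for l in range(0, pk_l_max + 1):
            table.add_count(
                enumerate_loop(LoopType.PK_LOOP, (l, span), max_size_cap=pk_l_max)
            )
    return table


def _internal00() -> tuple[int, int]:
    """Counts for the degenerate (0,0) 'internal loop' (mismatch on a helix end)."""
    from rnamelt.lattice import AXIS_VEC, PAIR_VEC, count_free_walks, count_strand_walks

    blocked = (
        (-AXIS_VEC[0], -AXIS_VEC[1], -AXIS_VEC[2]),
        (PAIR_VEC[0] - AXIS_VEC[0], PAIR_VEC[1] - AXIS_VEC[1], PAIR_VEC[2] - AXIS_VEC[2]),
        (2 * AXIS_VEC[0], 2 * AXIS_VEC[1], 2 * AXIS_VEC[2]),
        tuple(2 * a + p for a, p in zip(AXIS_VEC, PAIR_VEC)),
    )
    inner3 = tuple(a + p for a, p in zip(AXIS_VEC, PAIR_VEC))
    closed = count_strand_walks(
        2, (0, 0, 0), AXIS_VEC, blocked=blocked, second=(2, inner3, PAIR_VEC)
    )
    return closed, count_free_walks(2) ** 2


_DEFAULT_TABLE: LoopEntropyTable | None = None


def default_table() -> LoopEntropyTable:
    """The shipped pre-tabulated entropy table (loaded once per process)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        from importlib.resources import files

        text = files("rnamelt").joinpath("data/loop_entropy.tsv").read_text()
        _DEFAULT_TABLE = LoopEntropyTable.from_tsv(text)
    return _DEFAULT_TABLE


__all__ = [
    "UNFORMABLE",
    "loop_entropy",
    "FitError",
    "LoopEntropyTable",
    "extrapolate_entropy",
    "mismatch_loop_entropy",
    "build_table",
    "default_table",
]
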