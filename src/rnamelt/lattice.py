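"""Virtual-bond loop conformations on the diamond lattice.

The RNA backbone is coarse-grained to two virtual bonds per nucleotide
(P-C4' and C4'-P) and embedded on the diamond (tetrahedral) lattice,
whose 109.5-degree bond geometry matches the virtual-bond angles of
A-form RNA well.  Loop entropies follow from exhaustively counting
self-avoiding walks (SAWs) that satisfy the closure geometry imposed by
the closing helix, relative to unconstrained chains of the same length.

Lattice embedding
-----------------
Sites are integer triples with all three coordinates of equal parity.
Even-parity sites step along ``DIRS``; odd-parity sites along ``-DIRS``.
Every site has coordination number 4.

Closure templates (canonical, fixed once)
-----------------------------------------
* a base pair occupies two lattice vertices separated by ``PAIR_VEC``;
* successive pairs of a helix are translated by ``AXIS_VEC``;
* a strand of ``k`` unpaired nucleotides connecting two anchor vertices
  is a SAW of ``2*(k+1)`` bonds between them;
* one extra stacked pair of the closing helix is kept as excluded volume.

These templates are a declared stand-in for the full helix geometry: the
counts are exact for this lattice model, and all downstream contracts
(counts -> entropies -> free energies) are independent of the template
choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache

import numpy as np
from numba import njit

from rnamelt.params import LoopType

#: step vectors available from an even-parity site (negate for odd parity)
DIRS = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=np.int64)

#: displacement between the two vertices of a base pair
PAIR_VEC = (2, 2, 0)

#: displacement between successive base pairs along a helix
AXIS_VEC = (2, 0, 2)

#: largest total loop size (nt) enumerated exactly by default
DEFAULT_ENUMERATION_CAP = 10


class EnumerationCapError(ValueError):
    """Requested loop exceeds the exact-enumeration cap; extrapolate instead."""


class UnformableLoopError(ValueError):
    """No lattice conformation satisfies the closure constraints."""


class Provenance(str, Enum):
    ENUMERATED = "enumerated"
    EXTRAPOLATED = "extrapolated"


@dataclass(frozen=True)
class ConformationCount:
    """Exact conformation counts for one loop geometry."""

    loop_type: LoopType
    sizes: tuple[int, ...]
    omega_closed: int
    omega_open: int

    def __post_init__(self) -> None:
        if self.omega_open <= 0:
            raise ValueError("omega_open must be positive")
        if not (0 <= self.omega_closed <= self.omega_open):
            raise ValueError("need 0 <= omega_closed <= omega_open")


@dataclass(frozen=True)
class LatticeConformation:
    """One explicit virtual-bond chain (used for small-size inspection only)."""

    vertices: tuple[tuple[int, int, int], ...]
    closure: tuple[tuple[int, int, int], tuple[int, int, int]]

    def __post_init__(self) -> None:
        if len(set(self.vertices)) != len(self.vertices):
            raise ValueError("conformation is not self-avoiding")
        for a, b in zip(self.vertices, self.vertices[1:]):
            d = tuple(bi - ai for ai, bi in zip(a, b))
            sign = 1 if sum(a) % 2 == 0 else -1
            if not any(all(di == sign * v for di, v in zip(d, row)) for row in DIRS):
                raise ValueError(f"vertices {a} -> {b} are not lattice neighbors")


# ---------------------------------------------------------------------------
# numba DFS cores
# ---------------------------------------------------------------------------


@njit(cache=True)
def _dfs_strands(occ, G, off, n1, s1, t1, n2, s2, t2):
    """Count joint self-avoiding placements of one or two anchored strands.

    ``occ`` is a flattened G^3 occupancy grid pre-marked with anchors and
    excluded volume.  Strand vertices are marked while walking so a second
    strand automatically avoids the first.  ``n2 == 0`` with ``s2 == t2 == -1``
    means a single strand.  Returns the number of placements where each
    strand's final step lands exactly on its target.
    """
    G2 = G * G
    # decode targets
    t1x = t1 % G - off
    t1y = (t1 // G) % G - off
    t1z = t1 // G2 - off
    t2x = t2 % G - off if t2 >= 0 else 0
    t2y = (t2 // G) % G - off if t2 >= 0 else 0
    t2z = t2 // G2 - off if t2 >= 0 else 0

    ntot = n1 + n2
    px = np.empty(ntot + 2, dtype=np.int64)
    py = np.empty(ntot + 2, dtype=np.int64)
    pz = np.empty(ntot + 2, dtype=np.int64)
    ci = np.zeros(ntot + 2, dtype=np.int64)  # next direction index to try
    marked = np.zeros(ntot + 2, dtype=np.uint8)  # did we mark occ at this depth

    dirx = np.array([1, 1, -1, -1], dtype=np.int64)
    diry = np.array([1, -1, 1, -1], dtype=np.int64)
    dirz = np.array([1, -1, -1, 1], dtype=np.int64)

    px[0] = s1 % G - off
    py[0] = (s1 // G) % G - off
    pz[0] = s1 // G2 - off

    count = 0
    depth = 0
    while depth >= 0:
        if ci[depth] >= 4:
            # backtrack
            if marked[depth]:
                occ[(px[depth] + off) + G * (py[depth] + off) + G2 * (pz[depth] + off)] = False
                marked[depth] = 0
            ci[depth] = 0
            depth -= 1
            continue
        k = ci[depth]
        ci[depth] += 1

        # teleport bookkeeping: depth d means d steps taken overall
        if depth < n1:
            strand = 0
            local = depth  # steps taken within current strand
        else:
            strand = 1
            local = depth - n1

        # position to step from
        x = px[depth]
        y = py[depth]
        z = pz[depth]
        # all coords of a site share parity; odd sites step along -DIRS
        sign = 1 if (x % 2 + 2) % 2 == 0 else -1
        nx = x + sign * dirx[k]
        ny = y + sign * diry[k]
        nz = z + sign * dirz[k]

        if strand == 0:
            rem = n1 - local - 1
            tx, ty, tz = t1x, t1y, t1z
            nsteps_this = n1
        else:
            rem = n2 - local - 1
            tx, ty, tz = t2x, t2y, t2z
            nsteps_this = n2

        # pruning: per-coordinate reachability with parity
        dx = nx - tx
        if dx < 0:
            dx = -dx
        dy = ny - ty
        if dy < 0:
            dy = -dy
        dz = nz - tz
        if dz < 0:
            dz = -dz
        if dx > rem or dy > rem or dz > rem:
            continue
        if (rem - dx) % 2 != 0 or (rem - dy) % 2 != 0 or (rem - dz) % 2 != 0:
            continue

        flat = (nx + off) + G * (ny + off) + G2 * (nz + off)

        if rem == 0:
            # final step of this strand must land exactly on the target
            if nx == tx and ny == ty and nz == tz:
                if strand == 1 or n2 == 0:
                    count += 1
                else:
                    # start strand 2 from its anchor
                    depth += 1
                    px[depth] = s2 % G - off
                    py[depth] = (s2 // G) % G - off
                    pz[depth] = s2 // G2 - off
                    marked[depth] = 0
                    ci[depth] = 0
            continue

        if occ[flat]:
            continue
        occ[flat] = True
        depth += 1
        px[depth] = nx
        py[depth] = ny
        pz[depth] = nz
        marked[depth] = 1
        ci[depth] = 0

    return count


@njit(cache=True)
def _dfs_free(occ, G, off, n_steps, sx, sy, sz):
    """Count free SAW continuations of ``n_steps`` bonds from (sx, sy, sz)."""
    if n_steps <= 0:
        return 1
    G2 = G * G
    px = np.empty(n_steps + 2, dtype=np.int64)
    py = np.empty(n_steps + 2, dtype=np.int64)
    pz = np.empty(n_steps + 2, dtype=np.int64)
    ci = np.zeros(n_steps + 2, dtype=np.int64)
    marked = np.zeros(n_steps + 2, dtype=np.uint8)

    dirx = np.array([1, 1, -1, -1], dtype=np.int64)
    diry = np.array([1, -1, 1, -1], dtype=np.int64)
    dirz = np.array([1, -1, -1, 1], dtype=np.int64)

    px[0] = sx
    py[0] = sy
    pz[0] = sz

    count = 0
    depth = 0
    while depth >= 0:
        if ci[depth] >= 4:
            if marked[depth]:
                occ[(px[depth] + off) + G * (py[depth] + off) + G2 * (pz[depth] + off)] = False
                marked[depth] = 0
            ci[depth] = 0
            depth -= 1
            continue
        k = ci[depth]
        ci[depth] += 1
        x = px[depth]
        y = py[depth]
        z = pz[depth]
        sign = 1 if (x % 2 + 2) % 2 == 0 else -1
        nx = x + sign * dirx[k]
        ny = y + sign * diry[k]
        nz = z + sign * dirz[k]
        flat = (nx + off) + G * (ny + off) + G2 * (nz + off)
        if occ[flat]:
            continue
        if depth + 1 == n_steps:
            count += 1
            continue
        occ[flat] = True
        depth += 1
        px[depth] = nx
        py[depth] = ny
        pz[depth] = nz
        marked[depth] = 1
        ci[depth] = 0
    return count


# ---------------------------------------------------------------------------
# python-level wrappers
# ---------------------------------------------------------------------------


def _grid(max_steps: int):
    off = max_steps + 6
    G = 2 * off + 1
    occ = np.zeros(G * G * G, dtype=np.bool_)
    return occ, G, off


def _flat(v, G, off):
    return (v[0] + off) + G * (v[1] + off) + G * G * (v[2] + off)


def count_strand_walks(
    n_steps: int,
    start=(0, 0, 0),
    target=(0, 0, 0),
    blocked=(),
    second=None,
) -> int:
    """Exact count of anchored self-avoiding strand placements.

    ``second``, if given, is a tuple ``(n_steps2, start2, target2)`` for a
    jointly enumerated second strand (mutual avoidance included).
    """
    n2, s2, t2 = second if second is not None else (0, None, None)
    max_steps = n_steps + n2
    if n_steps == 0 and n2 == 0:
        return 1 if tuple(start) == tuple(target) else 0
    occ, G, off = _grid(max_steps)
    for b in blocked:
        occ[_flat(b, G, off)] = True
    occ[_flat(start, G, off)] = True
    occ[_flat(target, G, off)] = True
    if second is not None:
        occ[_flat(s2, G, off)] = True
        occ[_flat(t2, G, off)] = True
    return int(
        _dfs_strands(
            occ,
            G,
            off,
            n_steps,
            _flat(start, G, off),
            _flat(target, G, off),
            n2,
            _flat(s2, G, off) if second is not None else -1,
            _flat(t2, G, off) if second is not None else -1,
        )
    )


@lru_cache(maxsize=None)
def count_free_walks(n_steps: int) -> int:
    """Number of free SAWs of ``n_steps`` bonds from a fixed even-parity origin.

    Uses the lattice point-group symmetry (first step x4, second step x3) to
    enumerate only walks with a fixed two-step prefix.
    """
    if n_steps < 0:
        raise ValueError("negative step count")
    if n_steps == 0:
        return 1
    if n_steps == 1:
        return 4
    occ, G, off = _grid(n_steps)
    occ[_flat((0, 0, 0), G, off)] = True
    occ[_flat((1, 1, 1), G, off)] = True
    occ[_flat((2, 2, 0), G, off)] = True
    return 12 * int(_dfs_free(occ, G, off, n_steps - 2, 2, 2, 0))


def _neg(v):
    return tuple(-c for c in v)


def _add(a, b):
    return tuple(x + y for x, y in zip(a, b))


def _scale(k, v):
    return tuple(k * c for c in v)


#: excluded volume of the next stacked pair of the closing helix
_CLOSING_HELIX_BLOCK = (_neg(AXIS_VEC), _add(_neg(AXIS_VEC), PAIR_VEC))


def strand_steps(n_unpaired: int) -> int:
    """Virtual bonds used by a strand of ``n_unpaired`` nucleotides."""
    return 2 * (n_unpaired + 1)


def _normalize_sizes(loop_type: LoopType, sizes) -> tuple[int, ...]:
    sizes = tuple(int(s) for s in sizes)
    if loop_type is LoopType.HAIRPIN:
        if len(sizes) != 1 or sizes[0] < 0:
            raise ValueError(f"hairpin sizes must be (L,), got {sizes}")
    elif loop_type in (LoopType.INTERNAL, LoopType.BULGE):
        if loop_type is LoopType.BULGE:
            if len(sizes) == 1:
                sizes = (0, sizes[0])
        if len(sizes) != 2 or min(sizes) < 0 or max(sizes) < 1:
            raise ValueError(f"internal/bulge sizes must be (s1, s2), got {sizes}")
        sizes = tuple(sorted(sizes))
    elif loop_type is LoopType.PK_LOOP:
        if len(sizes) != 2 or sizes[0] < 0 or sizes[1] < 1:
            raise ValueError(f"pseudoknot strand sizes must be (l, span), got {sizes}")
    return sizes


def enumerate_loop(
    loop_type: LoopType,
    sizes,
    max_size_cap: int = DEFAULT_ENUMERATION_CAP,
) -> ConformationCount:
    """Exact conformation counts for one loop, by exhaustive SAW enumeration.

    sizes:
      HAIRPIN  -> (L,)        loop of L unpaired nt closed by one pair
      INTERNAL -> (s1, s2)    two strands between two pairs (bulge: one side 0)
      BULGE    -> (s,) or (0, s)
      PK_LOOP  -> (l, span)   strand of l nt bridging a helix of `span` pairs

    Raises :class:`EnumerationCapError` when the total unpaired length
    exceeds ``max_size_cap`` (enumeration cost is exponential).
    """
    loop_type = LoopType(loop_type)
    sizes = _normalize_sizes(loop_type, sizes)
    total = sizes[0] if loop_type in (LoopType.HAIRPIN, LoopType.PK_LOOP) else sum(sizes)
    if total > max_size_cap:
        raise EnumerationCapError(
            f"{loop_type.value} loop of total size {total} exceeds enumeration cap "
            f"{max_size_cap}; use the extrapolated entropy table instead"
        )

    if loop_type is LoopType.HAIRPIN:
        n = strand_steps(sizes[0])
        closed = count_strand_walks(n, (0, 0, 0), PAIR_VEC, blocked=_CLOSING_HELIX_BLOCK)
        opened = count_free_walks(n)
    elif loop_type in (LoopType.INTERNAL, LoopType.BULGE):
        s1, s2 = sizes
        inner5 = AXIS_VEC
        inner3 = _add(AXIS_VEC, PAIR_VEC)
        blocked = _CLOSING_HELIX_BLOCK + (
            _scale(2, AXIS_VEC),
            _add(_scale(2, AXIS_VEC), PAIR_VEC),
        )
        closed = count_strand_walks(
            strand_steps(s1),
            (0, 0, 0),
            inner5,
            blocked=blocked,
            second=(strand_steps(s2), inner3, PAIR_VEC),
        )
        opened = count_free_walks(strand_steps(s1)) * count_free_walks(strand_steps(s2))
    elif loop_type is LoopType.PK_LOOP:
        l, span = sizes
        blocked = tuple(_scale(t, AXIS_VEC) for t in range(1, span)) + tuple(
            _add(_scale(t, AXIS_VEC), PAIR_VEC) for t in range(span + 1)
        )
        closed = count_strand_walks(
            strand_steps(l), (0, 0, 0), _scale(span, AXIS_VEC), blocked=blocked
        )
        opened = count_free_walks(strand_steps(l))
    else:  # pragma: no cover
        raise ValueError(loop_type)

    return ConformationCount(loop_type, sizes, closed, opened)


def generate_loop_conformations(loop_type: LoopType, sizes, limit: int | None = None):
    """Materialize hairpin-loop conformations (small sizes; inspection/tests).

    Pure-python reference generator; yields :class:`LatticeConformation`.
    """
    loop_type = LoopType(loop_type)
    sizes = _normalize_sizes(loop_type, sizes)
    if loop_type is not LoopType.HAIRPIN:
        raise NotImplementedError("explicit conformations only provided for hairpins")
    n = strand_steps(sizes[0])
    start, target = (0, 0, 0), PAIR_VEC
    blocked = set(_CLOSING_HELIX_BLOCK) | {start, target}
    out = []

    def rec(path):
        if limit is not None and len(out) >= limit:
            return
        pos = path[-1]
        d = len(path) - 1
        if d == n:
            if pos == target:
                out.append(LatticeConformation(tuple(path), (start, target)))
            return
        sign = 1 if pos[0] % 2 == 0 else -1
        for row in DIRS:
            nxt = (pos[0] + sign * row[0], pos[1] + sign * row[1], pos[2] + sign * row[2])
            if d + 1 == n:
                if nxt == target:
                    rec(path + [nxt])
            elif nxt not in blocked and nxt not in path:
                rec(path + [nxt])

    rec([start])
    return out


__all__ = [
    "DIRS",
    "PAIR_VEC",
    "AXIS_VEC",
    "DEFAULT_ENUMERATION_CAP",
    "EnumerationCapError",
    "UnformableLoopError",
    "Provenance",
    "ConformationCount",
    "LatticeConformation",
    "count_strand_walks",
    "count_free_walks",
    "strand_steps",
    "enumerate_loop",
    "generate_loop_conformations",
]
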