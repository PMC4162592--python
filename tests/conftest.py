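"""Shared fixtures and the independent lattice-walk reference enumerator.

The reference counter below is written separately from the production
enumerator (recursive descent instead of an iterative stack machine, its
own blocking/geometry assembly) and serves as the brute-force oracle for
conformation counts.
"""

from __future__ import annotations

import numpy as np
import pytest
from numba import njit

from rnamelt.entropy import default_table
from rnamelt.params import LoopType, get_params

@njit
def _ref_walk_free(x, y, z, rem, occ, G, off):
    """Recursive free-SAW counter (leaves at depth 0)."""
    if rem == 0:
        return 1
    total = 0
    sign = 1 if ((x % 2) + 2) % 2 == 0 else -1
    for k in range(4):
        dx = (1, 1, -1, -1)[k]
        dy = (1, -1, 1, -1)[k]
        dz = (1, -1, -1, 1)[k]
        nx, ny, nz = x + sign * dx, y + sign * dy, z + sign * dz
        flat = (nx + off) + G * ((ny + off) + G * (nz + off))
        if occ[flat]:
            continue
        occ[flat] = True
        total += _ref_walk_free(nx, ny, nz, rem - 1, occ, G, off)
        occ[flat] = False
    return total


@njit
def _ref_walk_to(x, y, z, rem, tx, ty, tz, occ, G, off):
    """Recursive SAW counter; final vertex must hit the (pre-marked) target."""
    total = 0
    sign = 1 if ((x % 2) + 2) % 2 == 0 else -1
    for k in range(4):
        dx = (1, 1, -1, -1)[k]
        dy = (1, -1, 1, -1)[k]
        dz = (1, -1, -1, 1)[k]
        nx, ny, nz = x + sign * dx, y + sign * dy, z + sign * dz
        if rem == 1:
            if nx == tx and ny == ty and nz == tz:
                total += 1
            continue
        ax = nx - tx if nx > tx else tx - nx
        ay = ny - ty if ny > ty else ty - ny
        az = nz - tz if nz > tz else tz - nz
        r = rem - 1
        if ax > r or ay > r or az > r:
            continue
        if (r - ax) % 2 or (r - ay) % 2 or (r - az) % 2:
            continue
        flat = (nx + off) + G * ((ny + off) + G * (nz + off))
        if occ[flat]:
            continue
        occ[flat] = True
        total += _ref_walk_to(nx, ny, nz, rem - 1, tx, ty, tz, occ, G, off)
        occ[flat] = False
    return total


@njit
def _ref_walk2(
    x, y, z, rem, tx, ty, tz,
    s2x, s2y, s2z, rem2, t2x, t2y, t2z,
    occ, G, off,
):
    """Two anchored strands enumerated jointly (mutual avoidance)."""
    total = 0
    sign = 1 if ((x % 2) + 2) % 2 == 0 else -1
    for k in range(4):
        dx = (1, 1, -1, -1)[k]
        dy = (1, -1, 1, -1)[k]
        dz = (1, -1, -1, 1)[k]
        nx, ny, nz = x + sign * dx, y + sign * dy, z + sign * dz
        if rem == 1:
            if nx == tx and ny == ty and nz == tz:
                total += _ref_walk_to(s2x, s2y, s2z, rem2, t2x, t2y, t2z, occ, G, off)
            continue
        ax = nx - tx if nx > tx else tx - nx
        ay = ny - ty if ny > ty else ty - ny
        az = nz - tz if nz > tz else tz - nz
        r = rem - 1
        if ax > r or ay > r or az > r:
            continue
        if (r - ax) % 2 or (r - ay) % 2 or (r - az) % 2:
            continue
        flat = (nx + off) + G * ((ny + off) + G * (nz + off))
        if occ[flat]:
            continue
        occ[flat] = True
        total += _ref_walk2(
            nx, ny, nz, rem - 1, tx, ty, tz, s2x, s2y, s2z, rem2, t2x, t2y, t2z,
            occ, G, off,
        )
        occ[flat] = False
    return total


def _ref_grid(max_steps, marks):
    off = max_steps + 6
    G = 2 * off + 1
    occ = np.zeros(G * G * G, dtype=np.bool_)
    for (mx, my, mz) in marks:
        occ[(mx + off) + G * ((my + off) + G * (mz + off))] = True
    return occ, G, off


def ref_count_closed(n_steps, start, target, blocked=()):
    if n_steps == 0:
        return 1 if tuple(start) == tuple(target) else 0
    occ, G, off = _ref_grid(n_steps, list(blocked) + [tuple(start), tuple(target)])
    return int(
        _ref_walk_to(start[0], start[1], start[2], n_steps, target[0], target[1],
                     target[2], occ, G, off)
    )


def ref_count_two_strands(n1, s1, t1, n2, s2, t2, blocked=()):
    occ, G, off = _ref_grid(
        n1 + n2, list(blocked) + [tuple(s1), tuple(t1), tuple(s2), tuple(t2)]
    )
    return int(
        _ref_walk2(s1[0], s1[1], s1[2], n1, t1[0], t1[1], t1[2],
                   s2[0], s2[1], s2[2], n2, t2[0], t2[1], t2[2], occ, G, off)
    )


_free_cache: dict[int, int] = {}


def ref_count_free(n_steps):
    if n_steps not in _free_cache:
        if n_steps == 0:
            _free_cache[n_steps] = 1
        else:
            occ, G, off = _ref_grid(n_steps, [(0, 0, 0)])
            _free_cache[n_steps] = int(
                _ref_walk_free(0, 0, 0, n_steps, occ, G, off)
            )
    return _free_cache[n_steps]


# geometry templates mirrored from the production module's documented layout
_PAIR = (2, 2, 0)
_AXIS = (2, 0, 2)
_BLOCK_CLOSING = ((-2, 0, -2), (0, 2, -2))


def ref_enumerate_loop(loop_type: LoopType, sizes):
    """Independent (closed, open) counts for one loop geometry."""
    loop_type = LoopType(loop_type)

    def steps(k):
        return 2 * (k + 1)

    if loop_type is LoopType.HAIRPIN:
        (L,) = sizes
        closed = ref_count_closed(steps(L), (0, 0, 0), _PAIR, blocked=_BLOCK_CLOSING)
        return closed, ref_count_free(steps(L))
    if loop_type in (LoopType.INTERNAL, LoopType.BULGE):
        if len(sizes) == 1:
            sizes = (0, sizes[0])
        s1, s2 = sorted(sizes)
        blocked = _BLOCK_CLOSING + ((4, 0, 4), (6, 2, 4))
        closed = ref_count_two_strands(
            steps(s1), (0, 0, 0), _AXIS, steps(s2), (4, 2, 2), _PAIR, blocked=blocked
        )
        return closed, ref_count_free(steps(s1)) * ref_count_free(steps(s2))
    if loop_type is LoopType.PK_LOOP:
        l, span = sizes
        blocked = tuple((2 * t, 0, 2 * t) for t in range(1, span)) + tuple(
            (2 * t + 2, 2, 2 * t) for t in range(span + 1)
        )
        closed = ref_count_closed(
            steps(l), (0, 0, 0), (2 * span, 0, 2 * span), blocked=blocked
        )
        return closed, ref_count_free(steps(l))
    raise ValueError(loop_type)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session", params=["turner04", "mfold23"])
def dialect_params(request):
    return get_params(request.param)
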