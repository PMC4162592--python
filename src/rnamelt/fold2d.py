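"""Equilibrium secondary-structure ensembles and base-pair probabilities.

The partition function

    Q = sum over structures s of exp(-dG(s) / R T)

is taken over all structures built from helices of >= 2 stacked canonical
pairs (hairpin loops >= 3 nt), optionally extended by H-type pseudoknots.
dG(s) assembles nearest-neighbor stack free energies plus loop free
energies from the lattice-enumerated entropy tables; every hairpin and
internal/bulge loop is summed over its admissible intra-loop mismatch
variants, so each loop term is a Boltzmann-weighted sum of conformational
substates rather than a single value.

Base-pair probabilities are obtained from the same dynamic program by
differentiating Q with respect to per-helix statistical weights: Q is a
polynomial in one formal weight per candidate helix, and x_h dQ/dx_h at
x = 1 is the total weight of structures containing helix h.  The DP
carries (value, gradient) vectors, which avoids a separate outside
recursion.

The pure enumeration oracle (:func:`exhaustive_oracle`) generates every
admissible structure explicitly, scores each with
:func:`structure_free_energy` (an independent pair-set decomposition),
and sums weights directly; it is the reference the dynamic program is
tested against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from rnamelt.entropy import UNFORMABLE, LoopEntropyTable, default_table
from rnamelt.params import (
    EnergyParamSet,
    LoopType,
    Temperature,
    get_params,
    pair_ok,
    stack_key,
)
from rnamelt.sequence import RnaSequence
from rnamelt.structures import (
    HTypeGeometry,
    InvalidStructureError,
    PseudoknotMode,
    SecondaryStructure,
    classify_h_type,
    helix_runs,
    runs_cross,
)

MIN_HELIX = 2
MIN_HAIRPIN = 3

#: per-branch multiloop penalty, kcal/mol (temperature-independent)
MULTILOOP_BRANCH_PENALTY = 0.1

#: default chain-length cap for the all-junction pseudoknot mode
MAX_ANY_JUNCTION_LENGTH = 60


class FeasibilityError(ValueError):
    """Requested mode is infeasible for this chain length."""


# ---------------------------------------------------------------------------
# loop variants and the shared energy model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LoopVariant:
    """One conformational substate of a loop (plain or single-mismatch)."""

    mismatch: tuple[int, int] | None  # sequence positions, 0-based
    ds_R: float  # loop entropy, units of R
    stack_keys: tuple  # mismatch-stack keys contributing stacking terms
    dG: float  # total free energy of this substate, kcal/mol


def _hairpin_variants(seq, p, q, T, params, ent):
    """Substates of the hairpin loop closed by pair (p, q)."""
    L = q - p - 1
    out = []
    if L < MIN_HAIRPIN:
        return out
    RT = params.gas_constant * T.kelvin

    def emit(mismatch, ds, keys):
        if ds == UNFORMABLE:
            return
        dg = -RT * ds
        for k in keys:
            dh, dsk = params.lookup_mismatch(k)
            dg += dh - T.kelvin * dsk
        out.append(LoopVariant(mismatch, ds, tuple(keys), dg))

    emit(None, ent.entropy(LoopType.HAIRPIN, (L,)), ())
    for u in range(1, L + 1):
        for v in range(u + MIN_HAIRPIN + 1, L + 1):
            if (u, v) == (1, L):
                continue  # that substate is the helix extended by one pair
            x, y = seq[p + u], seq[p + v]
            if not pair_ok(x, y):
                continue
            ds = ent.entropy(LoopType.HAIRPIN, (v - u - 1,)) + ent.entropy(
                LoopType.INTERNAL, (u - 1, L - v)
            )
            keys = []
            if u == 1:
                keys.append(stack_key(seq[p], x, seq[q], y))
            elif v == L:
                keys.append(stack_key(seq[p], x, seq[q], y))
            emit((p + u, p + v), ds, keys)
    return out


def _internal_variants(seq, p, q, a, b, T, params, ent):
    """Substates of the internal/bulge loop between pairs (p, q) and (a, b)."""
    s1, s2 = a - p - 1, q - b - 1
    out = []
    if s1 < 0 or s2 < 0 or s1 + s2 < 1:
        return out
    RT = params.gas_constant * T.kelvin

    def emit(mismatch, ds, keys):
        if ds == UNFORMABLE:
            return
        dg = -RT * ds
        for k in keys:
            dh, dsk = params.lookup_mismatch(k)
            dg += dh - T.kelvin * dsk
        out.append(LoopVariant(mismatch, ds, tuple(keys), dg))

    emit(None, ent.entropy(LoopType.INTERNAL, (s1, s2)), ())
    for u in range(1, s1 + 1):
        for v in range(1, s2 + 1):
            x, y = seq[p + u], seq[q - v]
            if not pair_ok(x, y):
                continue
            outer = (u - 1, v - 1)
            inner = (s1 - u, s2 - v)
            if outer == (0, 0) or inner == (0, 0):
                continue  # substate identical to extending a closing helix
            ds = ent.entropy(LoopType.INTERNAL, outer) + ent.entropy(
                LoopType.INTERNAL, inner
            )
            keys = []
            if u == 1 or v == 1:
                keys.append(stack_key(seq[p], x, seq[q], y))
            if s1 - u == 0 or s2 - v == 0:
                keys.append(stack_key(x, seq[a], y, seq[b]))
            emit((p + u, q - v), ds, keys)
    return out


def enumerate_mismatch_variants(
    seq: RnaSequence,
    loop,
    T: Temperature,
    params: EnergyParamSet,
    entropies: LoopEntropyTable,
) -> list[LoopVariant]:
    """All substates (plain + admissible single mismatches) of one loop.

    ``loop`` is ``("hairpin", (p, q))`` or ``("internal", (p, q), (a, b))``
    with 0-based closing pairs.  The plain loop is always first; the list
    is never empty for a geometrically valid loop.
    """
    kind = loop[0]
    if kind == "hairpin":
        (p, q) = loop[1]
        return _hairpin_variants(seq, p, q, T, params, entropies)
    if kind == "internal":
        (p, q), (a, b) = loop[1], loop[2]
        return _internal_variants(seq, p, q, a, b, T, params, entropies)
    raise ValueError(f"unknown loop kind {kind!r}")


class EnergyModel:
    """Boltzmann weights of structural motifs for one (sequence, T, dialect).

    Shared by the dynamic program and by per-structure scoring, so that a
    structure's weight is identical no matter which route computes it.
    """

    def __init__(self, seq, T, params=None, entropies=None):
        self.seq = seq if isinstance(seq, RnaSequence) else RnaSequence.parse(seq)
        self.T = T if isinstance(T, Temperature) else Temperature(T)
        self.params = params or get_params()
        self.ent = entropies or default_table()
        self.RT = self.params.gas_constant * self.T.kelvin
        self.beta = 1.0 / self.RT
        a, c = self.ent.hairpin_fit()
        self._ml_a, self._ml_c = a, c
        self._hp_cache: dict = {}
        self._int_cache: dict = {}

    # -- stacks -------------------------------------------------------------

    def helix_stack_dg(self, p: int, q: int, k: int) -> float:
        s = self.seq
        dg = 0.0
        for t in range(k - 1):
            key = stack_key(s[p + t], s[p + t + 1], s[q - t], s[q - t - 1])
            dh, ds = self.params.lookup(key)
            dg += dh - self.T.kelvin * ds
        return dg

    def helix_weight(self, p, q, k) -> float:
        return math.exp(-self.beta * self.helix_stack_dg(p, q, k))

    # -- loops (variant-summed weights) -------------------------------------

    def hairpin_weight(self, p, q) -> float:
        key = (p, q)
        if key not in self._hp_cache:
            vs = _hairpin_variants(self.seq, p, q, self.T, self.params, self.ent)
            self._hp_cache[key] = sum(math.exp(-self.beta * v.dG) for v in vs)
        return self._hp_cache[key]

    def internal_weight(self, p, q, a, b) -> float:
        key = (p, q, a, b)
        if key not in self._int_cache:
            vs = _internal_variants(self.seq, p, q, a, b, self.T, self.params, self.ent)
            self._int_cache[key] = sum(math.exp(-self.beta * v.dG) for v in vs)
        return self._int_cache[key]

    def multiloop_weight(self, unpaired: int, branches: int) -> float:
        ds = self._ml_a - self._ml_c * math.log(max(unpaired, 1))
        return math.exp(ds) * math.exp(
            -self.beta * MULTILOOP_BRANCH_PENALTY * branches
        )

    def pk_loop_ds(self, geo: HTypeGeometry) -> float:
        """Total loop entropy (units of R) of an H-type geometry."""
        ka, kb = geo.stem1[2], geo.stem2[2]
        ds = (
            self.ent.entropy(LoopType.PK_LOOP, (geo.loop1, kb))
            + self.ent.entropy(LoopType.PK_LOOP, (geo.loop3, ka))
            + self.ent.entropy(LoopType.PK_LOOP, (geo.junction, 1))
        )
        return ds

    def pk_weight(self, geo: HTypeGeometry) -> float:
        ds = self.pk_loop_ds(geo)
        if ds == UNFORMABLE:
            return 0.0
        w = math.exp(ds)
        for (p, q, k) in (geo.stem1, geo.stem2):
            w *= self.helix_weight(p, q, k)
        return w


# ---------------------------------------------------------------------------
# candidate helices
# ---------------------------------------------------------------------------


def candidate_helices(seq: RnaSequence) -> list[tuple[int, int, int]]:
    """All (p, q, k) with k >= 2 stacked canonical pairs and q - p - 2k + 1 >= 0."""
    n = len(seq)
    out = []
    for p in range(n):
        for q in range(p + 2 * MIN_HELIX - 1, n):
            k = 0
            while (
                p + k < q - k
                and pair_ok(seq[p + k], seq[q - k])
            ):
                k += 1
                if q - p - 2 * k + 1 < 0:
                    break
            for kk in range(MIN_HELIX, k + 1):
                if q - p - 2 * kk + 1 >= 0:
                    out.append((p, q, kk))
    return out


def _h_type_geometries(helices, n, mode: PseudoknotMode):
    """All admissible H-type two-stem geometries under the junction mode."""
    if mode is PseudoknotMode.NONE:
        return
    hset = sorted(helices)
    for i, r1 in enumerate(hset):
        for r2 in hset[i + 1:]:
            if not runs_cross(r1, r2):
                continue
            geo = classify_h_type(r1, r2)
            if geo is None:
                continue
            if mode.max_junction is not None and geo.junction > mode.max_junction:
                continue
            yield geo


# ---------------------------------------------------------------------------
# structure scoring (pair-set decomposition; used by the oracle and the API)
# ---------------------------------------------------------------------------


def structure_weight(model: EnergyModel, s: SecondaryStructure) -> float:
    """Boltzmann weight of one structure by decomposing its pair set."""
    runs = s.runs()
    if not runs:
        return 1.0
    geo = s.h_type()
    w = 1.0
    nested = list(runs)
    if geo is not None:
        nested = [r for r in runs if r not in (geo.stem1, geo.stem2)]
        w *= model.pk_weight(geo)
        if w == 0.0:
            return 0.0

    partner = s.partner()
    for (p, q, k) in nested:
        w *= model.helix_weight(p, q, k)
        # region inside the innermost pair
        P, Q = p + k - 1, q - k + 1
        children = []
        x = P + 1
        unpaired = 0
        while x < Q:
            if x in partner and partner[x] > x:
                children.append((x, partner[x]))
                x = partner[x] + 1
            else:
                unpaired += 1
                x += 1
        if not children:
            w *= model.hairpin_weight(P, Q)
        elif len(children) == 1 and unpaired >= 1:
            (a, b) = children[0]
            w *= model.internal_weight(P, Q, a, b)
        else:
            w *= model.multiloop_weight(unpaired, len(children) + 1)
    return w


def structure_free_energy(
    seq: RnaSequence,
    s: SecondaryStructure,
    T: Temperature,
    params: EnergyParamSet | None = None,
    entropies: LoopEntropyTable | None = None,
) -> float:
    """Effective free energy dG(s, T) of one structure, kcal/mol.

    Stacks over all helix runs plus loop terms for every loop; each
    hairpin/internal loop term is the Boltzmann-weighted sum over its
    mismatch variants, so dG is an effective (variant-summed) free energy
    with the open chain at dG = 0.  An unformable structure (zero weight)
    returns +inf.
    """
    model = EnergyModel(seq, T, params, entropies)
    s.check_sequence(model.seq)
    w = structure_weight(model, s)
    if w == 0.0:
        return math.inf
    return -model.RT * math.log(w)


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Helix:
    """A maximal run of stacked pairs with its formation probability."""

    start_i: int  # 0-based outer 5' position
    start_j: int  # 0-based outer 3' position
    length: int
    probability: float

    def pairs(self):
        return [(self.start_i + t, self.start_j - t) for t in range(self.length)]


@dataclass
class FoldResult:
    """Partition function, pair probabilities and derived structure calls."""

    seq: RnaSequence
    temperature: Temperature
    mode: PseudoknotMode
    dialect: str
    Q: float
    lnQ: float
    bpp: np.ndarray
    helices: list = field(default_factory=list)
    dominant: tuple | None = None  # (SecondaryStructure, probability)
    alternatives: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# the dynamic program
# ---------------------------------------------------------------------------


class _Folder:
    """Interval DP over the helix-decomposed ensemble.

    Weights are numpy vectors: scalar mode (length 1) for Q only, gradient
    mode (length H+1) carrying dQ/dx_h per candidate helix for pair
    probabilities.
    """

    def __init__(self, model: EnergyModel, mode: PseudoknotMode, gradient: bool):
        self.m = model
        self.mode = mode
        self.n = len(model.seq)
        self.helices = candidate_helices(model.seq)
        self.hid = {h: i for i, h in enumerate(self.helices)}
        self.M = 1 + len(self.helices) if gradient else 1
        self.gradient = gradient
        self.sw = [model.helix_weight(*h) for h in self.helices]
        self.by_start: dict[int, list[int]] = {}
        for i, (p, q, k) in enumerate(self.helices):
            self.by_start.setdefault(p, []).append(i)
        self._C: dict = {}
        self._Z: dict = {}
        self._F: dict = {}

    # vector algebra ---------------------------------------------------------

    def one(self):
        v = np.zeros(self.M)
        v[0] = 1.0
        return v

    def mul(self, a, b):
        if self.M == 1:
            return a * b
        out = a * b[0]
        out[1:] += a[0] * b[1:]
        return out

    # recursions -------------------------------------------------------------

    def C(self, h: int):
        """Closed weight of helix h: formal weight x_h, stacks, interior."""
        if h not in self._C:
            p, q, k = self.helices[h]
            inner = self.loop_in(p + k - 1, q - k + 1)
            v = inner * self.sw[h]
            if self.gradient:
                v[h + 1] += v[0]  # d/dx_h of x_h * (...), at x = 1
            self._C[h] = v
        return self._C[h]

    def Z(self, i: int, j: int):
        """Ensemble weight of [i..j] hanging off the exterior loop."""
        if i > j:
            return self.one()
        key = (i, j)
        if key not in self._Z:
            v = self.Z(i + 1, j).copy()
            for h in self.by_start.get(i, ()):
                q = self.helices[h][1]
                if q <= j:
                    v = v + self.mul(self.C(h), self.Z(q + 1, j))
            self._Z[key] = v
        return self._Z[key]

    def F(self, i: int, j: int):
        """Multiloop filling of [i..j]: {(branches, unpaired): weight}."""
        if i > j:
            return {(0, 0): self.one()}
        key = (i, j)
        if key not in self._F:
            out = {}
            for (b, u), v in self.F(i + 1, j).items():
                out[(b, u + 1)] = v.copy()
            for h in self.by_start.get(i, ()):
                q = self.helices[h][1]
                if q <= j:
                    c = self.C(h)
                    if not c.any():
                        continue
                    for (b, u), v in self.F(q + 1, j).items():
                        k2 = (b + 1, u)
                        cur = out.get(k2)
                        w = self.mul(c, v)
                        out[k2] = w if cur is None else cur + w
            self._F[key] = out
        return self._F[key]

    def loop_in(self, P: int, Q: int):
        """Weight of everything strictly inside an innermost closing pair."""
        v = self.one() * self.m.hairpin_weight(P, Q)
        for h, (a, b, k) in enumerate(self.helices):
            if P < a and b < Q and (a - P - 1) + (Q - b - 1) >= 1:
                iw = self.m.internal_weight(P, Q, a, b)
                if iw:
                    v = v + self.mul(self.C(h), self.one() * iw)
        if Q - P - 1 >= 2 * (2 * MIN_HELIX + MIN_HAIRPIN):  # room for 2 branches
            for (b, u), w in self.F(P + 1, Q - 1).items():
                if b >= 2:
                    v = v + w * self.m.multiloop_weight(u, b + 1)
        return v

    def total(self):
        v = self.Z(0, self.n - 1).copy()
        for geo in _h_type_geometries(self.helices, self.n, self.mode):
            w = self.m.pk_weight(geo)
            if w == 0.0:
                continue
            vv = self.one() * w
            if self.gradient:
                for stem in (geo.stem1, geo.stem2):
                    u = np.zeros(self.M)
                    u[0] = 1.0
                    u[self.hid[stem] + 1] = 1.0
                    vv = self.mul(vv, u)
            vv = self.mul(vv, self.Z(0, geo.stem1[0] - 1))
            vv = self.mul(vv, self.Z(geo.stem2[1] + 1, self.n - 1))
            v = v + vv
        return v


def partition_function(
    seq,
    T=37.0,
    params: EnergyParamSet | None = None,
    entropies: LoopEntropyTable | None = None,
    pk: PseudoknotMode = PseudoknotMode.NONE,
    compute_bpp: bool = True,
    max_any_junction: int = MAX_ANY_JUNCTION_LENGTH,
) -> FoldResult:
    """Partition function Q and base-pair probability matrix P_ij.

    Q is relative to the open chain (weight 1), so Q >= 1.  P_ij is the
    equilibrium probability that i pairs j within a helix of the ensemble
    selected by ``pk``.
    """
    model = EnergyModel(seq, T, params, entropies)
    pk = PseudoknotMode(pk)
    n = len(model.seq)
    if pk is PseudoknotMode.ANY_JUNCTION and n > max_any_junction:
        raise FeasibilityError(
            f"mode {pk.value} is restricted to N <= {max_any_junction} "
            f"(got {n}); use mode 'none' or 'junction1'"
        )
    folder = _Folder(model, pk, gradient=compute_bpp)
    v = folder.total()
    Q = float(v[0])
    bpp = np.zeros((n, n))
    if compute_bpp:
        for h, (p, q, k) in enumerate(folder.helices):
            t_h = float(v[h + 1])  # weight of all structures containing helix h
            if t_h == 0.0:
                continue
            prob = t_h / Q
            for t in range(k):
                bpp[p + t, q - t] += prob
                bpp[q - t, p + t] += prob
    return FoldResult(
        seq=model.seq,
        temperature=model.T,
        mode=pk,
        dialect=model.params.dialect.value,
        Q=Q,
        lnQ=math.log(Q),
        bpp=bpp,
    )


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle
# ---------------------------------------------------------------------------

MAX_ORACLE_LENGTH = 25


def _oracle_helices(seq):
    """Candidate (p, q, k) runs, written independently of candidate_helices."""
    n = len(seq)
    found = []
    for p in range(n):
        for q in range(n - 1, p, -1):
            run = 0
            while p + run < q - run and pair_ok(seq[p + run], seq[q - run]):
                run += 1
            for k in range(MIN_HELIX, run + 1):
                if (q - k + 1) - (p + k - 1) >= 1:
                    found.append((p, q, k))
    return sorted(found)


def enumerate_structures(seq, pk: PseudoknotMode = PseudoknotMode.NONE):
    """Yield every admissible SecondaryStructure for a short sequence."""
    seq = seq if isinstance(seq, RnaSequence) else RnaSequence.parse(seq)
    n = len(seq)
    if n > MAX_ORACLE_LENGTH:
        raise FeasibilityError(
            f"explicit enumeration refused for N = {n} > {MAX_ORACLE_LENGTH}"
        )
    helices = _oracle_helices(seq)
    memo: dict = {}

    def nested(i, j):
        """All tuples of runs filling [i..j] without crossings."""
        if i >= j:
            return [()]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = list(nested(i + 1, j))
        for (p, q, k) in helices:
            if p != i or q > j:
                continue
            P, Q = p + k - 1, q - k + 1
            if Q - P - 1 < MIN_HAIRPIN:
                continue  # interior cannot close a legal hairpin
            for inner in nested(P + 1, Q - 1):
                # reject helix-continuation splits: same physical run counted twice
                if any(r[0] == P + 1 and r[1] == Q - 1 for r in inner):
                    continue
                for right in nested(q + 1, j):
                    out.append(((p, q, k),) + inner + right)
        memo[key] = out
        return out

    def to_structure(runs):
        pairs = [(p + t, q - t) for (p, q, k) in runs for t in range(k)]
        return SecondaryStructure(pairs)

    for runs in nested(0, n - 1):
        yield to_structure(runs)

    if pk is not PseudoknotMode.NONE:
        for geo in _h_type_geometries(helices, n, pk):
            for left in nested(0, geo.stem1[0] - 1):
                for right in nested(geo.stem2[1] + 1, n - 1):
                    yield to_structure((geo.stem1, geo.stem2) + left + right)


def exhaustive_oracle(
    seq,
    T=37.0,
    params: EnergyParamSet | None = None,
    entropies: LoopEntropyTable | None = None,
    pk: PseudoknotMode = PseudoknotMode.NONE,
    return_structures: bool = False,
):
    """Reference result by explicit enumeration and direct Boltzmann sums."""
    model = EnergyModel(seq, T, params, entropies)
    pk = PseudoknotMode(pk)
    n = len(model.seq)
    Q = 0.0
    bpp = np.zeros((n, n))
    scored = []
    for s in enumerate_structures(model.seq, pk):
        w = structure_weight(model, s)
        if w == 0.0:
            continue
        Q += w
        for (i, j) in s.pairs:
            bpp[i, j] += w
            bpp[j, i] += w
        if return_structures:
            scored.append((s, w))
    bpp /= Q
    result = FoldResult(
        seq=model.seq,
        temperature=model.T,
        mode=pk,
        dialect=model.params.dialect.value,
        Q=Q,
        lnQ=math.log(Q),
        bpp=bpp,
    )
    if return_structures:
        return result, scored
    return result


# ---------------------------------------------------------------------------
# helix probabilities and structure calls
# ---------------------------------------------------------------------------

PROB_FLOOR = 1e-9


def helix_probabilities(result: FoldResult, floor: float = PROB_FLOOR) -> list[Helix]:
    """Maximal runs of consecutive probable pairs, scored by their mean P_ij."""
    n = len(result.seq)
    bpp = result.bpp
    present = {
        (i, j) for i in range(n) for j in range(i + 1, n) if bpp[i, j] > floor
    }
    helices = []
    for (i, j) in sorted(present):
        if (i - 1, j + 1) in present:
            continue
        k = 0
        while (i + k, j - k) in present and i + k < j - k:
            k += 1
        if k >= MIN_HELIX:
            prob = float(np.mean([bpp[i + t, j - t] for t in range(k)]))
            helices.append(Helix(i, j, k, prob))
    helices.sort(key=lambda h: (-h.probability, h.start_i))
    result.helices = helices
    return helices


def _compatible(h1: Helix, h2: Helix) -> bool:
    occ1 = {x for p in h1.pairs() for x in p}
    occ2 = {x for p in h2.pairs() for x in p}
    if occ1 & occ2:
        return False
    return not runs_cross(
        (h1.start_i, h1.start_j, h1.length), (h2.start_i, h2.start_j, h2.length)
    )


def dominant_and_alternatives(
    result: FoldResult, level_tolerance: float = 0.15
) -> tuple:
    """Most probable structure (pairs with P_ij > 0.5) and alternatives.

    Alternatives are maximal sets of mutually compatible helices whose
    probabilities agree within ``level_tolerance``, reported at the set's
    common level; helix sets already inside the dominant structure are not
    re-reported.
    """
    n = len(result.seq)
    helices = result.helices or helix_probabilities(result)
    dom_pairs = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if result.bpp[i, j] > 0.5
    ]
    dom = SecondaryStructure(dom_pairs, validate_runs=False)
    dom_prob = (
        float(np.mean([result.bpp[i, j] for (i, j) in dom_pairs])) if dom_pairs else 0.0
    )
    result.dominant = (dom, dom_prob)

    assigned: set[int] = set()
    groups = []
    for idx, h in enumerate(helices):
        if idx in assigned:
            continue
        group = [idx]
        for jdx in range(idx + 1, len(helices)):
            if jdx in assigned:
                continue
            h2 = helices[jdx]
            if abs(h2.probability - h.probability) <= level_tolerance and all(
                _compatible(helices[g], h2) for g in group
            ):
                group.append(jdx)
        assigned.update(group)
        groups.append(group)

    alternatives = []
    for group in groups:
        pairs = [p for g in group for p in helices[g].pairs()]
        level = float(np.mean([helices[g].probability for g in group]))
        if set(pairs) <= set(dom.pairs):
            continue
        s = SecondaryStructure(pairs, validate_runs=False)
        alternatives.append((s, level))
    result.alternatives = alternatives
    return result.dominant, alternatives


def fold(
    seq,
    T=37.0,
    params=None,
    entropies=None,
    pk: PseudoknotMode = PseudoknotMode.NONE,
    level_tolerance: float = 0.15,
) -> FoldResult:
    """Full 2D prediction: Q, P_ij, helices, dominant and alternatives."""
    result = partition_function(seq, T, params, entropies, pk)
    helix_probabilities(result)
    dominant_and_alternatives(result, level_tolerance)
    return result


__all__ = [
    "MIN_HELIX",
    "MIN_HAIRPIN",
    "MULTILOOP_BRANCH_PENALTY",
    "MAX_ANY_JUNCTION_LENGTH",
    "MAX_ORACLE_LENGTH",
    "FeasibilityError",
    "LoopVariant",
    "enumerate_mismatch_variants",
    "EnergyModel",
    "candidate_helices",
    "structure_weight",
    "structure_free_energy",
    "Helix",
    "FoldResult",
    "partition_function",
    "enumerate_structures",
    "exhaustive_oracle",
    "helix_probabilities",
    "dominant_and_alternatives",
    "fold",
]
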