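"""Nearest-neighbor thermodynamic parameters for RNA base-pair stacks.

Two selectable parameter dialects are embedded as code-resident constants:

``turner04``
    Watson-Crick stack enthalpies/free energies from the 2004-era
    nearest-neighbor compilation (WC values from the 1998 optical-melting
    regression; wobble values from the later GU re-analyses).

``mfold23``
    The older stack set used by the 2.3-generation folding packages
    (1986/1989-era Watson-Crick values with a simplified uniform treatment
    of GU wobbles).

Each stack is stored as (dH, dS) with dH in kcal/mol and dS in
kcal/(mol K); the temperature-dependent stack free energy is

    dG(T) = dH - T_kelvin * dS

so entropies are derived once from the published (dH, dG37) pairs via
dS = (dH - dG37) / 310.15.

A stack is keyed by its two ordered base pairs (outer, inner), reading

    5'-X Y-3'
    3'-W Z-5'

as pairs X.W (outer) and Y.Z (inner).  A key and its 180-degree rotation
(Z.Y outer, W.X inner) denote the same physical stack and map to the same
parameters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

log = logging.getLogger(__name__)

#: gas constant in kcal/(mol K)
GAS_CONSTANT = 1.987e-3

#: temperature of the published free-energy tables, in kelvin (37 C)
T37_KELVIN = 310.15

BASES = ("A", "C", "G", "U")

#: pairs allowed in helices: Watson-Crick plus GU wobble
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)


class Dialect(str, Enum):
    TURNER04 = "turner04"
    MFOLD23 = "mfold23"


class ParameterMissingError(KeyError):
    """A stack key has no entry in the active parameter set."""


class InvalidLoopError(ValueError):
    """Loop sizes below the steric minimum for the loop type."""


@dataclass(frozen=True)
class Temperature:
    """A temperature in Celsius, restricted to -10 .. 150 C."""

    celsius: float

    def __post_init__(self) -> None:
        if not (-10.0 <= self.celsius <= 150.0):
            raise ValueError(
                f"temperature {self.celsius} C outside supported range -10..150 C"
            )

    @property
    def kelvin(self) -> float:
        return self.celsius + 273.15


@dataclass(frozen=True, order=True)
class StackKey:
    """Ordered stack of two base pairs: 5'-outer,inner-3' over 3',5'."""

    pair_outer: tuple[str, str]
    pair_inner: tuple[str, str]

    def rotated(self) -> "StackKey":
        """The same physical stack read from the opposite strand direction."""
        (x, w), (y, z) = self.pair_outer, self.pair_inner
        return StackKey((z, y), (w, x))

    def canonical(self) -> "StackKey":
        """Deterministic representative of the {key, rotated} class."""
        other = self.rotated()
        return self if self <= other else other

    def __str__(self) -> str:
        (x, w), (y, z) = self.pair_outer, self.pair_inner
        return f"5'{x}{y}3'/3'{w}{z}5'"


def stack_key(x: str, y: str, w: str, z: str) -> StackKey:
    """Build a StackKey from the four bases of ``5'-XY-3' / 3'-WZ-5'``."""
    return StackKey((x, w), (y, z))


def _table(entries: dict[str, tuple[float, float]]) -> dict[StackKey, tuple[float, float]]:
    """Expand '{XY/WZ: (dH, dG37)}' into canonical StackKey -> (dH, dS)."""
    out: dict[StackKey, tuple[float, float]] = {}
    for code, (dh, dg37) in entries.items():
        top, bottom = code.split("/")
        key = stack_key(top[0], top[1], bottom[0], bottom[1]).canonical()
        ds = (dh - dg37) / T37_KELVIN
        if key in out and out[key] != (dh, ds):
            raise ValueError(f"conflicting duplicate stack entry {code}")
        out[key] = (dh, ds)
    return out


# Watson-Crick stacks, 1998 regression: code 'XY/WZ', values (dH kcal/mol, dG37 kcal/mol)
_TURNER04_WC = {
    "AA/UU": (-6.82, -0.93),
    "AU/UA": (-9.38, -1.10),
    "UA/AU": (-7.69, -1.33),
    "CU/GA": (-10.48, -2.08),
    "CA/GU": (-10.44, -2.11),
    "GU/CA": (-11.40, -2.24),
    "GA/CU": (-12.44, -2.35),
    "CG/GC": (-10.64, -2.36),
    "GG/CC": (-13.39, -3.26),
    "GC/CG": (-14.88, -3.42),
}

# GU-wobble-containing stacks for the 2004-era dialect
_TURNER04_GU = {
    "AG/UU": (-3.21, -0.55),
    "AU/UG": (-8.81, -1.36),
    "CG/GU": (-5.61, -1.41),
    "CU/GG": (-12.11, -2.11),
    "GG/CU": (-12.59, -1.53),
    "GU/CG": (-12.83, -2.51),
    "UA/GU": (-8.33, -1.27),
    "GA/UU": (-5.30, -1.00),
    "GG/UU": (-7.32, 0.47),
    "GU/UG": (-9.26, 1.29),
    "UG/GU": (-6.30, 0.30),
}

# 2.3-generation Watson-Crick stacks (1986/89-era values)
_MFOLD23_WC = {
    "AA/UU": (-6.6, -0.9),
    "AU/UA": (-5.7, -0.9),
    "UA/AU": (-8.1, -1.1),
    "CA/GU": (-10.5, -1.8),
    "CU/GA": (-7.6, -1.7),
    "GA/CU": (-13.3, -2.3),
    "GU/CA": (-10.2, -2.1),
    "CG/GC": (-11.9, -2.0),
    "GG/CC": (-12.2, -2.9),
    "GC/CG": (-14.2, -3.4),
}

# simplified uniform GU treatment of the older dialect
_MFOLD23_GU = {
    code: ((-3.0, -0.3) if code in ("GG/UU", "GU/UG", "UG/GU") else (-6.3, -0.5))
    for code in _TURNER04_GU
}


def all_canonical_stack_keys() -> set[StackKey]:
    """Every distinct (rotation-deduplicated) stack of two canonical pairs."""
    keys = set()
    for x, w in CANONICAL_PAIRS:
        for y, z in CANONICAL_PAIRS:
            keys.add(StackKey((x, w), (y, z)).canonical())
    return keys


@dataclass
class EnergyParamSet:
    """One dialect's stack tables plus fallbacks for unpublished mismatch stacks."""

    dialect: Dialect
    stack_dh_ds: dict[StackKey, tuple[float, float]]
    mismatch_stack_dh_ds: dict[StackKey, tuple[float, float]] = field(default_factory=dict)
    mismatch_default: tuple[float, float] = (0.0, 0.0)
    gas_constant: float = GAS_CONSTANT

    def lookup(self, key: StackKey) -> tuple[float, float]:
        """(dH, dS) for a canonical-pair stack; raises on unknown keys."""
        entry = self.stack_dh_ds.get(key.canonical())
        if entry is None:
            raise ParameterMissingError(
                f"no stack parameters for {key} in dialect {self.dialect.value}"
            )
        return entry

    def lookup_mismatch(self, key: StackKey) -> tuple[float, float]:
        """(dH, dS) for a stack where one pair is a loop mismatch.

        Mismatches drawn from the canonical alphabet reuse the helix stack
        table; genuinely non-canonical mismatch stacks fall back to a
        configurable default (0 by default) with a logged warning.
        """
        canon = key.canonical()
        if canon in self.mismatch_stack_dh_ds:
            return self.mismatch_stack_dh_ds[canon]
        if canon in self.stack_dh_ds:
            return self.stack_dh_ds[canon]
        log.warning(
            "no mismatch-stack parameters for %s in dialect %s; using default %s",
            key, self.dialect.value, self.mismatch_default,
        )
        return self.mismatch_default

    def to_tsv(self) -> str:
        """The active stack table as tab-separated text for audit."""
        lines = ["# stack\tdH_kcal_mol\tdS_kcal_mol_K\tdG37_kcal_mol"]
        for key in sorted(self.stack_dh_ds):
            dh, ds = self.stack_dh_ds[key]
            lines.append(f"{key}\t{dh:.2f}\t{ds:.6f}\t{dh - T37_KELVIN * ds:.2f}")
        return "\n".join(lines) + "\n"


_PARAM_SETS: dict[Dialect, EnergyParamSet] = {}


def get_params(dialect: str | Dialect = Dialect.TURNER04) -> EnergyParamSet:
    """The embedded parameter set for a dialect name ('turner04' | 'mfold23')."""
    dialect = Dialect(dialect)
    if dialect not in _PARAM_SETS:
        if dialect is Dialect.TURNER04:
            table = _table({**_TURNER04_WC, **_TURNER04_GU})
        else:
            table = _table({**_MFOLD23_WC, **_MFOLD23_GU})
        missing = all_canonical_stack_keys() - set(table)
        if missing:  # tables are expanded from literals; guard their coverage
            raise RuntimeError(f"incomplete stack table for {dialect}: {sorted(missing)}")
        _PARAM_SETS[dialect] = EnergyParamSet(dialect=dialect, stack_dh_ds=table)
    return _PARAM_SETS[dialect]


def stack_free_energy(key: StackKey, T: Temperature, params: EnergyParamSet) -> float:
    """dG(T) = dH - T_kelvin * dS for one canonical stack, in kcal/mol."""
    dh, ds = params.lookup(key)
    return dh - T.kelvin * ds


def mismatch_stack_free_energy(key: StackKey, T: Temperature, params: EnergyParamSet) -> float:
    """dG(T) for a stack between a closing pair and an intra-loop mismatch."""
    dh, ds = params.lookup_mismatch(key)
    return dh - T.kelvin * ds


class LoopType(str, Enum):
    HAIRPIN = "hairpin"
    INTERNAL = "internal"
    BULGE = "bulge"
    PK_LOOP = "pk_loop"


MIN_HAIRPIN_LOOP = 3


def loop_free_energy(
    loop_type: LoopType,
    sizes: tuple[int, ...],
    closing_stacks: list[StackKey],
    T: Temperature,
    params: EnergyParamSet,
    entropies,
) -> float:
    """Free energy of a loop: -T*dS_loop(sizes) plus its closing/mismatch stacks.

    ``entropies`` is a loop-entropy table exposing
    ``entropy(loop_type, sizes) -> dS in units of R``.
    """
    loop_type = LoopType(loop_type)
    if loop_type is LoopType.HAIRPIN:
        if len(sizes) != 1 or sizes[0] < MIN_HAIRPIN_LOOP:
            raise InvalidLoopError(
                f"hairpin loop needs >= {MIN_HAIRPIN_LOOP} unpaired nt, got {sizes}"
            )
    elif loop_type is LoopType.INTERNAL:
        if len(sizes) != 2 or min(sizes) < 1:
            raise InvalidLoopError(f"internal loop needs sizes >= (1,1), got {sizes}")
    elif loop_type is LoopType.BULGE:
        if len(sizes) < 1 or sizes[0] < 1:
            raise InvalidLoopError(f"bulge needs >= 1 unpaired nt, got {sizes}")
    ds_loop_R = entropies.entropy(loop_type, sizes)  # units of R
    dg = -T.kelvin * params.gas_constant * ds_loop_R
    for key in closing_stacks:
        dg += mismatch_stack_free_energy(key, T, params)
    return dg


def pair_ok(x: str, y: str) -> bool:
    return (x, y) in CANONICAL_PAIRS


__all__ = [
    "GAS_CONSTANT",
    "T37_KELVIN",
    "BASES",
    "CANONICAL_PAIRS",
    "Dialect",
    "Temperature",
    "StackKey",
    "stack_key",
    "EnergyParamSet",
    "get_params",
    "stack_free_energy",
    "mismatch_stack_free_energy",
    "LoopType",
    "MIN_HAIRPIN_LOOP",
    "InvalidLoopError",
    "ParameterMissingError",
    "loop_free_energy",
    "pair_ok",
    "all_canonical_stack_keys",
]
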