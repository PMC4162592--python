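"""Melting thermodynamics: Q(T) scans and heat-capacity curves.

The excess heat capacity (relative to the open chain, with
temperature-independent dH/dS parameters) is

    C(T) = d/dT [ R T_k^2 d lnQ / dT ]

evaluated by central finite differences on a uniform temperature grid;
one point is lost at each boundary.  Peaks of C(T) mark structural
melting transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from rnamelt.fold2d import partition_function
from rnamelt.params import GAS_CONSTANT
from rnamelt.structures import PseudoknotMode

DEFAULT_T_MIN = 0.0
DEFAULT_T_MAX = 100.0
DEFAULT_T_STEP = 0.5

#: peaks must be prominent by this fraction of max C to be reported
DEFAULT_MIN_PROMINENCE = 0.05


class GridError(ValueError):
    """Temperature grid unsuitable for finite differences."""


@dataclass
class MeltingCurve:
    """Temperature grid with lnQ, excess heat capacity and detected peaks."""

    grid: np.ndarray  # temperatures, Celsius, uniform step
    lnQ: np.ndarray  # ln partition function per grid point
    C: np.ndarray = field(default=None)  # kcal/(mol K), on grid[1:-1]
    peaks: list = field(default_factory=list)  # (T_peak C, C_peak)

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    @property
    def inner_grid(self) -> np.ndarray:
        return self.grid[1:-1]


def temperature_grid(t_min: float, t_max: float, step: float) -> np.ndarray:
    if not (t_min < t_max) or step <= 0:
        raise GridError(f"need t_min < t_max and step > 0, got {t_min}, {t_max}, {step}")
    n = int(round((t_max - t_min) / step)) + 1
    return t_min + step * np.arange(n)


def partition_over_temperature(
    seq,
    t_min: float = DEFAULT_T_MIN,
    t_max: float = DEFAULT_T_MAX,
    step: float = DEFAULT_T_STEP,
    params=None,
    entropies=None,
    pk: PseudoknotMode = PseudoknotMode.NONE,
) -> MeltingCurve:
    """lnQ(T) on a uniform grid (default 0-100 C in 0.5 C steps)."""
    grid = temperature_grid(t_min, t_max, step)
    lnq = np.array(
        [
            partition_function(
                seq, T=float(t), params=params, entropies=entropies, pk=pk,
                compute_bpp=False,
            ).lnQ
            for t in grid
        ]
    )
    return MeltingCurve(grid=grid, lnQ=lnq)


def heat_capacity(curve: MeltingCurve) -> np.ndarray:
    """Excess heat capacity on the interior grid points, kcal/(mol K)."""
    grid, lnq = np.asarray(curve.grid, float), np.asarray(curve.lnQ, float)
    if grid.size < 5:
        raise GridError(f"need >= 5 grid points for heat capacity, got {grid.size}")
    h = float(grid[1] - grid[0])
    if not np.allclose(np.diff(grid), h):
        raise GridError("temperature grid must be uniform")
    tk = grid[1:-1] + 273.15
    g1 = (lnq[2:] - lnq[:-2]) / (2 * h)
    g2 = (lnq[2:] - 2 * lnq[1:-1] + lnq[:-2]) / (h * h)
    curve.C = GAS_CONSTANT * (2 * tk * g1 + tk * tk * g2)
    return curve.C


def find_peaks(
    curve: MeltingCurve, min_prominence: float = DEFAULT_MIN_PROMINENCE
) -> list:
    """Strict local maxima of C(T) with relative prominence >= min_prominence."""
    if curve.C is None:
        heat_capacity(curve)
    c = np.asarray(curve.C, float)
    cmax = c.max(initial=0.0)
    if cmax <= 0:
        curve.peaks = []
        return curve.peaks
    idx, _ = scipy.signal.find_peaks(c, prominence=min_prominence * cmax)
    inner = curve.inner_grid
    curve.peaks = [(float(inner[i]), float(c[i])) for i in sorted(idx)]
    return curve.peaks


def melting_curve(
    seq,
    t_min: float = DEFAULT_T_MIN,
    t_max: float = DEFAULT_T_MAX,
    step: float = DEFAULT_T_STEP,
    params=None,
    entropies=None,
    pk: PseudoknotMode = PseudoknotMode.NONE,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> MeltingCurve:
    """Full melting prediction: lnQ(T), C(T) and transition peaks."""
    curve = partition_over_temperature(seq, t_min, t_max, step, params, entropies, pk)
    heat_capacity(curve)
    find_peaks(curve, min_prominence)
    return curve


def plot_melting(curve: MeltingCurve, path):
    """Write a C(T) plot to an image file (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.inner_grid, curve.C, color="firebrick")
    for t, c in curve.peaks:
        ax.annotate(f"{t:.1f} C", (t, c), textcoords="offset points", xytext=(4, 4))
    ax.set_xlabel("temperature (C)")
    ax.set_ylabel("excess heat capacity (kcal mol$^{-1}$ K$^{-1}$)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


__all__ = [
    "MeltingCurve",
    "GridError",
    "temperature_grid",
    "partition_over_temperature",
    "heat_capacity",
    "find_peaks",
    "melting_curve",
    "plot_melting",
    "DEFAULT_MIN_PROMINENCE",
]
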