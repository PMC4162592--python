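"""Melting curves: grids, heat capacity, two-state limits, peak detection."""

import math

import numpy as np
import pytest

from rnamelt.fixtures import STUDY_BISTABLE, bistable, hairpin
from rnamelt.fold2d import partition_function
from rnamelt.params import GAS_CONSTANT
from rnamelt.thermal import (
    GridError,
    MeltingCurve,
    find_peaks,
    heat_capacity,
    melting_curve,
    partition_over_temperature,
    temperature_grid,
)


def two_state_curve(dh, ds, t_min=0.0, t_max=100.0, step=0.5):
    """Closed-form two-state lnQ = ln(1 + exp(-(dH - T dS)/RT))."""
    grid = temperature_grid(t_min, t_max, step)
    tk = grid + 273.15
    lnq = np.log1p(np.exp(-(dh - tk * ds) / (GAS_CONSTANT * tk)))
    return MeltingCurve(grid=grid, lnQ=lnq)


def test_default_grid_has_201_points():
    grid = temperature_grid(0.0, 100.0, 0.5)
    assert len(grid) == 201
    assert grid[0] == 0.0 and grid[-1] == 100.0


def test_unpairable_sequence_lnq_identically_zero():
    curve = partition_over_temperature("AAAAAAAA", 0, 20, 5)
    assert np.all(curve.lnQ == 0.0)
    heat_capacity(curve)
    assert np.allclose(curve.C, 0.0)
    assert find_peaks(curve) == []


def test_constant_lnq_gives_zero_heat_capacity():
    curve = MeltingCurve(grid=temperature_grid(0, 10, 1), lnQ=np.full(11, 3.7))
    assert np.allclose(heat_capacity(curve), 0.0)


def test_two_state_peak_at_compensation_temperature():
    """C(T) peaks within one grid step of Tm = dH/dS (60.18 C here)."""
    dh, ds = -40.0, -0.12
    tm = dh / ds - 273.15
    curve = two_state_curve(dh, ds)
    heat_capacity(curve)
    peaks = find_peaks(curve)
    assert len(peaks) == 1
    assert abs(peaks[0][0] - tm) <= 0.5


def test_two_state_finite_difference_convergence():
    """Halving the step changes C at shared points by < 1e-3 of the peak."""
    dh, ds = -40.0, -0.12
    coarse = two_state_curve(dh, ds, step=0.5)
    fine = two_state_curve(dh, ds, step=0.25)
    c1 = heat_capacity(coarse)
    c2 = heat_capacity(fine)
    shared = {round(t, 4): c for t, c in zip(fine.inner_grid, c2)}
    diffs = [
        abs(c - shared[round(t, 4)])
        for t, c in zip(coarse.inner_grid, c1)
        if round(t, 4) in shared
    ]
    assert max(diffs) < 1e-3 * c1.max()


def test_two_state_enthalpy_recovered_by_integration():
    """Integrating C over the transition recovers |dH| within 5%."""
    dh, ds = -40.0, -0.12
    tm = dh / ds - 273.15
    curve = two_state_curve(dh, ds, t_min=tm - 30, t_max=tm + 30, step=0.5)
    c = heat_capacity(curve)
    mask = np.abs(curve.inner_grid - tm) <= 25.0
    integral = np.trapezoid(c[mask], curve.inner_grid[mask])
    assert integral == pytest.approx(abs(dh), rel=0.05)


def test_lnq_consistent_with_fold2d_at_grid_points():
    seq = "GGGGAAAACCCC"
    curve = partition_over_temperature(seq, 20, 60, 10)
    for t, lnq in zip(curve.grid, curve.lnQ):
        assert lnq == partition_function(seq, T=float(t), compute_bpp=False).lnQ


def test_single_hairpin_peak_near_two_state_tm():
    """The dominant transition of one helix peaks within 2 grid steps of
    Tm computed from its own total dH/dS (independent closed form)."""
    f = hairpin(4, 4)
    seq = str(f.sequence)
    from rnamelt.entropy import default_table
    from rnamelt.fold2d import EnergyModel
    from rnamelt.params import LoopType

    from rnamelt.params import stack_key

    m = EnergyModel(seq, 37.0)
    dh = 0.0
    ds = 0.0
    for t in range(3):
        h, s = m.params.lookup(stack_key(seq[t], seq[t + 1], seq[11 - t], seq[10 - t]))
        dh += h
        ds += s
    ds += GAS_CONSTANT * default_table().entropy(LoopType.HAIRPIN, (4,))
    tm = dh / ds - 273.15
    curve = melting_curve(seq, 0, 140, 0.5)
    peaks = curve.peaks
    assert len(peaks) == 1
    assert abs(peaks[0][0] - tm) <= 1.0  # two grid steps


def test_monotone_heat_capacity_has_no_peaks():
    grid = temperature_grid(0, 20, 1)
    curve = MeltingCurve(grid=grid, lnQ=np.linspace(5, 0, len(grid)) ** 2)
    heat_capacity(curve)
    assert find_peaks(curve) == []


def test_bistable_two_peaks_ordered_by_stability():
    """The melting-study fixture shows one peak per helix class; the
    AU-rich arms melt below the GC anchor."""
    f = bistable(**STUDY_BISTABLE)
    curve = melting_curve(str(f.sequence))
    assert len(curve.peaks) == 2
    (t1, c1), (t2, c2) = curve.peaks
    assert t1 < t2
    assert t1 < 70 < t2


def test_bistable_peak_count_invariant_to_grid_step():
    f = bistable(**STUDY_BISTABLE)
    counts = {
        step: len(melting_curve(str(f.sequence), 0, 100, step).peaks)
        for step in (0.25, 0.5, 1.0)
    }
    assert set(counts.values()) == {2}


def test_grid_validation():
    with pytest.raises(GridError):
        temperature_grid(50, 10, 0.5)
    with pytest.raises(GridError):
        heat_capacity(MeltingCurve(grid=np.array([0.0, 1.0]), lnQ=np.zeros(2)))
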