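"""Ideal-mixing additivity, excess area of mixing, and squeeze-out detection
for co-spread lipid-polymer films.

The additivity rule predicts the mean molecular area of an ideally mixed
film from the pure-component isotherms at the same surface pressure:
``A_calc(Π) = x_polymer·A_polymer(Π) + x_lipid·A_lipid(Π)``.  Deviations of
the experimental film from this prediction define the excess area of
mixing.  All comparisons are made at common surface pressures within the
overlap of the curves' sampled ranges — never by extrapolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConventionError, PressureOutOfRangeError
from .isotherm import (
    PER_LIPID,
    PER_MOLECULE,
    IsothermCurve,
    area_at_pressure,
)


@dataclass(frozen=True)
class MixtureSpec:
    """Lipid:polymer mole ratio with derived mole fractions.

    ``x_lipid + x_polymer == 1`` exactly (x_polymer is defined as the
    complement).  ``polymer_count == 0`` is the pure-lipid limit.
    """

    lipid_count: float
    polymer_count: float

    def __post_init__(self):
        if self.lipid_count <= 0:
            raise ValueError("lipid count must be positive")
        if self.polymer_count < 0:
            raise ValueError("polymer count must be non-negative")

    @property
    def x_lipid(self) -> float:
        return self.lipid_count / (self.lipid_count + self.polymer_count)

    @property
    def x_polymer(self) -> float:
        return 1.0 - self.x_lipid

    @property
    def ratio_label(self) -> str:
        return f"{self.lipid_count:g}:{self.polymer_count:g}"


def mole_fractions(lipid_count: float, polymer_count: float) -> MixtureSpec:
    """Build a :class:`MixtureSpec` from mole counts (e.g. 10:1)."""
    return MixtureSpec(lipid_count=lipid_count, polymer_count=polymer_count)


@dataclass(frozen=True)
class ExcessAreaSeries:
    """ΔA(Π) values against a named reference isotherm.

    ``reference`` is ``"pure_lipid"`` (ΔA = A_mix − A_lipid, both per
    lipid) or ``"calculated_ideal"`` (ΔA = A_exp − A_calc).  Positive
    values mean the film occupies more area than the reference.
    Pressures that fell outside either curve's range are listed in
    ``skipped_pressures``.
    """

    pressures: np.ndarray
    delta_area: np.ndarray
    reference: str
    mixture: MixtureSpec | None = None
    skipped_pressures: tuple[float, ...] = ()

    def __post_init__(self):
        p = np.asarray(self.pressures, dtype=float)
        d = np.asarray(self.delta_area, dtype=float)
        object.__setattr__(self, "pressures", p)
        object.__setattr__(self, "delta_area", d)
        if p.size != d.size:
            raise ValueError("pressures and delta_area must have equal length")
        if p.size > 1 and not (np.diff(p) > 0).all():
            raise ValueError("pressures must be strictly increasing")
        if self.reference not in ("pure_lipid", "calculated_ideal"):
            raise ValueError(f"unknown reference {self.reference!r}")


def _overlap(a: IsothermCurve, b: IsothermCurve) -> tuple[float, float]:
    lo = max(a.pressures[0], b.pressures[0])
    hi = min(a.pressures[-1], b.pressures[-1])
    if lo >= hi:
        raise PressureOutOfRangeError("curves have no overlapping pressure range")
    return float(lo), float(hi)


def ideal_additive_isotherm(
    lipid: IsothermCurve,
    polymer: IsothermCurve,
    mix: MixtureSpec,
    pressure_grid,
) -> IsothermCurve:
    """Mole-fraction-weighted ideal mixture isotherm on ``pressure_grid``.

    Both inputs must be monotonized per-molecule curves; the grid must lie
    within the overlap of their sampled pressure ranges.  The result is a
    per-molecule curve (use :func:`to_per_lipid` for lipid-based plots).
    """
    for name, c in (("lipid", lipid), ("polymer", polymer)):
        if c.convention != PER_MOLECULE:
            raise ConventionError(
                f"{name} curve must be per_molecule, got {c.convention}"
            )
    grid = np.sort(np.asarray(pressure_grid, dtype=float))
    lo, hi = _overlap(lipid, polymer)
    if grid[0] < lo or grid[-1] > hi:
        raise PressureOutOfRangeError(
            f"grid outside curve overlap [{lo:g}, {hi:g}] mN/m"
        )
    a_calc = (
        mix.x_lipid * area_at_pressure(lipid, grid)
        + mix.x_polymer * area_at_pressure(polymer, grid)
    )
    # stored in compression order: decreasing area, increasing pressure
    order = np.argsort(grid)
    return IsothermCurve(
        areas=np.asarray(a_calc)[order],
        pressures=grid[order],
        convention=PER_MOLECULE,
        temperature=lipid.temperature,
        label=f"ideal {mix.ratio_label}",
    )


def to_per_lipid(curve: IsothermCurve, mix: MixtureSpec) -> IsothermCurve:
    """Rescale a per-molecule curve to area per lipid (divide by x_lipid)."""
    if curve.convention != PER_MOLECULE:
        raise ConventionError("to_per_lipid expects a per_molecule curve")
    if mix.x_lipid == 0:
        raise ValueError("x_lipid must be positive")
    return curve.with_areas(curve.areas / mix.x_lipid, convention=PER_LIPID)


def _delta_series(
    minuend: IsothermCurve,
    subtrahend: IsothermCurve,
    pressures,
    reference: str,
    mixture: MixtureSpec | None,
) -> ExcessAreaSeries:
    req = np.sort(np.asarray(pressures, dtype=float))
    lo = max(minuend.pressures[0], subtrahend.pressures[0])
    hi = min(minuend.pressures[-1], subtrahend.pressures[-1])
    inside = (req >= lo) & (req <= hi)
    skipped = tuple(float(p) for p in req[~inside])
    if skipped:
        warnings.warn(
            f"{len(skipped)} pressure(s) outside the shared range "
            f"[{lo:g}, {hi:g}] were skipped: {skipped}",
            stacklevel=3,
        )
    kept = req[inside]
    delta = area_at_pressure(minuend, kept) - area_at_pressure(subtrahend, kept)
    return ExcessAreaSeries(
        pressures=kept,
        delta_area=np.atleast_1d(delta),
        reference=reference,
        mixture=mixture,
        skipped_pressures=skipped,
    )


def area_shift_vs_lipid(
    mix_curve_per_lipid: IsothermCurve,
    pure_lipid_curve: IsothermCurve,
    pressures,
    mixture: MixtureSpec | None = None,
) -> ExcessAreaSeries:
    """ΔA(Π) = A_mix_per_lipid(Π) − A_lipid(Π), reference = pure lipid.

    Out-of-range pressures are skipped with a warning and recorded in the
    result.  The pure-lipid curve may carry either convention tag (they
    coincide for a pure lipid), but the mixture curve must be per lipid.
    """
    if mix_curve_per_lipid.convention != PER_LIPID:
        raise ConventionError("mixture curve must be per_lipid")
    return _delta_series(
        mix_curve_per_lipid, pure_lipid_curve, pressures, "pure_lipid", mixture
    )


def excess_area_of_mixing(
    experimental_per_lipid: IsothermCurve,
    calculated_per_lipid: IsothermCurve,
    pressures,
    mixture: MixtureSpec | None = None,
) -> ExcessAreaSeries:
    """ΔA(Π) = A_exp(Π) − A_calc(Π), reference = calculated ideal isotherm.

    Positive values mean the real film occupies more area than additivity
    predicts (repulsive / space-filling interaction); negative values past
    the squeeze-out pressure signal polymer leaving the interface.
    """
    if experimental_per_lipid.convention != calculated_per_lipid.convention:
        raise ConventionError(
            "experimental and calculated curves must share one convention"
        )
    return _delta_series(
        experimental_per_lipid,
        calculated_per_lipid,
        pressures,
        "calculated_ideal",
        mixture,
    )


def convergence_pressure(
    mix_curve_per_lipid: IsothermCurve,
    pure_lipid_curve: IsothermCurve,
    tolerance: float = 2.0,
    grid_step: float = 0.1,
) -> float | None:
    """Smallest Π above which |A_mix − A_lipid| stays below ``tolerance``.

    "Stays" means for every grid point from there to the end of the shared
    pressure range (a sustained window, not a single crossing).  Returns
    None when the curves never converge within the overlap.  The default
    tolerance is 2 Å², the stated molecular-area uncertainty.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    lo, hi = _overlap(mix_curve_per_lipid, pure_lipid_curve)
    n = max(int(np.ceil((hi - lo) / grid_step)) + 1, 2)
    grid = np.linspace(lo, hi, n)
    delta = np.abs(
        area_at_pressure(mix_curve_per_lipid, grid)
        - area_at_pressure(pure_lipid_curve, grid)
    )
    inside = delta < tolerance
    # last index where the condition fails; convergence starts just after
    failing = np.flatnonzero(~inside)
    if failing.size == 0:
        return float(grid[0])
    if failing[-1] == n - 1:
        return None
    return float(grid[failing[-1] + 1])
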