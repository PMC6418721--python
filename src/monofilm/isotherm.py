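"""Data model and feature extraction for single pressure-area isotherms.

Units are fixed package-wide: molecular area in Å² (per molecule or per
lipid, tracked by the ``convention`` tag), surface pressure in mN/m,
temperature in °C.  Compression order is decreasing area.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateCurveError,
    NoLiftOffError,
    PressureOutOfRangeError,
    SmoothingWindowError,
)

PER_MOLECULE = "per_molecule"
PER_LIPID = "per_lipid"

#: Instrument noise floor for surface pressure, mN/m.
PRESSURE_FLOOR = -0.5

#: Default lift-off threshold: the stated pressure uncertainty, mN/m.
DEFAULT_LIFT_OFF_THRESHOLD = 0.5


@dataclass(frozen=True)
class IsothermCurve:
    """One compression run: ordered (area, pressure) samples.

    Parameters
    ----------
    areas :
        Molecular areas in Å², in compression order (decreasing for a
        well-formed run; enforced only after :func:`monotonize`).
    pressures :
        Surface pressures in mN/m, same length as ``areas``.
    convention :
        ``"per_molecule"`` (area divided by all spread molecules) or
        ``"per_lipid"`` (area divided by lipid count only).
    temperature :
        Subphase temperature in °C.
    label :
        Free-text identifier.
    """

    areas: np.ndarray
    pressures: np.ndarray
    convention: str = PER_MOLECULE
    temperature: float = 20.0
    label: str = ""

    def __post_init__(self):
        areas = np.asarray(self.areas, dtype=float)
        pressures = np.asarray(self.pressures, dtype=float)
        object.__setattr__(self, "areas", areas)
        object.__setattr__(self, "pressures", pressures)
        if areas.ndim != 1 or pressures.ndim != 1:
            raise ValueError("areas and pressures must be 1-D")
        if areas.size != pressures.size:
            raise ValueError("areas and pressures must have equal length")
        if areas.size < 2:
            raise DegenerateCurveError("an isotherm needs at least 2 samples")
        if not (np.isfinite(areas).all() and np.isfinite(pressures).all()):
            raise ValueError("non-finite sample values")
        if (areas <= 0).any():
            raise ValueError("all areas must be positive")
        if (pressures < PRESSURE_FLOOR).any():
            raise ValueError(
                f"pressures below the {PRESSURE_FLOOR} mN/m noise floor"
            )
        if self.convention not in (PER_MOLECULE, PER_LIPID):
            raise ValueError(f"unknown convention {self.convention!r}")

    def __len__(self) -> int:
        return int(self.areas.size)

    @property
    def samples(self) -> list[tuple[float, float]]:
        return list(zip(self.areas.tolist(), self.pressures.tolist()))

    @property
    def pressure_range(self) -> tuple[float, float]:
        return float(self.pressures.min()), float(self.pressures.max())

    def is_monotonized(self) -> bool:
        """True if area is strictly decreasing and pressure strictly
        increasing in stored order."""
        return bool(
            (np.diff(self.areas) < 0).all() and (np.diff(self.pressures) > 0).all()
        )

    def with_areas(self, areas: np.ndarray, convention: str | None = None) -> "IsothermCurve":
        return replace(
            self, areas=np.asarray(areas, float),
            convention=convention or self.convention,
        )


def monotonize(curve: IsothermCurve) -> IsothermCurve:
    """Return a compression-ordered curve with single-valued A(Π).

    Samples are sorted by decreasing area, pressure is replaced by its
    running maximum, and for runs of equal pressure only the largest-area
    sample (first attainment during compression) is kept, so pressure ends
    up strictly increasing.  Idempotent; never increases the sample count.

    Raises
    ------
    DegenerateCurveError
        If fewer than 2 samples survive.
    """
    order = np.argsort(-curve.areas, kind="stable")
    areas = curve.areas[order]
    pressures = np.maximum.accumulate(curve.pressures[order])
    # first attainment: keep the first index of each pressure-tie run
    keep = np.empty(pressures.size, dtype=bool)
    keep[0] = True
    keep[1:] = pressures[1:] > pressures[:-1]
    # equal areas would break strict decrease; keep the first (max pressure
    # arrives later in the running max, so keep the *last* of an area tie)
    areas_k = areas[keep]
    pressures_k = pressures[keep]
    area_keep = np.empty(areas_k.size, dtype=bool)
    area_keep[-1] = True
    area_keep[:-1] = areas_k[:-1] > areas_k[1:]
    areas_k = areas_k[area_keep]
    pressures_k = pressures_k[area_keep]
    if areas_k.size < 2:
        raise DegenerateCurveError(
            f"only {areas_k.size} sample(s) survive monotonization"
        )
    return replace(curve, areas=areas_k, pressures=pressures_k)


def _require_monotone(curve: IsothermCurve) -> None:
    if not curve.is_monotonized():
        raise ValueError("curve must be monotonized first (see monotonize())")


def area_at_pressure(curve: IsothermCurve, pressure) -> float | np.ndarray:
    """Piecewise-linear interpolation of A as a function of Π.

    Never extrapolates: queries outside the sampled pressure range raise
    :class:`PressureOutOfRangeError`.  Accepts a scalar or an array of
    pressures.
    """
    _require_monotone(curve)
    p = np.asarray(pressure, dtype=float)
    lo, hi = curve.pressures[0], curve.pressures[-1]
    if (p < lo).any() or (p > hi).any():
        raise PressureOutOfRangeError(
            f"pressure query outside sampled range [{lo:g}, {hi:g}] mN/m"
        )
    out = np.interp(p, curve.pressures, curve.areas)
    return float(out) if np.isscalar(pressure) else out


def pressure_at_area(curve: IsothermCurve, area) -> float | np.ndarray:
    """Symmetric piecewise-linear interpolation of Π as a function of A."""
    _require_monotone(curve)
    a = np.asarray(area, dtype=float)
    lo, hi = curve.areas[-1], curve.areas[0]
    if (a < lo).any() or (a > hi).any():
        raise PressureOutOfRangeError(
            f"area query outside sampled range [{lo:g}, {hi:g}] Å²"
        )
    # areas are stored decreasing; np.interp wants increasing x
    out = np.interp(a, curve.areas[::-1], curve.pressures[::-1])
    return float(out) if np.isscalar(area) else out


def lift_off_area(
    curve: IsothermCurve,
    threshold: float = DEFAULT_LIFT_OFF_THRESHOLD,
    refine_window: int = 0,
) -> float:
    """Molecular area at which Π first reaches ``threshold`` on compression.

    By default this is the largest area with Π equal to the threshold,
    obtained by linear interpolation on the monotonized curve (exact for
    noiseless data).  With ``refine_window >= 5`` the crossing is instead
    estimated by an ordinary least-squares line through the raw samples in
    a window of that many points around the first crossing, which averages
    out pressure noise; the curve then only needs to be compression-sorted,
    not strictly monotone.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if curve.pressures.max() < threshold:
        raise NoLiftOffError(
            f"pressure never reaches the {threshold:g} mN/m threshold"
        )
    if refine_window >= 5:
        return _lift_off_refined(curve, threshold, refine_window)
    _require_monotone(curve)
    if curve.pressures[0] >= threshold:
        # curve starts already above threshold; first sample is the best
        # available first attainment
        return float(curve.areas[0])
    return float(np.interp(threshold, curve.pressures, curve.areas))


def _lift_off_refined(curve: IsothermCurve, threshold: float, window: int) -> float:
    order = np.argsort(-curve.areas, kind="stable")
    areas = curve.areas[order]
    pressures = curve.pressures[order]
    n = areas.size
    if n < window:
        raise SmoothingWindowError(f"need at least {window} samples, have {n}")
    # locate the first crossing on a lightly smoothed signal so an isolated
    # noise spike cannot trigger it
    smooth = _local_quadratic_value(areas, pressures, min(window, 11))
    crossings = np.flatnonzero(smooth >= threshold)
    if crossings.size == 0:
        raise NoLiftOffError(
            f"pressure never reaches the {threshold:g} mN/m threshold"
        )
    i = int(crossings[0])
    half = window // 2
    lo = max(0, i - half)
    hi = min(n, i + half + 1)
    a = areas[lo:hi]
    p = pressures[lo:hi]
    slope, intercept = np.polyfit(a, p, 1)
    if slope >= 0:
        # no usable local trend; fall back to the smoothed crossing point
        return float(areas[i])
    return float((threshold - intercept) / slope)


def _local_quadratic_value(x: np.ndarray, y: np.ndarray, window: int) -> np.ndarray:
    """Smoothed y at every point by a local quadratic fit (asymmetric
    windows at the edges)."""
    n = x.size
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, min(i - half, n - window))
        hi = lo + window
        xc = x[lo:hi] - x[i]
        coeffs = np.polynomial.polynomial.polyfit(xc, y[lo:hi], 2)
        out[i] = coeffs[0]
    return out


def smooth_isotherm(curve: IsothermCurve, window: int = 11) -> IsothermCurve:
    """Denoise pressures by a local quadratic fit along the area axis.

    Intended for noisy recordings before :func:`monotonize`: the area grid
    (set by the barrier program) is kept, only pressures are smoothed, so
    monotonization afterwards discards far fewer samples.
    """
    if window < 5 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 5")
    if len(curve) < window:
        raise SmoothingWindowError(
            f"need at least {window} samples, have {len(curve)}"
        )
    order = np.argsort(-curve.areas, kind="stable")
    areas = curve.areas[order]
    pressures = curve.pressures[order]
    smooth = _local_quadratic_value(areas, pressures, window)
    smooth = np.maximum(smooth, PRESSURE_FLOOR)
    return replace(curve, areas=areas, pressures=smooth)


def _local_quadratic_slope(x: np.ndarray, y: np.ndarray, window: int) -> np.ndarray:
    """dy/dx at interior points by a symmetric local quadratic fit.

    Handles non-uniform grids; returns slopes for indices
    ``half .. n - half - 1`` where ``half = window // 2``.
    """
    n = x.size
    half = window // 2
    slopes = np.empty(n - 2 * half)
    for i in range(half, n - half):
        xs = x[i - half : i + half + 1]
        ys = y[i - half : i + half + 1]
        xc = xs - x[i]
        # quadratic fit: slope at the centre is the linear coefficient
        coeffs = np.polynomial.polynomial.polyfit(xc, ys, 2)
        slopes[i - half] = coeffs[1]
    return slopes


def compressibility_modulus(
    curve: IsothermCurve, window: int = 11
) -> tuple[np.ndarray, np.ndarray]:
    """Compression modulus Cs⁻¹ = −A·dΠ/dA on the interior grid.

    The derivative is a smoothed local-quadratic fit over ``window`` points
    (odd, >= 5).  Returns ``(areas, cs_inv)`` in compression order, with
    ``window // 2`` samples trimmed from each edge.
    """
    _require_monotone(curve)
    if window < 5 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 5")
    if len(curve) < window:
        raise SmoothingWindowError(
            f"need at least {window} samples, have {len(curve)}"
        )
    half = window // 2
    slopes = _local_quadratic_slope(curve.areas, curve.pressures, window)
    areas = curve.areas[half : len(curve) - half]
    return areas, -areas * slopes


@dataclass(frozen=True)
class TransitionFeatures:
    """Landmarks of one isotherm's LE-LC transition region.

    ``found`` is False when no qualifying onset was detected; in that case
    the onset fields are None (lift-off is still reported when available).
    """

    lift_off_area: float | None
    transition_onset_pressure: float | None
    transition_onset_area: float | None
    plateau_end_area: float | None = None
    collapse_pressure: float | None = None
    found: bool = False

    def __post_init__(self):
        if self.found:
            if self.transition_onset_pressure is None or self.transition_onset_area is None:
                raise ValueError("found=True requires onset pressure and area")
            if self.transition_onset_pressure < 0:
                raise ValueError("onset pressure must be >= 0")
            if (
                self.lift_off_area is not None
                and self.lift_off_area < self.transition_onset_area
            ):
                raise ValueError("lift-off area must be >= onset area")


def transition_onset(
    curve: IsothermCurve,
    *,
    window: int = 11,
    drop_fraction: float = 0.25,
    sustain: int = 3,
    lift_threshold: float = DEFAULT_LIFT_OFF_THRESHOLD,
    min_le_points: int = 5,
) -> TransitionFeatures:
    """Locate the LE-LC transition onset from the compression-modulus dip.

    The onset is the first point (in compression order, above the lift-off
    pressure) where Cs⁻¹ drops below ``drop_fraction`` times the running
    median of the preceding liquid-expanded branch and stays there for
    ``sustain`` consecutive samples.  A curve with no qualifying dip gets
    ``found=False`` rather than an exception.
    """
    _require_monotone(curve)
    try:
        lo_area = lift_off_area(curve, lift_threshold)
    except NoLiftOffError:
        lo_area = None

    areas, cs = compressibility_modulus(curve, window=window)
    pressures = pressure_at_area(curve, areas)

    # restrict to the film region: gas-phase Cs⁻¹ ~ 0 would false-trigger
    film = np.flatnonzero(pressures >= lift_threshold)
    no_hit = TransitionFeatures(
        lift_off_area=lo_area,
        transition_onset_pressure=None,
        transition_onset_area=None,
        found=False,
    )
    if film.size < min_le_points + sustain:
        return no_hit
    idx = film  # compression order (areas decreasing)
    cs_f = cs[idx]

    onset_i = None
    for j in range(min_le_points, cs_f.size - sustain + 1):
        med = np.median(cs_f[:j])
        limit = drop_fraction * med
        if med > 0 and (cs_f[j : j + sustain] < limit).all():
            onset_i = j
            break
    if onset_i is None:
        return no_hit

    k = idx[onset_i]
    onset_area = float(areas[k])
    onset_pressure = float(pressures[k])

    # optional plateau end: first sustained recovery of Cs⁻¹ past the dip
    plateau_end = None
    med = np.median(cs_f[:onset_i])
    limit = drop_fraction * med
    for j in range(onset_i + sustain, cs_f.size - sustain + 1):
        if (cs_f[j : j + sustain] >= limit).all():
            plateau_end = float(areas[idx[j]])
            break

    return TransitionFeatures(
        lift_off_area=lo_area,
        transition_onset_pressure=onset_pressure,
        transition_onset_area=onset_area,
        plateau_end_area=plateau_end,
        found=True,
    )
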